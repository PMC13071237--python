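"""Ridge-regularized lagged regression (forward temporal response functions).

A forward TRF models the response as a lagged linear combination of one
or more stimulus features, y(t) = b + sum_i sum_tau w_i(tau) x_i(t - tau),
with tau running over a fixed lag window. Negative lags mean the
response precedes the feature (pre-stimulus weights): with lags from
-200 ms to +500 ms the weight at tau = -0.2 s multiplies the feature
0.2 s in the *future* of the response sample.

Weights solve ridge least squares on the lagged design matrix with an
unpenalized intercept, w = (X'X + lambda I)^-1 X'y on column-centered
data. Rows whose lag coverage would run off either end of the series
are dropped (valid-sample convention); the same convention applies at
prediction time, where edge samples are returned as NaN.

Features are z-scored before lagging, so weights are in standardized
units; a zero-variance feature is mapped to all zeros rather than NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-6, 6, 13))


@dataclass
class TRFModel:
    """Fitted lagged-regression weights: predictors x lags."""

    weights: np.ndarray  # (n_features, n_lags)
    lag_axis_s: np.ndarray  # seconds, strictly increasing, step 1/fs
    bias: float
    lam: float
    fs: int
    feature_means: np.ndarray = field(default=None)
    feature_stds: np.ndarray = field(default=None)

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.lag_axis_s = np.asarray(self.lag_axis_s, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("TRF weights must be finite")
        if np.any(np.diff(self.lag_axis_s) <= 0):
            raise ValueError("lag axis must be strictly increasing")

    def lag_window(self, lo_s: float, hi_s: float) -> "TRFModel":
        """Pure slice of the fitted lag axis onto [lo_s, hi_s]."""
        keep = (self.lag_axis_s >= lo_s - 1e-12) & (self.lag_axis_s <= hi_s + 1e-12)
        if not np.any(keep):
            raise ValueError("requested lag window does not intersect the lag axis")
        return TRFModel(
            self.weights[:, keep], self.lag_axis_s[keep], self.bias, self.lam, self.fs,
            self.feature_means, self.feature_stds,
        )

    def to_json(self, path) -> None:
        obj = {
            "weights": self.weights.tolist(),
            "lag_axis_s": self.lag_axis_s.tolist(),
            "bias": self.bias,
            "lambda": self.lam,
            "fs": self.fs,
            "feature_means": None if self.feature_means is None else self.feature_means.tolist(),
            "feature_stds": None if self.feature_stds is None else self.feature_stds.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "TRFModel":
        with open(path) as fh:
            obj = json.load(fh)
        fm = obj.get("feature_means")
        fsd = obj.get("feature_stds")
        return cls(
            np.array(obj["weights"]), np.array(obj["lag_axis_s"]), obj["bias"],
            obj["lambda"], obj["fs"],
            None if fm is None else np.array(fm),
            None if fsd is None else np.array(fsd),
        )


def _as_feature_matrix(features) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    elif x.ndim == 2 and x.shape[0] < x.shape[1]:
        # accept (k, n) layouts from stacked 1-D series
        x = x.T
    return x


def standardize(x: np.ndarray):
    """Z-score columns; zero-variance columns become all zeros."""
    means = x.mean(axis=0)
    stds = x.std(axis=0)
    safe = np.where(stds > 0, stds, 1.0)
    z = (x - means) / safe
    z[:, stds == 0] = 0.0
    return z, means, stds


def lag_samples(fs: int, lag_min_s: float, lag_max_s: float) -> np.ndarray:
    if lag_min_s >= lag_max_s:
        raise ValueError("lag_min_s must be below lag_max_s")
    return np.arange(int(round(lag_min_s * fs)), int(round(lag_max_s * fs)) + 1)


def lagged_design(x: np.ndarray, fs: int, lag_min_s: float, lag_max_s: float):
    """Build the valid-sample lagged design matrix.

    Returns ``(X, lag_axis_s, valid)`` where ``X`` is
    (n_valid, n_features * n_lags) with columns ordered feature-major
    (all lags of feature 0, then feature 1, ...), and ``valid`` is the
    slice of original sample indices retained.
    """
    x = _as_feature_matrix(x)
    n, k = x.shape
    lags = lag_samples(fs, lag_min_s, lag_max_s)
    t0 = max(int(lags[-1]), 0)
    t1 = n + min(int(lags[0]), 0)
    if t1 <= t0:
        raise ValueError("series too short for the requested lag window")
    rows = np.arange(t0, t1)
    X = np.empty((len(rows), k * len(lags)))
    for i in range(k):
        for j, l in enumerate(lags):
            X[:, i * len(lags) + j] = x[rows - l, i]
    return X, lags / fs, slice(t0, t1)


def _solve_centered(G, xy, xm, ym, n, lam):
    """Ridge solve on centered sufficient statistics with free intercept."""
    Gc = G - n * np.outer(xm, xm)
    rhs = xy - n * xm * ym
    A = Gc + lam * np.eye(len(G))
    try:
        w = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular lagged design (lambda={lam}); increase regularization"
        ) from err
    return w, float(ym - xm @ w)


def fit_trf(
    features,
    response,
    fs: int,
    lag_min_s: float,
    lag_max_s: float,
    lam: float = 0.0,
) -> TRFModel:
    """Fit a forward TRF by ridge regression on the lagged design."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    x = _as_feature_matrix(features)
    y = np.asarray(response, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"feature length {len(x)} != response length {len(y)}")
    z, means, stds = standardize(x)
    X, lag_axis, valid = lagged_design(z, fs, lag_min_s, lag_max_s)
    yv = y[valid]
    G = X.T @ X
    w, bias = _solve_centered(G, X.T @ yv, X.mean(axis=0), yv.mean(), len(yv), lam)
    weights = w.reshape(x.shape[1], len(lag_axis))
    return TRFModel(weights, lag_axis, bias, lam, fs, means, stds)


def predict(model: TRFModel, features) -> np.ndarray:
    """Predicted response; NaN on edge samples without full lag coverage."""
    x = _as_feature_matrix(features)
    if x.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature count {x.shape[1]} does not match model ({model.weights.shape[0]})"
        )
    if model.feature_means is not None:
        safe = np.where(model.feature_stds > 0, model.feature_stds, 1.0)
        x = (x - model.feature_means) / safe
        x[:, model.feature_stds == 0] = 0.0
    X, _, valid = lagged_design(x, model.fs, model.lag_axis_s[0], model.lag_axis_s[-1])
    out = np.full(len(x), np.nan)
    out[valid] = X @ model.weights.ravel() + model.bias
    return out


def r_squared(predicted, observed) -> float:
    """Squared Pearson correlation between prediction and observation.

    NaN samples (edge rows from the valid-sample convention) are
    dropped pairwise. Note this is symmetric and sign-invariant: a
    perfectly anti-correlated prediction also scores 1.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if len(p) != len(o):
        raise ValueError("predicted and observed must have equal length")
    keep = np.isfinite(p) & np.isfinite(o)
    p, o = p[keep], o[keep]
    if len(p) < 2 or np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("zero-variance input to r_squared")
    r = np.corrcoef(p, o)[0, 1]
    return float(r * r)


def select_lambda(
    features,
    response,
    fs: int,
    lag_min_s: float,
    lag_max_s: float,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
):
    """Regularization selection by contiguous-block k-fold CV.

    Returns the grid value maximizing the mean held-out coefficient of
    determination (1 - SS_res/SS_tot; unlike the squared correlation it
    penalizes amplitude error, so shrinkage wins under a pure-noise
    response); ties resolve to the smaller lambda.
    """
    grid = sorted(float(l) for l in np.atleast_1d(lambda_grid))
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    x = _as_feature_matrix(features)
    y = np.asarray(response, dtype=float)
    z, _, _ = standardize(x)
    X, _, valid = lagged_design(z, fs, lag_min_s, lag_max_s)
    yv = y[valid]
    n = len(yv)
    if n_folds > n:
        raise ValueError(f"{n_folds} folds exceed {n} valid samples")
    edges = np.linspace(0, n, n_folds + 1).astype(int)
    G_all = X.T @ X
    xy_all = X.T @ yv
    scores = np.zeros(len(grid))
    for f in range(n_folds):
        te = slice(edges[f], edges[f + 1])
        Xte, yte = X[te], yv[te]
        G_tr = G_all - Xte.T @ Xte
        xy_tr = xy_all - Xte.T @ yte
        n_tr = n - (edges[f + 1] - edges[f])
        xm = (X.sum(axis=0) - Xte.sum(axis=0)) / n_tr
        ym = (yv.sum() - yte.sum()) / n_tr
        var_te = np.var(yte)
        if var_te == 0:
            continue
        for gi, lam in enumerate(grid):
            w, b = _solve_centered(G_tr, xy_tr, xm, ym, n_tr, lam)
            pred = Xte @ w + b
            scores[gi] += (1.0 - np.mean((pred - yte) ** 2) / var_te) / n_folds
    return grid[int(np.argmax(scores))]
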