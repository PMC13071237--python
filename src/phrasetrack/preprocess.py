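"""EEG preprocessing: band-pass, epoching, average reference, MCCA denoising.

The denoising step is the two-stage-PCA formulation of multiway
canonical correlation analysis (MCCA): a PCA per subject (scores
whitened to unit variance), then a PCA across the subjects-concatenated
scores whose leading components are the signal shared across listeners
of the identical stimulus. The shared subspace is projected back into
each subject's data and, per subject, the single back-projected
component explaining the most variance in that subject's own data is
retained, collapsing the multichannel recording to one series per
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .eeg_sim import EEGRecording


@dataclass
class Epoch:
    """Channels x samples slab around one melody presentation."""

    data: np.ndarray
    fs: int
    t0_s: float  # melody onset relative to epoch start (= pre-padding)
    subject_id: str = ""
    melody_id: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))


@dataclass
class DenoisedComponent:
    """Single unit-variance component per subject after MCCA."""

    series: np.ndarray
    fs: int
    subject_id: str = ""
    melody_id: str = ""
    variance_explained: float = 0.0
    t0_s: float = 0.0


def bandpass(rec: EEGRecording, lo: float = 0.5, hi: float = 35.0, order: int = 5) -> EEGRecording:
    """Zero-phase (two-pass) Butterworth band-pass; length preserved."""
    if not 0 < lo < hi:
        raise ValueError(f"invalid band [{lo}, {hi}]")
    if rec.fs <= 2 * hi:
        raise ValueError(f"sample rate {rec.fs} too low for a {hi} Hz band edge")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=data)


def epoch(
    rec: EEGRecording,
    melody_onset_s: float,
    melody_dur_s: float,
    pre: float = 3.0,
    post: float = 2.0,
    melody_id: str = "",
) -> Epoch:
    """Extract a -pre .. melody .. +post slab around one presentation."""
    i0 = int(round((melody_onset_s - pre) * rec.fs))
    n = int(round((pre + melody_dur_s + post) * rec.fs))
    if i0 < 0 or i0 + n > rec.data.shape[1]:
        raise ValueError(
            f"epoch [{melody_onset_s - pre:.2f}, {melody_onset_s + melody_dur_s + post:.2f}] s "
            "exceeds the recording"
        )
    return Epoch(rec.data[:, i0 : i0 + n].copy(), rec.fs, pre, rec.subject_id, melody_id)


def rereference_average(ep: Epoch) -> Epoch:
    """Subtract the per-sample mean across channels (idempotent)."""
    if ep.data.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = ep.data - ep.data.mean(axis=0, keepdims=True)
    return Epoch(data, ep.fs, ep.t0_s, ep.subject_id, ep.melody_id)


def _pca(x: np.ndarray, n_keep: int):
    """PCA of (samples x features) data; returns scores, components, evr."""
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u[:, :n_keep] * s[:n_keep]
    var = s**2
    evr = var[:n_keep] / var.sum() if var.sum() > 0 else np.zeros(n_keep)
    return scores, vt[:n_keep], evr


def mcca_denoise(
    epochs: Sequence[Epoch],
    n_pcs_per_subject: int = 10,
    n_shared: int = 5,
    envelope: Optional[np.ndarray] = None,
) -> list:
    """Two-stage-PCA MCCA: one denoised component per subject.

    ``epochs`` holds one epoch per subject for the same melody (equal
    rate and length). If ``envelope`` (the stimulus envelope resampled
    to the epoch rate and length) is given, each returned component's
    sign is fixed so its correlation with the envelope is nonnegative;
    otherwise the PCA sign convention applies.
    """
    if len(epochs) < 2:
        raise ValueError("MCCA needs at least 2 subjects")
    fs = epochs[0].fs
    n = epochs[0].data.shape[1]
    for ep in epochs:
        if ep.fs != fs or ep.data.shape[1] != n:
            raise ValueError("all epochs must share the sample rate and length")
        if n_pcs_per_subject > ep.data.shape[0]:
            raise ValueError(
                f"n_pcs_per_subject={n_pcs_per_subject} exceeds channel count "
                f"{ep.data.shape[0]}"
            )

    # stage 1: per-subject PCA; scores keep their variance ordering but each
    # subject is normalized to unit total variance so subjects weigh equally
    whitened = []
    for ep in epochs:
        scores, _, _ = _pca(ep.data.T, n_pcs_per_subject)
        total = np.sqrt(np.mean(scores.var(axis=0)))
        whitened.append(scores / total if total > 0 else scores)

    # stage 2: PCA on subjects-concatenated scores (time x S*n_pcs)
    stacked = np.concatenate(whitened, axis=1)
    shared_scores, comps, _ = _pca(stacked, n_shared)

    out = []
    for s, ep in enumerate(epochs):
        cols = slice(s * n_pcs_per_subject, (s + 1) * n_pcs_per_subject)
        xc = ep.data.T - ep.data.T.mean(axis=0)
        total_var = np.sum(xc**2)
        best = None
        for k in range(n_shared):
            # subject's contribution to shared component k
            c = whitened[s] @ comps[k, cols]
            cc = c - c.mean()
            denom = np.sum(cc**2)
            if denom == 0:
                continue
            # variance of subject data explained by regressing channels on c
            explained = np.sum((xc.T @ cc) ** 2) / denom
            if best is None or explained > best[0]:
                best = (explained, cc)
        if best is None:
            raise ValueError("degenerate data: no shared component with variance")
        explained, cc = best
        series = cc / cc.std()
        if envelope is not None:
            env = np.asarray(envelope, dtype=float)
            if len(env) == len(series) and np.std(env) > 0:
                if np.corrcoef(series, env)[0, 1] < 0:
                    series = -series
        out.append(
            DenoisedComponent(
                series, fs, ep.subject_id, ep.melody_id,
                float(explained / total_var) if total_var > 0 else 0.0, ep.t0_s,
            )
        )
    return out
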