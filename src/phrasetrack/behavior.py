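"""Behavioral scoring of phrase-boundary detection.

Key presses are snapped to the beat grid (removing within-beat
fragmentation), then scored against the annotated boundaries with a
three-beat tolerance window centered on each boundary beat (b-1, b,
b+1): greedy nearest-first one-to-one matching yields true positives,
unmatched marks are false positives and unmatched boundaries false
negatives, and the F-score is the harmonic mean of precision and
recall. Shuffled melodies are scored against the boundary positions of
their unshuffled source, giving the chance-level baseline. Agreement
across listeners uses Krippendorff's alpha on the per-beat binary
marks; note that unlike a common informal description, alpha is not
bounded below by zero -- systematic disagreement drives it negative --
and the coincidence-matrix definition implemented here allows that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ResponseGrid:
    """Binary per-beat marks for one listener and one melody."""

    marks: np.ndarray
    subject_id: str = ""
    melody_id: str = ""

    def __post_init__(self):
        self.marks = np.asarray(self.marks, dtype=int)
        if not np.isin(self.marks, (0, 1)).all():
            raise ValueError("marks must be binary")


@dataclass
class ScoreReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    mean_offset_s: float = float("nan")
    pairs: tuple = ()  # matched (mark_beat, truth_beat) pairs


def grid_responses(
    press_times_s: Sequence[float],
    tempo_bpm: float,
    total_beats: int,
    subject_id: str = "",
    melody_id: str = "",
) -> ResponseGrid:
    """Assign presses to beat bins; multiple presses per beat collapse to one.

    Presses outside the melody span are dropped with a logged count.
    """
    if tempo_bpm <= 0:
        raise ValueError("tempo must be positive")
    marks = np.zeros(int(total_beats), dtype=int)
    dropped = 0
    for t in press_times_s:
        beat = int(np.floor(t * tempo_bpm / 60.0 + 1e-9))
        if 0 <= beat < len(marks):
            marks[beat] = 1
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d press(es) outside the melody span", dropped)
    return ResponseGrid(marks, subject_id, melody_id)


def _greedy_match(marks: np.ndarray, truths: np.ndarray, tolerance: float):
    """Nearest-first one-to-one matching within +-tolerance."""
    cand = [
        (abs(m - t), t, m)
        for m in marks
        for t in truths
        if abs(m - t) <= tolerance + 1e-9
    ]
    used_m: set = set()
    used_t: set = set()
    pairs = []
    for _, t, m in sorted(cand):
        if m in used_m or t in used_t:
            continue
        used_m.add(m)
        used_t.add(t)
        pairs.append((m, t))
    return pairs


def f_score(
    grid: ResponseGrid, truth_beats: Sequence[float], window_beats: int = 3
) -> ScoreReport:
    """Tolerance-windowed precision/recall/F against annotated boundaries.

    ``window_beats`` is the full window size: 3 accepts a mark at the
    boundary beat or one beat to either side. A mark can satisfy at
    most one boundary and vice versa (greedy nearest-first one-to-one
    matching).
    """
    if window_beats < 1:
        raise ValueError("window must span at least 1 beat")
    truth = np.asarray(truth_beats, dtype=float)
    if len(truth) and truth.max() > len(grid.marks) + 1e-9:
        raise ValueError("truth boundary beyond grid length")
    marks = np.flatnonzero(grid.marks).astype(float)
    half = (window_beats - 1) / 2.0
    pairs = _greedy_match(marks, truth, half)
    tp = len(pairs)
    fp = len(marks) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ScoreReport(tp, fp, fn, precision, recall, f, pairs=tuple(pairs))


def shuffled_baseline(
    grid: ResponseGrid, original_truth_beats: Sequence[float], window_beats: int = 3
) -> ScoreReport:
    """Score a shuffled-condition grid against the source melody's truth.

    The result is the chance-level accuracy for that response density.
    """
    truth = np.asarray(original_truth_beats, dtype=float)
    if truth.size == 0:
        raise ValueError("shuffled melody carries no pseudo-boundaries")
    return f_score(grid, truth, window_beats)


def chance_f_score(
    mark_density: float, n_boundaries: int, total_beats: int, window_beats: int = 3
) -> float:
    """Expected F-score for independent random marks at a given density.

    Assumes boundary windows are disjoint (boundaries >= window_beats
    apart): a boundary is hit when any of its ``window_beats`` bins is
    marked, so E[TP] = B (1 - (1-p)^w), and with E[marks] = p T the
    expected F is approximated by the ratio of expectations,
    2 E[TP] / (E[marks] + B).
    """
    p = float(mark_density)
    hit = 1.0 - (1.0 - p) ** window_beats
    e_tp = n_boundaries * hit
    denom = p * total_beats + n_boundaries
    return 2.0 * e_tp / denom if denom > 0 else 0.0


def krippendorff_alpha(ratings) -> float:
    """Nominal-level Krippendorff's alpha from a raters x units matrix.

    Missing entries are NaN and excluded pairwise; alpha = 1 - D_o/D_e
    with observed and expected disagreement taken from the coincidence
    matrix.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("need a raters x units matrix with >= 2 raters")
    values = np.unique(r[np.isfinite(r)])
    idx = {v: i for i, v in enumerate(values)}
    V = len(values)
    coincidence = np.zeros((V, V))
    for u in range(r.shape[1]):
        col = r[:, u]
        col = col[np.isfinite(col)]
        m = len(col)
        if m < 2:
            continue
        for i in range(m):
            for j in range(m):
                if i != j:
                    coincidence[idx[col[i]], idx[col[j]]] += 1.0 / (m - 1)
    n_total = coincidence.sum()
    if n_total == 0:
        raise ValueError("no pairable values")
    n_c = coincidence.sum(axis=1)
    d_o = (n_total - np.trace(coincidence)) / n_total
    d_e = (n_total**2 - np.sum(n_c**2)) / (n_total * (n_total - 1))
    if d_e == 0:
        return 1.0
    return float(1.0 - d_o / d_e)


def detection_rate(
    grids: Sequence[ResponseGrid], truth_beats: Sequence[float], window_beats: int = 3
) -> np.ndarray:
    """Per-boundary fraction of subjects with a true-positive match."""
    if not grids:
        raise ValueError("empty subject set")
    truth = np.asarray(truth_beats, dtype=float)
    hits = np.zeros(len(truth))
    for grid in grids:
        matched = {t for _, t in f_score(grid, truth, window_beats).pairs}
        for i, tb in enumerate(truth):
            if tb in matched:
                hits[i] += 1
    return hits / len(grids)


def response_offsets(
    press_times_s: Sequence[float],
    truth_times_s: Sequence[float],
    tempo_bpm: float,
    window_beats: int = 3,
) -> float:
    """Mean press-minus-boundary offset (s) over matched pairs.

    Matching mirrors the F-score pairing (nearest-first one-to-one,
    tolerance window converted to seconds at the stimulus tempo);
    negative offsets are anticipatory.
    """
    beat_s = 60.0 / tempo_bpm
    half_s = (window_beats - 1) / 2.0 * beat_s
    pairs = _greedy_match(
        np.asarray(press_times_s, dtype=float), np.asarray(truth_times_s, dtype=float), half_s
    )
    if not pairs:
        raise ValueError("no matched press/boundary pairs")
    return float(np.mean([p - t for p, t in pairs]))
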