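"""Behavioral scoring: gridding, F-score, chance baseline, agreement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phrasetrack import behavior
from phrasetrack.behavior import ResponseGrid


def brute_force_alpha(ratings):
    """Pairwise-disagreement oracle for nominal Krippendorff's alpha."""
    r = np.asarray(ratings, dtype=float)
    pairs_o = []  # observed pairs within units
    all_values = []
    for u in range(r.shape[1]):
        col = r[:, u]
        col = col[np.isfinite(col)]
        m = len(col)
        if m < 2:
            continue
        all_values.extend([(v, m) for v in col])
        for a, b in itertools.permutations(col, 2):
            pairs_o.append((a, b, m))
    n = sum(1 for _ in all_values)
    d_o = sum((1.0 if a != b else 0.0) / (m - 1) for a, b, m in pairs_o) / n
    vals = [v for v, _ in all_values]
    d_e = sum(
        1.0 for a, b in itertools.permutations(vals, 2) if a != b
    ) / (n * (n - 1))
    return 1 - d_o / d_e if d_e else 1.0


class TestGridResponses:
    def test_press_at_zero_marks_beat_zero(self):
        grid = behavior.grid_responses([0.0], 60.0, 10)
        assert grid.marks[0] == 1 and grid.marks.sum() == 1

    def test_same_beat_presses_collapse(self):
        grid = behavior.grid_responses([1.0, 1.1], 60.0, 10)
        assert grid.marks[1] == 1 and grid.marks.sum() == 1

    def test_index_arithmetic_at_74_4_bpm(self):
        grid = behavior.grid_responses([6.3], 74.4, 20)
        assert grid.marks[7] == 1  # floor(6.3 * 1.24) = 7

    def test_out_of_span_presses_dropped(self):
        grid = behavior.grid_responses([-1.0, 100.0, 2.0], 60.0, 10)
        assert grid.marks.sum() == 1

    def test_nonpositive_tempo_raises(self):
        with pytest.raises(ValueError):
            behavior.grid_responses([1.0], 0.0, 10)


class TestFScore:
    def test_perfect_detection(self):
        marks = np.zeros(32, dtype=int)
        truth = [8, 16, 24]
        for b in truth:
            marks[b] = 1
        rep = behavior.f_score(ResponseGrid(marks), truth)
        assert (rep.precision, rep.recall, rep.f_score) == (1.0, 1.0, 1.0)

    def test_no_marks_gives_zero_f(self):
        rep = behavior.f_score(ResponseGrid(np.zeros(32, dtype=int)), [8, 16, 24])
        assert rep.f_score == 0.0 and rep.fn == 3

    def test_hand_worked_example(self):
        """truths {8,16,24}, marks {8,15,30}: TP=2, FP=1, FN=1, F=2/3."""
        marks = np.zeros(32, dtype=int)
        for m in (8, 15, 30):
            marks[m] = 1
        rep = behavior.f_score(ResponseGrid(marks), [8, 16, 24])
        assert (rep.tp, rep.fp, rep.fn) == (2, 1, 1)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.f_score == pytest.approx(2 / 3)

    def test_one_mark_cannot_satisfy_two_boundaries(self):
        marks = np.zeros(12, dtype=int)
        marks[5] = 1
        rep = behavior.f_score(ResponseGrid(marks), [4, 6])
        assert rep.tp == 1 and rep.fn == 1

    def test_counts_partition_marks_and_truths(self, rng):
        for _ in range(20):
            marks = (rng.random(40) < 0.2).astype(int)
            truth = sorted(rng.choice(np.arange(3, 38), 5, replace=False).tolist())
            rep = behavior.f_score(ResponseGrid(marks), truth)
            assert rep.tp + rep.fn == len(truth)
            assert rep.tp + rep.fp == marks.sum()

    def test_converting_fp_to_tp_never_lowers_f(self):
        # enumerate small grids: adding a hit near an unmatched truth
        base = np.zeros(16, dtype=int)
        base[[1, 9]] = 1  # one FP (1), one TP (9)
        rep0 = behavior.f_score(ResponseGrid(base.copy()), [9, 13])
        moved = np.zeros(16, dtype=int)
        moved[[13, 9]] = 1  # FP moved onto the open truth
        rep1 = behavior.f_score(ResponseGrid(moved), [9, 13])
        assert rep1.f_score >= rep0.f_score

    def test_window_below_one_raises(self):
        with pytest.raises(ValueError):
            behavior.f_score(ResponseGrid(np.zeros(8, dtype=int)), [4], window_beats=0)


class TestShuffledBaseline:
    def test_empty_marks_score_zero(self):
        rep = behavior.shuffled_baseline(
            ResponseGrid(np.zeros(32, dtype=int)), [8, 16, 24]
        )
        assert rep.f_score == 0.0

    def test_missing_pseudo_boundaries_raise(self):
        with pytest.raises(ValueError):
            behavior.shuffled_baseline(ResponseGrid(np.zeros(8, dtype=int)), [])

    def test_random_marks_match_closed_form_chance_f(self):
        rng = np.random.default_rng(0)
        total_beats, density = 64, 0.15
        truth = [8, 16, 24, 32, 40, 48, 56]
        fs = []
        for _ in range(3000):
            marks = (rng.random(total_beats) < density).astype(int)
            fs.append(behavior.shuffled_baseline(ResponseGrid(marks), truth).f_score)
        expected = behavior.chance_f_score(density, len(truth), total_beats)
        assert np.mean(fs) == pytest.approx(expected, abs=0.02)

    def test_saturated_marks_have_full_recall(self):
        truth = [8, 16, 24]
        rep = behavior.shuffled_baseline(ResponseGrid(np.ones(32, dtype=int)), truth)
        assert rep.recall == 1.0
        assert rep.precision == pytest.approx(len(truth) / 32)


class TestKrippendorffAlpha:
    def test_identical_raters_agree_perfectly(self):
        r = np.tile((np.arange(10) % 2), (2, 1)).astype(float)
        assert behavior.krippendorff_alpha(r) == pytest.approx(1.0)

    def test_worked_example_minus_075(self):
        r = np.array([[1, 0, 1, 0], [0, 1, 0, 1]], dtype=float)
        assert behavior.krippendorff_alpha(r) == pytest.approx(-0.75)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            r = rng.integers(0, 2, size=(4, 12)).astype(float)
            r[rng.random(r.shape) < 0.15] = np.nan
            cols_ok = np.sum(np.isfinite(r), axis=0) >= 2
            if not cols_ok.any() or len(np.unique(r[np.isfinite(r)])) < 2:
                continue
            assert behavior.krippendorff_alpha(r) == pytest.approx(
                brute_force_alpha(r), abs=1e-12
            )

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(1)
        r = rng.integers(0, 2, size=(20, 4000)).astype(float)
        assert behavior.krippendorff_alpha(r) == pytest.approx(0.0, abs=0.05)

    def test_no_pairable_values_raise(self):
        r = np.full((2, 3), np.nan)
        r[0, 0] = 1.0
        with pytest.raises(ValueError):
            behavior.krippendorff_alpha(r)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_unit_order_exchangeability(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.integers(0, 2, size=(3, 10)).astype(float)
        if len(np.unique(r)) < 2:
            return
        perm = rng.permutation(10)
        assert behavior.krippendorff_alpha(r) == pytest.approx(
            behavior.krippendorff_alpha(r[:, perm])
        )


class TestDetectionRate:
    def test_all_hit_and_all_miss(self):
        truth = [8, 16, 24]
        hit = np.zeros(32, dtype=int)
        hit[truth] = 1
        grids = [ResponseGrid(hit.copy()) for _ in range(5)]
        assert np.allclose(behavior.detection_rate(grids, truth), 1.0)
        silent = [ResponseGrid(np.zeros(32, dtype=int)) for _ in range(5)]
        assert np.allclose(behavior.detection_rate(silent, truth), 0.0)

    def test_rate_matches_binomial_simulation(self, rng):
        truth = list(range(4, 400, 4))
        grids = []
        for s in range(10):
            marks = np.zeros(400, dtype=int)
            for b in truth:
                if rng.random() < 0.8:
                    marks[b] = 1
            grids.append(ResponseGrid(marks))
        rates = behavior.detection_rate(grids, truth)
        assert np.mean(rates) == pytest.approx(0.8, abs=0.04)

    def test_empty_subject_set_raises(self):
        with pytest.raises(ValueError):
            behavior.detection_rate([], [8])


class TestResponseOffsets:
    def test_exact_presses_have_zero_offset(self):
        truths = [6.45, 12.9, 19.35]
        assert behavior.response_offsets(truths, truths, 74.4) == pytest.approx(0.0)

    def test_uniform_shift_recovered(self):
        truths = np.array([6.45, 12.9, 19.35])
        assert behavior.response_offsets(truths + 0.1, truths, 74.4) == pytest.approx(
            0.1, abs=1e-9
        )

    def test_jittered_mean_offset(self, rng):
        truths = np.arange(1, 1001, dtype=float) * 4.0
        presses = truths + rng.normal(-0.02, 0.05, len(truths))
        est = behavior.response_offsets(presses, truths, 74.4)
        assert est == pytest.approx(-0.02, abs=0.005)

    def test_no_matches_raise(self):
        with pytest.raises(ValueError):
            behavior.response_offsets([100.0], [1.0], 74.4)
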