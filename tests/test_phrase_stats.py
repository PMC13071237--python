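"""Boundary-locked TRF marker, permutation nulls, and cluster inference."""

import numpy as np
import pytest

from phrasetrack import eeg_sim, melody, phrase_stats, trf
from phrasetrack.spectral import PowerEnvelope

LAG = 1.2  # s; covers the +-0.806 s RMS window at 74.4 bpm


@pytest.fixture(scope="module")
def seq():
    s = melody.generate_phrase_structure("irregular", 10, 74.4, 3)
    return melody.render_melody(s, seed=3, melody_id="m")


PAD_S = 2.0  # post-roll, as in epoched data; keeps boundaries off the lag edge


@pytest.fixture(scope="module")
def preds(seq):
    n = int(round((seq.duration_s + PAD_S) * 100))
    return phrase_stats.build_predictors(seq, n)


def make_pe(seq, amp, latency=0.05, width=0.2, seed=0, freq=2.48):
    """1/f noise plus boundary-locked Gaussian bumps in the power envelope."""
    n = int(round((seq.duration_s + PAD_S) * 100))
    t = np.arange(n) / 100
    vals = eeg_sim.one_over_f_noise(np.random.default_rng(seed), n)
    for b in seq.boundaries_s:
        vals += amp * np.exp(-0.5 * ((t - (b + latency)) / width) ** 2)
    return PowerEnvelope(freq, vals, 100, True, 0.0)


class TestBuildPredictors:
    def test_boundary_train_has_one_impulse_per_boundary(self, seq, preds):
        assert np.count_nonzero(preds.boundary_train) == len(seq.boundaries_beats)

    def test_nonzero_entries_are_zero_mean(self, preds):
        for train in (preds.duration_train, preds.frequency_train):
            nz = train[np.abs(train) > 0]
            # z-scored amplitudes over notes; collisions are absent for
            # monophonic input so the nonzero mean is the note mean
            assert abs(np.mean(nz)) <= 1e-8

    def test_equal_durations_give_zero_train(self):
        notes = tuple(melody.NoteEvent(i * 1.0, 1.0, 60 + i % 3) for i in range(8))
        s = melody.NoteSequence(
            notes, melody.PhraseStructure((8,), 74.4), (8.0,)
        )
        p = phrase_stats.build_predictors(s, 700)
        assert np.allclose(p.duration_train, 0.0)

    def test_boundary_outside_span_raises(self, seq):
        with pytest.raises(ValueError):
            phrase_stats.build_predictors(seq, 100)


class TestSummaryIndices:
    def test_rms_of_zero_profile(self):
        lags = np.linspace(-LAG, LAG, 241)
        assert phrase_stats.rms_modulation(np.zeros(241), lags) == 0.0

    def test_rms_of_constant_is_its_magnitude(self):
        lags = np.linspace(-LAG, LAG, 241)
        assert phrase_stats.rms_modulation(np.full(241, -0.7), lags) == pytest.approx(0.7)

    def test_rms_of_unit_sine_is_inverse_sqrt2(self):
        beat_s = 60 / 74.4
        lags = np.arange(-120, 121) / 100.0
        w = np.sin(2 * np.pi * np.arange(241) / (2 * beat_s * 100))
        # one full period spanning the two-beat window
        rms = phrase_stats.rms_modulation(w, lags)
        assert rms == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_window_outside_axis_raises(self):
        lags = np.linspace(-0.1, 0.1, 21)
        with pytest.raises(ValueError):
            phrase_stats.rms_modulation(np.zeros(21), lags)

    def test_peak_latency_of_centered_bump(self):
        lags = np.arange(-120, 121) / 100.0
        w = np.exp(-0.5 * ((lags - 0.1) / 0.05) ** 2)
        assert phrase_stats.peak_latency(w, lags) == pytest.approx(0.1, abs=0.01)

    def test_twin_peaks_tie_resolves_to_negative(self):
        lags = np.arange(-120, 121) / 100.0
        w = np.zeros(241)
        w[np.argmin(np.abs(lags + 0.2))] = 1.0
        w[np.argmin(np.abs(lags - 0.2))] = 1.0
        assert phrase_stats.peak_latency(w, lags) == pytest.approx(-0.2)

    def test_flat_profile_peaks_at_zero_lag(self):
        lags = np.arange(-120, 121) / 100.0
        assert phrase_stats.peak_latency(np.ones(241), lags) == pytest.approx(0.0)

    def test_all_nan_raises(self):
        lags = np.linspace(-LAG, LAG, 11)
        with pytest.raises(ValueError):
            phrase_stats.peak_latency(np.full(11, np.nan), lags)


class TestBoundaryTRF:
    def test_profile_matches_direct_trf_fit(self, seq, preds):
        pe = make_pe(seq, 2.0)
        prof = phrase_stats.boundary_trf(pe, preds, 1.0, -LAG, LAG)
        direct = trf.fit_trf(preds.features(), pe.values, 100, -LAG, LAG, 1.0)
        assert np.max(np.abs(prof.weights - direct.weights[0])) < 1e-10

    def test_injected_bump_peak_recovered_within_30ms(self, seq, preds):
        pe = make_pe(seq, 3.0, latency=0.05, width=0.15)
        prof = phrase_stats.boundary_trf(pe, preds, 1.0, -LAG, LAG)
        assert abs(prof.peak_latency_s - 0.05) <= 0.03

    def test_null_profile_stays_below_permutation_threshold(self, seq, preds):
        pe = make_pe(seq, 0.0, seed=9)
        prof = phrase_stats.boundary_trf(pe, preds, 1.0, -LAG, LAG)
        null = phrase_stats.permutation_null(pe, preds, 1.0, 50, 0, -LAG, LAG)
        assert prof.r2 <= null.threshold_95

    def test_covariate_only_signal_absorbed(self, seq):
        """Bumps at long notes (duration-cued) do not masquerade as
        boundary responses once the covariates partial them out."""
        n = int(round((seq.duration_s + PAD_S) * 100))
        preds = phrase_stats.build_predictors(seq, n)
        t = np.arange(n) / 100
        vals = eeg_sim.one_over_f_noise(np.random.default_rng(2), n)
        beat_s = 60 / 74.4
        for note in seq.notes:
            if note.duration_beats >= 2.0:  # every long note, boundary or not
                onset = note.onset_beats * beat_s
                vals += 2.0 * np.exp(-0.5 * ((t - onset - 0.05) / 0.15) ** 2)
        pe = PowerEnvelope(2.48, vals, 100, True, 0.0)
        null = phrase_stats.permutation_null(pe, preds, 1.0, 50, 1, -LAG, LAG)
        prof = phrase_stats.boundary_trf(pe, preds, 1.0, -LAG, LAG)
        # duration covariate absorbs the long-note response: the boundary
        # predictor adds little over the permuted-onset null
        assert prof.r2 <= null.threshold_95 * 1.05


class TestPermutationNull:
    def test_injected_modulation_exceeds_threshold(self, seq, preds):
        pe = make_pe(seq, 2.0)
        prof = phrase_stats.boundary_trf(pe, preds, 1.0, -LAG, LAG)
        null = phrase_stats.permutation_null(pe, preds, 1.0, 100, 0, -LAG, LAG)
        assert prof.r2 > null.threshold_95
        assert prof.rms > null.rms_threshold_95

    def test_single_permutation_threshold_is_that_sample(self, seq, preds):
        pe = make_pe(seq, 1.0)
        null = phrase_stats.permutation_null(pe, preds, 1.0, 1, 0, -LAG, LAG)
        assert null.threshold_95 == pytest.approx(null.statistic_samples[0])

    def test_deterministic_per_seed(self, seq, preds):
        pe = make_pe(seq, 1.0)
        a = phrase_stats.permutation_null(pe, preds, 1.0, 10, 5, -LAG, LAG)
        b = phrase_stats.permutation_null(pe, preds, 1.0, 10, 5, -LAG, LAG)
        assert np.array_equal(a.statistic_samples, b.statistic_samples)

    def test_threshold_invariant_to_sample_order(self, seq, preds):
        pe = make_pe(seq, 1.0)
        null = phrase_stats.permutation_null(pe, preds, 1.0, 20, 0, -LAG, LAG)
        shuffled = np.random.default_rng(0).permutation(null.statistic_samples)
        assert np.percentile(shuffled, 95) == pytest.approx(null.threshold_95)

    def test_too_few_boundaries_raise(self):
        s = melody.generate_phrase_structure("regular", 1, 74.4, 0)
        one = melody.render_melody(s, seed=0)
        n = int(round((one.duration_s + PAD_S) * 100))
        p = phrase_stats.build_predictors(one, n)
        pe = make_pe(one, 1.0)
        with pytest.raises(ValueError):
            phrase_stats.permutation_null(pe, p, 1.0, 10, 0, -LAG, LAG)


class TestControls:
    def test_random_onsets_weaker_than_true_boundaries(self, seq, preds):
        pe = make_pe(seq, 2.5)
        true_prof = phrase_stats.boundary_trf(pe, preds, 1.0, -LAG, LAG)
        ctrl = phrase_stats.random_onset_control(pe, preds, 1.0, 0, -LAG, LAG)
        assert ctrl.rms < true_prof.rms
        assert ctrl.r2 < true_prof.r2

    def test_random_onsets_equivalent_under_null(self, seq, preds):
        diffs = []
        for s in range(30):
            pe = make_pe(seq, 0.0, seed=100 + s)
            true_prof = phrase_stats.boundary_trf(pe, preds, 1.0, -LAG, LAG)
            ctrl = phrase_stats.random_onset_control(pe, preds, 1.0, s, -LAG, LAG)
            diffs.append(true_prof.rms - ctrl.rms)
        ci = 1.96 * np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) <= ci + 1e-12

    def test_frequency_specificity_of_injected_modulation(self, seq, preds):
        pe_248 = make_pe(seq, 2.0, freq=2.48, seed=4)
        pe_1 = make_pe(seq, 0.0, freq=1.0, seed=5)
        main = phrase_stats.boundary_trf(pe_248, preds, 1.0, -LAG, LAG)
        ctrl = phrase_stats.low_freq_control(pe_1, preds, 1.0, -LAG, LAG)
        assert ctrl.rms < main.rms
        # and the ordering reverses when the modulation lives at 1 Hz
        pe_248b = make_pe(seq, 0.0, freq=2.48, seed=6)
        pe_1b = make_pe(seq, 2.0, freq=1.0, seed=7)
        main_b = phrase_stats.boundary_trf(pe_248b, preds, 1.0, -LAG, LAG)
        ctrl_b = phrase_stats.low_freq_control(pe_1b, preds, 1.0, -LAG, LAG)
        assert ctrl_b.rms > main_b.rms


class TestNestedModels:
    def test_full_model_r2_at_least_covariates_only(self, seq, preds):
        for s in range(5):
            pe = make_pe(seq, [0.0, 1.0, 2.0, 0.5, 1.5][s], seed=20 + s)
            model = phrase_stats.BoundaryModel(pe, preds, 1e-3, -LAG, LAG)
            _, r2_full, _ = model.fit()
            assert r2_full >= model.fit_covariates_only() - 1e-9


class TestClusterTest:
    def _profiles(self, rng, n_subjects=20, n_lags=121, effect=None):
        data = rng.standard_normal((n_subjects, n_lags))
        if effect is not None:
            lo, hi, amp = effect
            data[:, lo:hi] += amp
        return data, np.linspace(-0.6, 0.6, n_lags)

    def test_common_deflection_found_as_significant_cluster(self):
        rng = np.random.default_rng(0)
        lags = np.linspace(-0.6, 0.6, 121)
        i0 = np.argmin(np.abs(lags + 0.01))
        i1 = np.argmin(np.abs(lags - 0.05))
        data, lags = self._profiles(rng, effect=(i0, i1 + 1, 1.2))
        clusters = phrase_stats.cluster_test(data, lags, 500, seed=1)
        sig = [c for c in clusters if c[3] < 0.05]
        assert sig
        start, end = sig[0][0], sig[0][1]
        assert start <= 0.05 and end >= -0.01  # overlaps the injected window

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        data, lags = self._profiles(rng, effect=(40, 60, 1.0))
        up = phrase_stats.cluster_test(data, lags, 300, seed=3)
        down = phrase_stats.cluster_test(-data, lags, 300, seed=3)
        assert len(up) == len(down)
        for a, b in zip(up, down):
            assert a[0] == b[0] and a[1] == b[1]
            assert a[2] == pytest.approx(-b[2])
            assert a[3] == pytest.approx(b[3])

    def test_too_few_subjects_raise(self):
        rng = np.random.default_rng(4)
        data, lags = self._profiles(rng, n_subjects=4)
        with pytest.raises(ValueError):
            phrase_stats.cluster_test(data, lags, 100, seed=0)

    def test_accepts_boundary_profiles(self, seq, preds):
        profs = []
        for s in range(6):
            pe = make_pe(seq, 2.0, seed=40 + s)
            profs.append(
                phrase_stats.boundary_trf(pe, preds, 1.0, -LAG, LAG, f"sub{s}")
            )
        clusters = phrase_stats.cluster_test(profs, n_perm=100, seed=5)
        assert isinstance(clusters, list)


def test_rms_monotone_in_modulation_amplitude(seq, preds):
    """Recovered RMS tracks the injected boundary-burst amplitude."""
    amps = [0.0, 0.5, 1.0, 2.0, 4.0]
    rms = []
    for a in amps:
        vals = [
            phrase_stats.boundary_trf(
                make_pe(seq, a, seed=60 + r), preds, 1.0, -LAG, LAG
            ).rms
            for r in range(3)
        ]
        rms.append(np.mean(vals))
    assert np.all(np.diff(rms) > 0)
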