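"""End-to-end orchestration: simulate -> preprocess -> markers -> report.

A run is fully determined by a :class:`RunConfig` (YAML-serializable).
Stimulus, EEG, behavioral, and permutation randomness flow from the
single run seed through named substreams, so re-running any stage on
unchanged inputs reproduces its outputs bit-for-bit.

Stage functions are importable individually (the ``analysis/`` scripts
are thin drivers over them); :func:`run_simulation` materializes a
dataset directory (MIDI + boundary sidecars, WAV, EEG containers,
press logs, ground truth) and :func:`run_analysis` executes the
preprocessing -> envelope TRF + coherence -> narrow-band power ->
boundary TRF + controls + permutation null + cluster tests ->
behavioral scoring chain and serializes a report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from . import acoustics, behavior, eeg_sim, melody, midi_io, phrase_stats, preprocess, spectral, trf

logger = logging.getLogger(__name__)

CONDITIONS = ("regular", "irregular", "shuffled")


@dataclass
class RunConfig:
    """All tunable parameters of a simulated experiment and its analysis."""

    seed: int = 0
    tempo_bpm: float = 74.4
    # stimuli
    melodies_per_condition: int = 2
    n_phrases: dict = field(default_factory=lambda: {"regular": 5, "irregular": 4})
    cue_duration_factor: float = 2.0
    cue_interval_semitones: float = 5.0
    distractor_rate: float = 0.15
    # EEG simulation
    n_subjects: int = 4
    n_channels: int = 16
    eeg_fs: int = 500
    snr_db: float = -3.0
    mod_amplitudes: dict = field(
        default_factory=lambda: {"regular": 1.0, "irregular": 0.7, "shuffled": 0.0}
    )
    mod_latency_s: float = 0.05
    mod_width_s: float = 0.3
    mod_freq_hz: float = 2.48
    shared_fraction: float = 1.0
    n_repeats: int = 2  # presentations per melody, averaged at the epoch level
    # behavior simulation
    hit_rates: dict = field(
        default_factory=lambda: {"regular": 0.8, "irregular": 0.75, "shuffled": 0.15}
    )
    false_alarm_rate_per_min: float = 2.0
    timing_jitter_s: float = 0.25
    # preprocessing
    filter_lo_hz: float = 0.5
    filter_hi_hz: float = 35.0
    filter_order: int = 5
    epoch_pre_s: float = 3.0
    epoch_post_s: float = 2.0
    n_pcs_per_subject: int = 10
    n_shared: int = 5
    # envelope TRF
    env_lag_min_s: float = -0.2
    env_lag_max_s: float = 0.5
    env_stats_lag_s: tuple = (-0.1, 0.4)
    env_lambda: float = 1.0
    # coherence
    cacoh_nperseg: int = 1024
    cacoh_noverlap: int = 512
    # boundary TRF
    boundary_lag_s: float = 3.0
    boundary_lambda: float = 1.0
    rms_window_beats: tuple = (-1.0, 1.0)
    n_permutations: int = 100
    n_cluster_permutations: int = 1000
    window_beats: int = 3

    def __post_init__(self):
        if self.tempo_bpm <= 0:
            raise ValueError("invalid config: tempo_bpm must be positive")
        if self.eeg_fs <= 0:
            raise ValueError("invalid config: eeg_fs must be positive")
        if self.melodies_per_condition < 1:
            raise ValueError("invalid config: melodies_per_condition must be >= 1")
        for cond in ("regular", "irregular"):
            if cond not in self.n_phrases:
                raise ValueError(f"invalid config: n_phrases missing {cond!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"invalid config: unknown field(s) {sorted(unknown)}")
        for key in ("rms_window_beats", "env_stats_lag_s"):
            if key in obj:
                obj[key] = tuple(obj[key])
        return cls(**obj)

    def to_yaml(self, path) -> None:
        obj = dataclasses.asdict(self)
        obj["rms_window_beats"] = list(self.rms_window_beats)
        obj["env_stats_lag_s"] = list(self.env_stats_lag_s)
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))

    def substream(self, name: str) -> np.random.Generator:
        """Named child RNG derived from the run seed."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:4], "big"))

    def subseed(self, name: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big")


def build_stimuli(cfg: RunConfig):
    """Melodies for all three conditions with audio and envelopes.

    Returns a list of ``(NoteSequence, Envelope)``; shuffled stimuli are
    half-beat shuffles of freshly drawn source melodies (alternating
    regular/irregular sources), carrying the source boundaries as
    pseudo-boundaries.
    """
    rng = cfg.substream("stimuli")
    stimuli = []
    for cond in ("regular", "irregular"):
        for m in range(cfg.melodies_per_condition):
            structure = melody.generate_phrase_structure(
                cond, cfg.n_phrases[cond], cfg.tempo_bpm, rng
            )
            seq = melody.render_melody(
                structure,
                cfg.cue_duration_factor,
                cfg.cue_interval_semitones,
                cfg.distractor_rate,
                seed=rng,
                melody_id=f"{cond}-{m:02d}",
            )
            stimuli.append(seq)
    for m in range(cfg.melodies_per_condition):
        source_cond = ("regular", "irregular")[m % 2]
        structure = melody.generate_phrase_structure(
            source_cond, cfg.n_phrases[source_cond], cfg.tempo_bpm, rng
        )
        src = melody.render_melody(
            structure,
            cfg.cue_duration_factor,
            cfg.cue_interval_semitones,
            cfg.distractor_rate,
            seed=rng,
            melody_id=f"shuffled-{m:02d}-src",
        )
        shuf = melody.shuffle_melody(src, seed=rng)
        shuf = dataclasses.replace(shuf, melody_id=f"shuffled-{m:02d}")
        stimuli.append(shuf)

    out = []
    for seq in stimuli:
        wav = acoustics.synthesize_audio(seq)
        env = acoustics.gammatone_envelope(wav, stimulus_id=seq.melody_id)
        out.append((seq, env))
    return out


def _condition_of(seq: melody.NoteSequence) -> str:
    return seq.structure.condition if seq.structure is not None else "regular"


def simulate_eeg(cfg: RunConfig, stimuli):
    """Recordings for every (subject, melody, repeat); returns (recs, truth).

    ``recs[(subject_id, melody_id, repeat)]`` is an EEGRecording; the
    modulation amplitude follows the per-condition map.
    """
    recordings = {}
    amp_by_melody = {}
    bounds_by_melody = {}
    base = eeg_sim.SimulationConfig(
        n_subjects=cfg.n_subjects,
        n_channels=cfg.n_channels,
        fs=cfg.eeg_fs,
        mod_latency_s=cfg.mod_latency_s,
        mod_width_s=cfg.mod_width_s,
        mod_freq_hz=cfg.mod_freq_hz,
        shared_fraction=cfg.shared_fraction,
        snr_db=cfg.snr_db,
        seed=cfg.seed,
    )
    for seq, env in stimuli:
        cond = _condition_of(seq)
        amp = cfg.mod_amplitudes.get(cond, 0.0)
        boundaries = np.asarray(seq.boundaries_s)
        amp_by_melody[seq.melody_id] = amp
        bounds_by_melody[seq.melody_id] = boundaries
        for rep in range(cfg.n_repeats):
            sim_cfg = dataclasses.replace(
                base, mod_amplitude=amp, seed=cfg.subseed(f"eeg:{seq.melody_id}:{rep}")
            )
            for s in range(cfg.n_subjects):
                rec = eeg_sim.simulate_subject(
                    env, boundaries, sim_cfg, s,
                    pre_s=cfg.epoch_pre_s + 1.0, post_s=cfg.epoch_post_s + 1.0,
                    stimulus_id=seq.melody_id,
                )
                recordings[(rec.subject_id, seq.melody_id, rep)] = rec
    truth = eeg_sim.GroundTruth(
        base.kernel, cfg.eeg_fs, amp_by_melody, cfg.mod_latency_s, cfg.mod_width_s,
        cfg.mod_freq_hz, bounds_by_melody, cfg.snr_db, cfg.seed,
    )
    return recordings, truth


def simulate_presses(cfg: RunConfig, stimuli) -> pd.DataFrame:
    """Press logs: columns subject, melody, condition, press_time_s."""
    rows = []
    for seq, _ in stimuli:
        cond = _condition_of(seq)
        hit = cfg.hit_rates.get(cond, 0.0)
        for s in range(cfg.n_subjects):
            rng = cfg.substream(f"behavior:{seq.melody_id}:{s}")
            presses = eeg_sim.simulate_behavior(
                seq, hit, cfg.false_alarm_rate_per_min, cfg.timing_jitter_s, rng
            )
            rows.extend(
                {
                    "subject": f"sub-{s:02d}",
                    "melody": seq.melody_id,
                    "condition": cond,
                    "press_time_s": t,
                }
                for t in presses
            )
    return pd.DataFrame(rows, columns=["subject", "melody", "condition", "press_time_s"])


def run_simulation(cfg: RunConfig, out_dir) -> Path:
    """Materialize the full synthetic dataset on disk."""
    out = Path(out_dir)
    (out / "stimuli").mkdir(parents=True, exist_ok=True)
    (out / "eeg").mkdir(exist_ok=True)
    t0 = time.time()
    stimuli = build_stimuli(cfg)
    manifest = {"melodies": [], "config": dataclasses.asdict(cfg)}
    manifest["config"]["rms_window_beats"] = list(cfg.rms_window_beats)
    manifest["config"]["env_stats_lag_s"] = list(cfg.env_stats_lag_s)
    for seq, env in stimuli:
        base = out / "stimuli" / seq.melody_id
        midi_io.write_midi(seq, f"{base}.mid")
        midi_io.write_boundary_sidecar(seq, f"{base}.boundaries.csv")
        wav = acoustics.synthesize_audio(seq)
        acoustics.write_wav(wav, f"{base}.wav")
        np.savetxt(
            f"{base}.envelope.csv",
            np.column_stack([np.arange(len(env.values)) / env.fs, env.values]),
            delimiter=",",
            header="time_s,value",
            comments="",
        )
        manifest["melodies"].append(
            {
                "melody_id": seq.melody_id,
                "condition": _condition_of(seq),
                "n_boundaries": len(seq.boundaries_beats),
                "duration_s": seq.duration_s,
                "pseudo_boundaries": seq.pseudo_boundaries,
                "note_table": melody.note_table(seq).tolist(),
                "boundaries_beats": list(seq.boundaries_beats),
                "tempo_bpm": seq.structure.tempo_bpm,
                "phrase_lengths": list(seq.structure.phrase_lengths),
            }
        )
    recs, truth = simulate_eeg(cfg, stimuli)
    for (sub, mel, rep), rec in recs.items():
        eeg_sim.save_recording(rec, out / "eeg" / f"{sub}_{mel}_rep{rep}")
    truth.to_json(out / "ground_truth.json")
    simulate_presses(cfg, stimuli).to_csv(out / "presses.csv", index=False)
    cfg.to_yaml(out / "config.yaml")
    checksum = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    manifest["checksum"] = checksum
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("simulation written to %s in %.1f s", out, time.time() - t0)
    return out


def load_stimuli(dataset_dir) -> list:
    """Rebuild (NoteSequence, Envelope) pairs from a dataset directory."""
    out = []
    manifest = json.loads((Path(dataset_dir) / "manifest.json").read_text())
    for entry in manifest["melodies"]:
        cond = entry["condition"]
        structure = melody.PhraseStructure(
            tuple(entry["phrase_lengths"]), entry["tempo_bpm"], cond
        )
        notes = tuple(
            melody.NoteEvent(o, d, p) for o, d, p in entry["note_table"]
        )
        seq = melody.NoteSequence(
            notes, structure, tuple(entry["boundaries_beats"]),
            entry["pseudo_boundaries"], entry["melody_id"],
        )
        env_tab = np.loadtxt(
            Path(dataset_dir) / "stimuli" / f"{seq.melody_id}.envelope.csv",
            delimiter=",", skiprows=1,
        )
        env = acoustics.Envelope(env_tab[:, 1], 100, seq.melody_id)
        out.append((seq, env))
    return out


def preprocess_melody(cfg: RunConfig, recs: dict, seq, env):
    """Band-pass, epoch, re-reference, repeat-average, and MCCA one melody.

    Returns one DenoisedComponent per subject at the EEG rate.
    """
    epochs = []
    for s in range(cfg.n_subjects):
        sub = f"sub-{s:02d}"
        rep_epochs = []
        for rep in range(cfg.n_repeats):
            rec = recs[(sub, seq.melody_id, rep)]
            filtered = preprocess.bandpass(rec, cfg.filter_lo_hz, cfg.filter_hi_hz, cfg.filter_order)
            onset_s = rec.events[0][1] / rec.fs
            ep = preprocess.epoch(
                filtered, onset_s, seq.duration_s, cfg.epoch_pre_s, cfg.epoch_post_s,
                seq.melody_id,
            )
            rep_epochs.append(preprocess.rereference_average(ep))
        avg = rep_epochs[0]
        if len(rep_epochs) > 1:
            avg = dataclasses.replace(
                avg, data=np.mean([e.data for e in rep_epochs], axis=0)
            )
        epochs.append(avg)
    # envelope resampled onto the epoch grid for the sign convention
    n_ep = epochs[0].data.shape[1]
    env_eeg = sps.resample_poly(env.values, cfg.eeg_fs // 100, 1)
    aligned = np.zeros(n_ep)
    i0 = int(round(cfg.epoch_pre_s * cfg.eeg_fs))
    n_env = min(len(env_eeg), n_ep - i0)
    aligned[i0 : i0 + n_env] = env_eeg[:n_env]
    return preprocess.mcca_denoise(epochs, cfg.n_pcs_per_subject, cfg.n_shared, aligned)


def component_power(cfg: RunConfig, comp: preprocess.DenoisedComponent, freqs=(2.48, 1.0)):
    """Morlet power envelopes of a component, at 100 Hz, baseline-corrected."""
    down = cfg.eeg_fs // 100
    series = sps.resample_poly(comp.series, 1, down)
    powers = spectral.morlet_power(series, freqs, fs=100, t0_s=-cfg.epoch_pre_s)
    return {f: spectral.baseline_correct(pe) for f, pe in powers.items()}


@dataclass
class RunReport:
    rms_table: pd.DataFrame  # subject x condition RMS / peak latency / R^2
    cacoh_table: pd.DataFrame  # beat and double-beat coherence per subject x melody
    cluster_table: pd.DataFrame
    behavior_table: pd.DataFrame
    agreement_table: pd.DataFrame
    null_thresholds: dict
    recovery: dict  # ground-truth recovery summary
    config: dict
    version: str = "0.1.0"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rms_table.to_csv(out / "rms_table.csv", index=False)
        self.cacoh_table.to_csv(out / "cacoh_table.csv", index=False)
        self.cluster_table.to_csv(out / "cluster_table.csv", index=False)
        self.behavior_table.to_csv(out / "behavior_table.csv", index=False)
        self.agreement_table.to_csv(out / "agreement_table.csv", index=False)
        summary = {
            "null_thresholds": self.null_thresholds,
            "recovery": self.recovery,
            "config": self.config,
            "version": self.version,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=1, default=float))


def score_behavior(cfg: RunConfig, stimuli, presses: pd.DataFrame):
    """Behavioral tables: per-subject scores and per-condition agreement."""
    rows = []
    grids_by_cond: dict = {c: {} for c in CONDITIONS}
    for seq, _ in stimuli:
        cond = _condition_of(seq)
        total_beats = int(round(seq.total_beats))
        truth = np.asarray(seq.boundaries_beats)
        tempo = seq.structure.tempo_bpm
        melody_grids = []
        for s in range(cfg.n_subjects):
            sub = f"sub-{s:02d}"
            times = presses.query("subject == @sub and melody == @seq.melody_id")[
                "press_time_s"
            ].to_numpy()
            grid = behavior.grid_responses(times, tempo, total_beats, sub, seq.melody_id)
            melody_grids.append(grid)
            report = (
                behavior.shuffled_baseline(grid, truth, cfg.window_beats)
                if seq.pseudo_boundaries
                else behavior.f_score(grid, truth, cfg.window_beats)
            )
            try:
                offset = behavior.response_offsets(
                    times, truth * 60.0 / tempo, tempo, cfg.window_beats
                )
            except ValueError:
                offset = np.nan
            rows.append(
                {
                    "subject": sub,
                    "melody": seq.melody_id,
                    "condition": cond,
                    "tp": report.tp,
                    "fp": report.fp,
                    "fn": report.fn,
                    "precision": report.precision,
                    "recall": report.recall,
                    "f_score": report.f_score,
                    "mean_offset_s": offset,
                }
            )
        grids_by_cond[cond][seq.melody_id] = melody_grids
    behavior_table = pd.DataFrame(rows)
    agree_rows = []
    for cond, by_melody in grids_by_cond.items():
        alphas = []
        for mel, grids in by_melody.items():
            mat = np.stack([g.marks for g in grids]).astype(float)
            try:
                alphas.append(behavior.krippendorff_alpha(mat))
            except ValueError:
                continue
        if alphas:
            agree_rows.append(
                {"condition": cond, "krippendorff_alpha": float(np.mean(alphas))}
            )
    return behavior_table, pd.DataFrame(agree_rows)


def run_analysis(cfg: RunConfig, dataset_dir, out_dir=None) -> RunReport:
    """Execute the full analysis chain on a simulated dataset."""
    dataset_dir = Path(dataset_dir)
    stimuli = load_stimuli(dataset_dir)
    truth = eeg_sim.GroundTruth.from_json(dataset_dir / "ground_truth.json")
    presses = pd.read_csv(dataset_dir / "presses.csv")
    recs = {}
    for seq, _ in stimuli:
        for s in range(cfg.n_subjects):
            sub = f"sub-{s:02d}"
            for rep in range(cfg.n_repeats):
                recs[(sub, seq.melody_id, rep)] = eeg_sim.load_recording(
                    dataset_dir / "eeg" / f"{sub}_{seq.melody_id}_rep{rep}"
                )

    lag = cfg.boundary_lag_s
    rms_rows = []
    cacoh_rows = []
    profiles_by_cond: dict = {c: {} for c in CONDITIONS}
    null_thresholds: dict = {}
    kernel_xcorr = []
    for seq, env in stimuli:
        cond = _condition_of(seq)
        t0 = time.time()
        comps = preprocess_melody(cfg, recs, seq, env)
        down = cfg.eeg_fs // 100
        n100 = len(sps.resample_poly(comps[0].series, 1, down))
        preds = phrase_stats.build_predictors(seq, n100, pre_s=cfg.epoch_pre_s)
        for comp in comps:
            series100 = sps.resample_poly(comp.series, 1, down)
            # envelope TRF + kernel recovery + coherence on the melody span
            i0 = int(round(cfg.epoch_pre_s * 100))
            neural = series100[i0 : i0 + len(env.values)]
            model = trf.fit_trf(
                env.values, neural, 100, cfg.env_lag_min_s, cfg.env_lag_max_s,
                cfg.env_lambda,
            )
            stats_model = model.lag_window(*cfg.env_stats_lag_s)
            k_true = sps.resample_poly(truth.kernel, 1, truth.fs // 100)
            k_est = stats_model.weights[0][stats_model.lag_axis_s >= 0]
            m = min(len(k_true), len(k_est))
            if m > 2 and np.std(k_est[:m]) > 0 and np.std(k_true[:m]) > 0:
                kernel_xcorr.append(
                    float(np.corrcoef(k_est[:m], k_true[:m])[0, 1])
                )
            try:
                spec = spectral.cacoh(
                    neural, env.values, nperseg=cfg.cacoh_nperseg,
                    noverlap=cfg.cacoh_noverlap, stimulus_id=seq.melody_id,
                    subject_id=comp.subject_id,
                )
                beat_val, double_val = spectral.beat_band_values(spec)
            except ValueError:
                beat_val = double_val = np.nan
            cacoh_rows.append(
                {
                    "subject": comp.subject_id,
                    "melody": seq.melody_id,
                    "condition": cond,
                    "cacoh_beat": beat_val,
                    "cacoh_double_beat": double_val,
                }
            )
            powers = component_power(cfg, comp, (cfg.mod_freq_hz, 1.0))
            bm = phrase_stats.BoundaryModel(
                powers[cfg.mod_freq_hz], preds, cfg.boundary_lambda, -lag, lag
            )
            profile = phrase_stats.boundary_trf(
                powers[cfg.mod_freq_hz], preds, cfg.boundary_lambda, -lag, lag,
                comp.subject_id, cond, model=bm,
            )
            control = phrase_stats.low_freq_control(
                powers[1.0], preds, cfg.boundary_lambda, -lag, lag,
                comp.subject_id, cond,
            )
            r2_cov = bm.fit_covariates_only()
            rms_rows.append(
                {
                    "subject": comp.subject_id,
                    "melody": seq.melody_id,
                    "condition": cond,
                    "rms": profile.rms,
                    "peak_latency_s": profile.peak_latency_s,
                    "r2_full": profile.r2,
                    "r2_acoustics_only": r2_cov,
                    "rms_1hz": control.rms,
                    "variance_explained": comp.variance_explained,
                }
            )
            profiles_by_cond[cond].setdefault(comp.subject_id, []).append(profile)
        # permutation null on the subject-averaged power envelope (first
        # melody of each condition keeps the run inside its time budget)
        if cond not in null_thresholds:
            pe_mean = None
            for comp in comps:
                pw = component_power(cfg, comp, (cfg.mod_freq_hz,))[cfg.mod_freq_hz]
                pe_mean = pw.values if pe_mean is None else pe_mean + pw.values
            pe = dataclasses.replace(pw, values=pe_mean / len(comps))
            null = phrase_stats.permutation_null(
                pe, preds, cfg.boundary_lambda, cfg.n_permutations,
                cfg.substream(f"null:{cond}"), -lag, lag,
            )
            obs = phrase_stats.boundary_trf(
                pe, preds, cfg.boundary_lambda, -lag, lag, "group", cond
            )
            null_thresholds[cond] = {
                "r2_threshold_95": float(np.percentile(null.r2_samples, 95)),
                "rms_threshold_95": null.rms_threshold_95,
                "observed_r2": obs.r2,
                "observed_rms": obs.rms,
            }
        logger.info("melody %s analyzed in %.1f s", seq.melody_id, time.time() - t0)

    rms_table = pd.DataFrame(rms_rows)
    cacoh_table = pd.DataFrame(cacoh_rows)

    cluster_rows = []
    for cond in CONDITIONS:
        by_subject = profiles_by_cond[cond]
        if len(by_subject) < 5:
            continue
        mats = []
        for sub, profs in sorted(by_subject.items()):
            mats.append(np.mean([p.weights for p in profs], axis=0))
        clusters = phrase_stats.cluster_test(
            np.stack(mats), profs[0].lag_axis_s, cfg.n_cluster_permutations,
            seed=cfg.substream(f"cluster:{cond}"),
        )
        cluster_rows.extend(
            {"condition": cond, "start_s": a, "end_s": b, "mass": m, "p": p}
            for a, b, m, p in clusters
        )
    cluster_table = pd.DataFrame(
        cluster_rows, columns=["condition", "start_s", "end_s", "mass", "p"]
    )

    behavior_table, agreement_table = score_behavior(cfg, stimuli, presses)

    cond_rms = rms_table.groupby("condition")["rms"].mean()
    recovery = {
        "kernel_correlation_mean": float(np.mean(kernel_xcorr)) if kernel_xcorr else np.nan,
        "rms_by_condition": {c: float(cond_rms.get(c, np.nan)) for c in CONDITIONS},
        "rms_ordering_ok": bool(
            cond_rms.get("regular", np.nan)
            > cond_rms.get("irregular", np.nan)
            > cond_rms.get("shuffled", np.nan)
        ),
        "true_mod_amplitudes": truth.mod_amplitude_by_melody,
    }
    report = RunReport(
        rms_table, cacoh_table, cluster_table, behavior_table, agreement_table,
        null_thresholds, recovery, json.loads(json.dumps(dataclasses.asdict(cfg), default=list)),
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def make_fixtures(out_dir, seed: int = 1234) -> Path:
    """Tiny deterministic dataset (short melodies, 4 subjects) for tests."""
    cfg = RunConfig(
        seed=seed,
        melodies_per_condition=1,
        n_phrases={"regular": 3, "irregular": 2},
        n_subjects=4,
        n_repeats=1,
        n_permutations=20,
        n_cluster_permutations=200,
    )
    return run_simulation(cfg, out_dir)
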