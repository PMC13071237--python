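"""Audio rendering and cochlear envelope extraction.

Note sequences are rendered at 16 kHz with a simple decaying-harmonic
keyboard timbre. The broadband amplitude envelope is extracted with a
32-band gammatone filterbank spanning 50-4000 Hz (ERB-rate spaced
centers, 4th-order filters), per-band analytic-signal magnitudes
averaged across bands, anti-alias filtered and resampled to 100 Hz --
the rate shared by all downstream stimulus predictors and neural
series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .melody import NoteSequence

AUDIO_FS = 16_000
ENVELOPE_FS = 100


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray
    fs: int = AUDIO_FS

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class Envelope:
    """Nonnegative acoustic-envelope series at `fs` (100 Hz by default)."""

    values: np.ndarray
    fs: int = ENVELOPE_FS
    stimulus_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs


def synthesize_audio(
    seq: NoteSequence,
    fs: int = AUDIO_FS,
    n_harmonics: int = 4,
    decay_s: float = 0.6,
    ramp_s: float = 0.010,
) -> Waveform:
    """Render a note sequence as a peak-normalized waveform.

    Each note is a sum of ``n_harmonics`` harmonics with 1/k amplitude
    roll-off and exponential decay (time constant ``decay_s``), gated by
    a 10 ms raised-cosine onset ramp. Notes abut with no silence, so
    the total duration is total beats x 60/tempo.
    """
    if not seq.notes:
        raise ValueError("cannot synthesize an empty note sequence")
    beat_s = seq.structure.beat_s if seq.structure is not None else 60.0 / 74.4
    n_total = int(round(seq.total_beats * beat_s * fs))
    out = np.zeros(n_total)
    for note in seq.notes:
        i0 = int(round(note.onset_beats * beat_s * fs))
        i1 = min(int(round(note.offset_beats * beat_s * fs)), n_total)
        t = np.arange(i1 - i0) / fs
        f0 = 440.0 * 2.0 ** ((note.pitch - 69.0) / 12.0)
        tone = np.zeros_like(t)
        for k in range(1, n_harmonics + 1):
            if k * f0 < fs / 2:
                tone += np.sin(2 * np.pi * k * f0 * t) / k
        tone *= np.exp(-t / decay_s)
        n_ramp = min(int(round(ramp_s * fs)), len(t))
        if n_ramp > 1:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            tone[:n_ramp] *= ramp
        out[i0:i1] += tone
    peak = np.max(np.abs(out))
    if peak > 0:
        out /= peak
    return Waveform(out, fs)


def _erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale."""
    erb = lambda f: 21.4 * np.log10(1 + 0.00437 * f)
    inv = lambda e: (10 ** (e / 21.4) - 1) / 0.00437
    return inv(np.linspace(erb(f_lo), erb(f_hi), n))


def gammatone_envelope(
    w: Waveform,
    n_bands: int = 32,
    f_lo: float = 50.0,
    f_hi: float = 4000.0,
    out_fs: int = ENVELOPE_FS,
    stimulus_id: str = "",
) -> Envelope:
    """Broadband envelope via a gammatone filterbank.

    4th-order gammatone filters at ``n_bands`` ERB-spaced centers in
    [f_lo, f_hi]; per-band envelope as the magnitude of the analytic
    signal; bands averaged; anti-alias filtered and resampled to
    ``out_fs``.
    """
    if f_lo >= f_hi:
        raise ValueError(f"f_lo ({f_lo}) must be below f_hi ({f_hi})")
    if w.fs <= 2 * f_hi:
        raise ValueError(f"audio rate {w.fs} must exceed twice f_hi ({f_hi})")
    if out_fs > w.fs:
        raise ValueError("out_fs cannot exceed the audio rate")
    from scipy.fft import next_fast_len

    centers = _erb_space(f_lo, f_hi, n_bands)
    n = len(w.samples)
    nfft = next_fast_len(n)
    acc = np.zeros(n)
    for fc in centers:
        b, a = signal.gammatone(fc, "iir", fs=w.fs)
        band = signal.lfilter(b, a, w.samples)
        acc += np.abs(signal.hilbert(band, N=nfft)[:n])
    env = acc / n_bands
    factor = int(round(w.fs / out_fs))
    if abs(w.fs / out_fs - factor) > 1e-9:
        raise ValueError(f"audio rate {w.fs} must be an integer multiple of out_fs {out_fs}")
    down = signal.resample_poly(env, 1, factor)  # includes anti-alias filtering
    return Envelope(np.clip(down, 0.0, None), out_fs, stimulus_id)


def envelope_spectrum(e: Envelope) -> tuple:
    """One-sided magnitude spectrum of the mean-removed envelope."""
    n = len(e.values)
    if n < 2 * e.fs:
        raise ValueError("need at least 2 s of envelope for a spectrum")
    x = e.values - np.mean(e.values)
    mags = np.abs(np.fft.rfft(x)) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / e.fs)
    return freqs, mags


def write_wav(w: Waveform, path) -> None:
    """16-bit PCM WAV output."""
    wavfile.write(path, w.fs, np.round(np.clip(w.samples, -1, 1) * 32767).astype(np.int16))


def read_wav(path) -> Waveform:
    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data / 32767.0
    return Waveform(np.asarray(data, dtype=float), int(fs))
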