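"""Cerebral-acoustic coherence and Morlet wavelet power envelopes.

Cacoh is the magnitude-squared coherence between a neural series and
the stimulus amplitude envelope, both at 100 Hz, estimated by Welch
cross-spectra with 1024-point Hanning segments and 512-point overlap.
The spectrum is evaluated on a 0.05 Hz grid over 0.1-20 Hz by
zero-padding segments to 2000 points (100 Hz / 2000 = 0.05 Hz exactly);
1 s is trimmed from each end of both series beforehand to suppress
onset/offset transients.

Narrow-band power envelopes come from complex Morlet convolution. The
wavelet width is 3 cycles up to the double-beat rate (2.48 Hz) and
grows linearly in frequency to 10 cycles at 35 Hz, trading spectral for
temporal resolution where phrase tracking lives. Samples within half a
wavelet length of an edge are flagged invalid and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

POWER_FS = 100
CACOH_GRID_STEP = 0.05
CACOH_NFFT = 2000  # 100 Hz / 2000 points = exact 0.05 Hz grid


@dataclass(frozen=True)
class CoherenceSpectrum:
    frequencies: np.ndarray  # Hz, 0.1-20 in 0.05 steps
    values: np.ndarray  # magnitude-squared coherence in [0, 1]
    stimulus_id: str = ""
    subject_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class PowerEnvelope:
    """Narrow-band power time course at 100 Hz.

    ``t0_s`` is the time of the first sample relative to melody onset
    (negative when the epoch starts in the pre-stimulus period);
    ``edge_invalid_s`` marks the span at each end contaminated by the
    wavelet edge.
    """

    freq_hz: float
    values: np.ndarray
    fs: int = POWER_FS
    baseline_corrected: bool = False
    t0_s: float = 0.0
    edge_invalid_s: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.freq_hz <= 0:
            raise ValueError("freq_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.fs


def cacoh(
    neural,
    envelope,
    fs: int = POWER_FS,
    nperseg: int = 1024,
    noverlap: int = 512,
    f_lo: float = 0.1,
    f_hi: float = 20.0,
    trim_s: float = 1.0,
    stimulus_id: str = "",
    subject_id: str = "",
) -> CoherenceSpectrum:
    """Magnitude-squared coherence on the 0.05 Hz evaluation grid."""
    x = np.asarray(neural, dtype=float)
    y = np.asarray(envelope, dtype=float)
    if len(x) != len(y):
        raise ValueError("neural and envelope series must have equal length")
    cut = int(round(trim_s * fs))
    x = x[cut : len(x) - cut]
    y = y[cut : len(y) - cut]
    if len(x) < 2 * nperseg:
        raise ValueError(
            f"need at least {2 * nperseg} samples after trimming, got {len(x)}"
        )
    f, cxy = sps.coherence(
        x, y, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, nfft=CACOH_NFFT
    )
    keep = (f >= f_lo - 1e-9) & (f <= f_hi + 1e-9)
    return CoherenceSpectrum(
        f[keep], np.clip(cxy[keep], 0.0, 1.0), stimulus_id, subject_id
    )


def beat_band_values(
    spec: CoherenceSpectrum, beat_hz: float = 1.24, double_beat_hz: float = 2.48
) -> tuple:
    """Coherence at the grid points nearest the beat and double-beat rates."""
    out = []
    for target in (beat_hz, double_beat_hz):
        if target < spec.frequencies[0] - 1e-9 or target > spec.frequencies[-1] + 1e-9:
            raise ValueError(f"target {target} Hz outside the coherence grid")
        out.append(float(spec.values[np.argmin(np.abs(spec.frequencies - target))]))
    return tuple(out)


def n_cycles(freq_hz: float, low_edge: float = 2.48, high_edge: float = 35.0) -> float:
    """Wavelet width: 3 cycles up to 2.48 Hz, linear to 10 cycles at 35 Hz."""
    if freq_hz <= low_edge:
        return 3.0
    if freq_hz >= high_edge:
        return 10.0
    return 3.0 + (freq_hz - low_edge) / (high_edge - low_edge) * 7.0


def _morlet_wavelet(freq_hz: float, cycles: float, fs: int) -> np.ndarray:
    sigma_t = cycles / (2 * np.pi * freq_hz)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-0.5 * (t / sigma_t) ** 2)
    w = gauss * np.exp(2j * np.pi * freq_hz * t)
    return w / gauss.sum()


def morlet_power(
    series,
    freqs=(1.0, 1.24, 2.0, 2.48) + tuple(range(3, 36)),
    fs: int = POWER_FS,
    t0_s: float = 0.0,
    cycle_schedule=n_cycles,
) -> dict:
    """Complex Morlet power envelopes at the requested frequencies.

    Returns ``{freq: PowerEnvelope}``; power is the squared magnitude of
    the wavelet convolution, at the input rate.
    """
    x = np.asarray(series, dtype=float)
    out = {}
    for f in np.atleast_1d(freqs):
        f = float(f)
        if f >= fs / 2:
            raise ValueError(f"frequency {f} Hz at or above Nyquist ({fs / 2} Hz)")
        w = _morlet_wavelet(f, cycle_schedule(f), fs)
        if len(w) > len(x):
            raise ValueError(
                f"series of {len(x)} samples shorter than the {f} Hz wavelet ({len(w)})"
            )
        analytic = sps.fftconvolve(x, w, mode="same")
        out[f] = PowerEnvelope(
            f, np.abs(analytic) ** 2, fs, False, t0_s, (len(w) // 2) / fs
        )
    return out


def baseline_correct(pe: PowerEnvelope, baseline_window_s=(-2.0, -0.5)) -> PowerEnvelope:
    """Subtract mean power over a pre-stimulus window (idempotent-safe flag)."""
    lo, hi = baseline_window_s
    t = pe.times_s
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not np.any(mask):
        raise ValueError(
            f"baseline window [{lo}, {hi}] s outside the epoch span "
            f"[{t[0]:.2f}, {t[-1]:.2f}] s"
        )
    return replace(pe, values=pe.values - pe.values[mask].mean(), baseline_corrected=True)
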