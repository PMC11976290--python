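"""Morlet-wavelet time-frequency decomposition and spike-phase assignment.

The LFP is decomposed with complex Morlet wavelets of c = 7 cycles on a
log-spaced theta grid (1.5 ... 8 Hz). From the analytic coefficients we
take instantaneous power and phase, z-score power against a pre-stimulus
baseline, average delay-period spectra, and read off the oscillation
phase at each spike time.

Phase convention (shared package-wide): phase 0 at the peak of a cosine,
increasing with time, reported in [0, 2*pi).

Edge handling: the trace is reflect-padded by half the wavelet support at
the lowest frequency and a per-frequency validity mask marks samples
closer than half a wavelet support to either edge; spikes falling on
invalid samples are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "THETA_GRID",
    "SpectralDecomposition",
    "morlet_transform",
    "zscore_power",
    "delay_spectrum",
    "spike_phases",
]

# Log-spaced theta-range center frequencies (Hz) used for spike-phase coupling.
THETA_GRID = np.array([1.5, 1.75, 2.03, 2.37, 2.8, 3.2, 3.7, 4.4, 5.1, 5.9, 6.9, 8.0])

_N_SIGMA = 3.5  # wavelet truncated at +/- 3.5 temporal standard deviations


@dataclass
class SpectralDecomposition:
    coeffs: np.ndarray        # complex, (n_freqs, n_samples)
    freqs: np.ndarray         # Hz, strictly increasing
    fs: float                 # Hz
    t0: float                 # time of first sample, s
    cycles: float             # Morlet cycle parameter c
    valid: np.ndarray         # bool, (n_freqs, n_samples); False near edges

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.coeffs.shape[1]) / self.fs

    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2

    def phase(self) -> np.ndarray:
        """Instantaneous phase in [0, 2*pi)."""
        return np.mod(np.angle(self.coeffs), 2.0 * np.pi)

    def _index_of(self, frequency: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - frequency)))
        if abs(self.freqs[i] - frequency) > 1e-6:
            raise ValueError(f"frequency {frequency} Hz not on the grid")
        return i


def _morlet_kernel(freq: float, fs: float, cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, scaled so a unit cosine at ``freq`` yields
    coefficients of magnitude ~1."""
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(_N_SIGMA * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = envelope * np.exp(2j * np.pi * freq * t)
    return kernel * (2.0 / envelope.sum())


def morlet_transform(samples, fs: float | None = None, freqs=THETA_GRID,
                     cycles: float = 7.0, t0: float = 0.0) -> SpectralDecomposition:
    """Convolve a trace with complex Morlet wavelets on a frequency grid.

    ``samples`` may be an LfpTrace-like object exposing ``samples``, ``fs``
    and ``t0`` (in which case ``fs`` may be omitted) or a plain 1-D array
    plus ``fs``/``t0``.
    """
    if hasattr(samples, "samples"):
        fs = samples.fs
        t0 = samples.t0
        samples = samples.samples
    if fs is None:
        raise TypeError("fs is required for plain-array input")
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D trace")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if freqs[0] <= 0 or freqs[-1] >= fs / 2:
        raise ValueError("frequencies must lie in (0, fs/2)")
    n = x.size
    halves = np.ceil(_N_SIGMA * (cycles / (2 * np.pi * freqs)) * fs).astype(int)
    pad = int(halves.max())
    if n <= 2:
        raise ValueError("trace too short for wavelet analysis")
    # reflect-pad in chunks if the trace is shorter than one support
    xp = x
    while pad >= xp.size:
        xp = np.pad(xp, xp.size - 1, mode="reflect")
    xp = np.pad(xp, pad, mode="reflect")
    offset = (xp.size - n) // 2
    coeffs = np.empty((freqs.size, n), dtype=complex)
    valid = np.ones((freqs.size, n), dtype=bool)
    for i, f in enumerate(freqs):
        kern = _morlet_kernel(f, fs, cycles)
        conv = fftconvolve(xp, kern, mode="same")
        coeffs[i] = conv[offset:offset + n]
        h = halves[i]
        if h > 0:
            valid[i, :min(h, n)] = False
            valid[i, max(n - h, 0):] = False
    return SpectralDecomposition(coeffs=coeffs, freqs=freqs, fs=fs, t0=t0,
                                 cycles=cycles, valid=valid)


def _window_slice(dec: SpectralDecomposition, window) -> slice:
    start, stop = window
    i0 = int(np.ceil((start - dec.t0) * dec.fs))
    i1 = int(np.floor((stop - dec.t0) * dec.fs))
    n = dec.coeffs.shape[1]
    if i0 < 0 or i1 > n or i0 >= i1:
        raise ValueError(f"window {window} outside trace [{dec.t0}, {dec.t0 + n / dec.fs})")
    return slice(i0, i1)


def zscore_power(dec: SpectralDecomposition, baseline_window) -> np.ndarray:
    """Power z-scored per frequency against a baseline window [start, stop)."""
    power = dec.power()
    sl = _window_slice(dec, baseline_window)
    base = power[:, sl]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, keepdims=True)
    if np.any(sd <= 0):
        raise ValueError("zero baseline variance at some frequency")
    return (power - mu) / sd


def delay_spectrum(dec: SpectralDecomposition, probe_time: float,
                   baseline_window, window: float = 1.5, band=None):
    """Average z-scored power over the last ``window`` seconds before probe.

    Returns ``(spectrum, peak_frequency)`` where the peak is searched
    within ``band`` (a (lo, hi) tuple, default the whole grid). Ties are
    broken toward the lowest frequency.
    """
    z = zscore_power(dec, baseline_window)
    sl = _window_slice(dec, (probe_time - window, probe_time))
    spectrum = z[:, sl].mean(axis=1)
    freqs = dec.freqs
    if band is not None:
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        if not in_band.any():
            raise ValueError("band contains no grid frequencies")
    else:
        in_band = np.ones_like(freqs, dtype=bool)
    sub = np.where(in_band)[0]
    peak = freqs[sub[np.argmax(spectrum[sub])]]  # argmax takes the first (lowest) on ties
    return spectrum, float(peak)


def spike_phases(spike_times, dec: SpectralDecomposition, frequency: float,
                 window=None):
    """Oscillation phase at each spike time (nearest-sample lookup).

    Spikes outside ``window`` [start, stop) or on edge-invalid samples are
    excluded. Returns ``(phases, n_excluded)`` with phases in [0, 2*pi).
    """
    fi = dec._index_of(frequency)
    times = np.asarray(spike_times, dtype=float)
    n = dec.coeffs.shape[1]
    idx = np.round((times - dec.t0) * dec.fs).astype(int)
    keep = (idx >= 0) & (idx < n)
    if window is not None:
        keep &= (times >= window[0]) & (times < window[1])
    safe = np.clip(idx, 0, n - 1)
    keep &= dec.valid[fi, safe]
    phases = np.mod(np.angle(dec.coeffs[fi, safe[keep]]), 2.0 * np.pi)
    return phases, int((~keep).sum())
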