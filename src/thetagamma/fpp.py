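"""Per-cycle frequency x theta-phase power (FPP) matrices.

The FPP of a theta cycle is the 81 (frequency, 20-180 Hz step 2) by
20 (theta-phase bin) matrix of z-scored Morlet wavelet power — the
feature vector (1620-dimensional when flattened) used to cluster cycles
into theta-gamma coupling states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import uniform_filter1d

from .preprocess import ThetaCycle

FREQS = np.arange(20.0, 181.0, 2.0)     # Hz
N_FREQS = FREQS.size                     # 81
N_PHASE_BINS = 20
PHASE_BIN_WIDTH = 2.0 * np.pi / N_PHASE_BINS
PHASE_BIN_CENTERS = -np.pi + PHASE_BIN_WIDTH * (np.arange(N_PHASE_BINS) + 0.5)

#: complex analytic Morlet with omega0 = 5 (center frequency 5/(2pi)
#: cycles per unit time, bandwidth parameter 2 giving the unit-variance
#: Gaussian envelope of the classic Morlet wavelet)
_OMEGA0 = 5.0
MORLET_NAME = f"cmor2.0-{_OMEGA0 / (2.0 * np.pi):.10f}"

# smoothing supports at the 2 Hz / 625 Hz analysis grid:
# +/-2 Hz -> 3 frequency bins; +/-8 ms -> 11 samples
FREQ_SMOOTH_BINS = 3
TIME_SMOOTH_SAMPLES = 11


@dataclass(frozen=True)
class FppMatrix:
    """FPP of one theta cycle (81 x 20, z-units)."""

    values: np.ndarray
    cycle_index: int
    freq_axis: np.ndarray = None
    phase_bin_centers: np.ndarray = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_FREQS, N_PHASE_BINS):
            raise ValueError(f"FPP must be {N_FREQS} x {N_PHASE_BINS}, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("FPP contains non-finite entries")
        object.__setattr__(self, "values", values)
        if self.freq_axis is None:
            object.__setattr__(self, "freq_axis", FREQS.copy())
        if self.phase_bin_centers is None:
            object.__setattr__(self, "phase_bin_centers", PHASE_BIN_CENTERS.copy())

    def flatten(self) -> np.ndarray:
        return self.values.ravel()


def wavelet_power(samples: np.ndarray, fs: float, freqs: np.ndarray = FREQS) -> np.ndarray:
    """Morlet wavelet power |W(t, f)|^2, shape (n_freqs, n_samples)."""
    samples = np.asarray(samples, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2):
        raise ValueError("requested frequency at or above Nyquist")
    scales = pywt.frequency2scale(MORLET_NAME, freqs / fs)
    coef, _ = pywt.cwt(samples, scales, MORLET_NAME, sampling_period=1.0 / fs, method="fft")
    return np.abs(coef) ** 2


def smooth_and_zscore(ws: np.ndarray) -> np.ndarray:
    """Boxcar-smooth (+/-2 Hz, +/-8 ms) then z-score each frequency row.

    Rows with zero variance map to all-zero rather than dividing by zero.
    """
    ws = np.asarray(ws, dtype=float)
    smoothed = uniform_filter1d(ws, FREQ_SMOOTH_BINS, axis=0, mode="nearest")
    smoothed = uniform_filter1d(smoothed, TIME_SMOOTH_SAMPLES, axis=1, mode="nearest")
    mean = smoothed.mean(axis=1, keepdims=True)
    sd = smoothed.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (smoothed - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    return out


def phase_bin_indices(phase: np.ndarray) -> np.ndarray:
    """Map wrapped phases (-pi, pi] to bin indices 0..19."""
    idx = np.floor((np.asarray(phase) + np.pi) / PHASE_BIN_WIDTH).astype(np.int64)
    return np.clip(idx, 0, N_PHASE_BINS - 1)


def _interp_empty_bins(row_sums: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Per-bin means (rows = frequencies) with circular linear
    interpolation across empty phase bins."""
    means = np.where(counts > 0, row_sums / np.where(counts == 0, 1, counts), np.nan)
    empty = counts == 0
    if not empty.any():
        return means
    if empty.all():
        return np.zeros_like(means)
    filled = np.flatnonzero(~empty)
    targets = np.flatnonzero(empty)
    # tile the filled support once on each side so interpolation wraps
    xp = np.concatenate([filled - N_PHASE_BINS, filled, filled + N_PHASE_BINS])
    for f in range(means.shape[0]):
        means[f, targets] = np.interp(targets, xp, np.tile(means[f, filled], 3))
    return means


def compute_fpp(cycle: ThetaCycle, zpower: np.ndarray, phase: np.ndarray) -> FppMatrix:
    """FPP of a single cycle from the epoch-wide z-scored power."""
    if cycle.end - cycle.start < N_PHASE_BINS:
        raise ValueError("cycle shorter than the number of phase bins")
    if cycle.end > zpower.shape[1]:
        raise ValueError("cycle extends beyond the z-scored epoch")
    bins = phase_bin_indices(phase[cycle.slice])
    seg = zpower[:, cycle.slice]
    counts = np.bincount(bins, minlength=N_PHASE_BINS).astype(float)
    sums = np.zeros((zpower.shape[0], N_PHASE_BINS))
    np.add.at(sums.T, bins, seg.T)
    values = _interp_empty_bins(sums, counts)
    return FppMatrix(values=values, cycle_index=cycle.index)


def fpp_stack(cycles: list[ThetaCycle], zpower: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """FPPs for many cycles at once, shape (n_cycles, 81, 20).

    Vectorized accumulation over the whole epoch; identical to calling
    :func:`compute_fpp` per cycle.
    """
    n_samples = zpower.shape[1]
    n_cycles = len(cycles)
    if n_cycles == 0:
        return np.empty((0, N_FREQS, N_PHASE_BINS))
    cycle_of_sample = np.full(n_samples, -1, dtype=np.int64)
    for i, cyc in enumerate(cycles):
        cycle_of_sample[cyc.start : cyc.end] = i
    in_cycle = cycle_of_sample >= 0
    flat_idx = cycle_of_sample[in_cycle] * N_PHASE_BINS + phase_bin_indices(phase[in_cycle])
    counts = np.bincount(flat_idx, minlength=n_cycles * N_PHASE_BINS).astype(float)
    sums = np.zeros((n_cycles * N_PHASE_BINS, N_FREQS))
    np.add.at(sums, flat_idx, zpower[:, in_cycle].T)
    counts = counts.reshape(n_cycles, N_PHASE_BINS)
    sums = sums.reshape(n_cycles, N_PHASE_BINS, N_FREQS).transpose(0, 2, 1)
    out = np.empty((n_cycles, N_FREQS, N_PHASE_BINS))
    for i in range(n_cycles):
        out[i] = _interp_empty_bins(sums[i], counts[i])
    return out
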