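"""Channel selection, theta phase, and theta-cycle segmentation.

The pyramidal-layer channel is the one with the highest ripple-band
(150-250 Hz) RMS.  Theta phase is the analytic-signal angle of the
zero-phase band-passed (5-10 Hz) LFP, so phase 0 falls on theta peaks;
cycles run peak to peak and are kept only if their duration is
consistent with the theta band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt

ANALYSIS_FS = 625.0
THETA_BAND = (5.0, 10.0)
RIPPLE_BAND = (150.0, 250.0)
#: accepted per-cycle duration gate, s (enforces 5-10 Hz per cycle)
CYCLE_DURATION_BOUNDS = (0.100, 0.200)


@dataclass(frozen=True)
class ThetaCycle:
    """One retained theta cycle; start/end are shared boundary samples."""

    index: int
    start: int          # sample index of the phase-0 boundary
    end: int            # sample index of the next phase-0 boundary
    duration: float     # s

    @property
    def slice(self) -> slice:
        return slice(self.start, self.end)


def downsample(samples: np.ndarray, fs_in: float, fs_out: float = ANALYSIS_FS) -> np.ndarray:
    """Polyphase resampling to the analysis rate (no-op if already there)."""
    if fs_in == fs_out:
        return np.asarray(samples, dtype=float)
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return resample_poly(np.asarray(samples, dtype=float), frac.numerator, frac.denominator, axis=-1)


def _bandpass_sos(band, fs, order=4):
    return butter(order, band, btype="bandpass", fs=fs, output="sos")


def select_pyramidal_channel(
    lfp: np.ndarray,
    fs: float,
    edge_channels: set[int] | None = None,
) -> int:
    """Index of the non-edge channel maximizing 150-250 Hz RMS.

    ``edge_channels`` lists channels at the top/bottom of a shank, to be
    excluded when the probe geometry is known.  Ties break to the lowest
    index.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if fs < 500:
        raise ValueError("fs must be >= 500 Hz for ripple-band selection")
    n_channels = lfp.shape[0]
    candidates = [c for c in range(n_channels) if not edge_channels or c not in edge_channels]
    if not candidates:
        raise ValueError("all channels excluded by shank geometry")
    if n_channels == 1:
        return 0
    sos = _bandpass_sos(RIPPLE_BAND, fs)
    rms = np.full(n_channels, -np.inf)
    for c in candidates:
        filtered = sosfiltfilt(sos, lfp[c])
        rms[c] = np.sqrt(np.mean(filtered**2))
    return int(np.argmax(rms))


def theta_phase(samples: np.ndarray, fs: float, band: tuple[float, float] = THETA_BAND) -> np.ndarray:
    """Instantaneous theta phase in (-pi, pi], zero at filtered-theta peaks."""
    samples = np.asarray(samples, dtype=float)
    min_len = int(3 * fs / band[0])
    if samples.size < min_len:
        raise ValueError(f"signal too short for theta filtering (< {min_len} samples)")
    if np.ptp(samples) == 0:
        raise ValueError("constant signal has no defined theta phase")
    sos = _bandpass_sos(band, fs)
    filtered = sosfiltfilt(sos, samples)
    return np.angle(hilbert(filtered))


def detect_theta_cycles(
    phase: np.ndarray,
    fs: float,
    duration_bounds: tuple[float, float] = CYCLE_DURATION_BOUNDS,
) -> list[ThetaCycle]:
    """Segment the phase series into duration-gated peak-to-peak cycles.

    Boundaries are upward zero crossings of the wrapped phase (excluding
    the +/-pi wrap); cycles whose duration falls outside
    ``duration_bounds`` or whose unwrapped phase is non-monotonic are
    discarded.
    """
    phase = np.asarray(phase, dtype=float)
    upward = (phase[:-1] < 0) & (phase[1:] >= 0) & (np.diff(phase) < np.pi)
    boundaries = np.flatnonzero(upward) + 1
    cycles: list[ThetaCycle] = []
    lo, hi = duration_bounds
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        duration = (b - a) / fs
        if not (lo <= duration <= hi):
            continue
        seg = np.unwrap(phase[a:b])
        if np.any(np.diff(seg) < 0):
            continue
        cycles.append(ThetaCycle(index=len(cycles), start=int(a), end=int(b), duration=duration))
    return cycles
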