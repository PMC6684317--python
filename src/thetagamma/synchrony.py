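"""Pairwise phase consistency (PPC) for spike-field and LFP-LFP analysis.

PPC is the bias-free phase-locking estimator of Vinck et al.: the mean
cosine of phase differences over all distinct pairs, bounded in [-1, 1].
Spike-field PPC is computed per 6-Hz band across trials; LFP-LFP PPC is
computed per (frequency, theta-phase) bin across theta cycles from the
Morlet wavelet cross spectrum, then averaged over a gamma-field-anchored
theta-phase window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import butter, hilbert, sosfiltfilt

from . import fpp as fpp_mod
from .preprocess import ThetaCycle
from .states import GammaField

#: 33 contiguous 6-Hz bands tiling 2-200 Hz
PPC_BANDS = [(2.0 + 6.0 * i, 8.0 + 6.0 * i) for i in range(33)]


@dataclass(frozen=True)
class PpcSpectrum:
    bands: list
    ppc: np.ndarray            # per band, in [-1, 1]; NaN where undefined
    n_trials: int
    spikes_per_trial: np.ndarray


@dataclass(frozen=True)
class PpcMap:
    values: np.ndarray         # (81, 20) in [-1, 1]
    n_cycles: int
    freq_axis: np.ndarray
    phase_bin_centers: np.ndarray


@dataclass(frozen=True)
class UnitExclusion:
    unit_id: str
    reason: str


def spike_field_ppc(spike_phases_by_trial) -> float:
    """PPC across trials from per-trial spike-phase lists.

    Equals the double sum over distinct trial pairs of the dot products
    of per-spike unit phase vectors, normalized by N_m N_l — computed
    via per-trial mean resultant vectors v_m:
    PPC = (1/(M(M-1))) * sum_{m != l} Re(v_m conj(v_l)).
    """
    vectors = []
    for phases in spike_phases_by_trial:
        phases = np.asarray(phases, dtype=float)
        if phases.size == 0:
            continue
        vectors.append(np.mean(np.exp(1j * phases)))
    m = len(vectors)
    if m < 2:
        raise ValueError("PPC needs at least 2 trials with spikes")
    v = np.asarray(vectors)
    total = np.abs(v.sum()) ** 2 - np.sum(np.abs(v) ** 2)
    ppc = float(total / (m * (m - 1)))
    return float(np.clip(ppc, -1.0, 1.0))


def check_unit_inclusion(
    unit_id: str,
    cell_type: str,
    spike_times: np.ndarray,
    trials: list[tuple[float, float]],
    duration: float,
) -> UnitExclusion | None:
    """Inclusion rule: fired in >= 10 trials and rate > 5 Hz for
    interneurons, > 2 Hz for pyramidal cells.  Returns an exclusion
    record, or None if the unit passes."""
    spike_times = np.asarray(spike_times, dtype=float)
    fired = sum(1 for a, b in trials if np.any((spike_times >= a) & (spike_times < b)))
    if fired < 10:
        return UnitExclusion(unit_id, f"fired in only {fired} trials (<10)")
    rate = spike_times.size / duration if duration > 0 else 0.0
    threshold = 5.0 if cell_type == "interneuron" else 2.0
    if rate <= threshold:
        return UnitExclusion(unit_id, f"rate {rate:.2f} Hz <= {threshold} Hz for {cell_type}")
    return None


def default_trials(duration: float, window_s: float = 2.0) -> list[tuple[float, float]]:
    """Fixed windows used as trials when no task structure is supplied."""
    edges = np.arange(0.0, duration, window_s)
    return [(float(a), float(a + window_s)) for a in edges if a + window_s <= duration]


def traversal_trials(position_t, position_x, track_length: float, margin_frac: float = 0.1):
    """End-to-end traversals of a linear track, used as trials.

    A trial spans the interval between a visit to one track end and the
    next visit to the opposite end (ends = within ``margin_frac`` of the
    track extremes).
    """
    t = np.asarray(position_t, dtype=float)
    x = np.asarray(position_x, dtype=float)
    lo = track_length * margin_frac
    hi = track_length * (1.0 - margin_frac)
    trials = []
    state = 0  # 0: unknown, -1: at low end, +1: at high end
    start = None
    for i in range(t.size):
        if x[i] <= lo:
            if state == 1 and start is not None:
                trials.append((start, float(t[i])))
            state, start = -1, float(t[i])
        elif x[i] >= hi:
            if state == -1 and start is not None:
                trials.append((start, float(t[i])))
            state, start = 1, float(t[i])
    return trials


def spike_field_ppc_spectrum(
    spike_times: np.ndarray,
    lfp: np.ndarray,
    fs: float,
    trials: list[tuple[float, float]],
    bands=None,
) -> PpcSpectrum:
    """Spike-field PPC in each 6-Hz band from 2 to 200 Hz.

    For each band the LFP is zero-phase band-passed, spike phases are
    read off the analytic signal, grouped by trial, and PPC computed
    across trials.  Bands with fewer than 2 spiking trials are NaN.
    """
    if bands is None:
        bands = PPC_BANDS
    spike_times = np.asarray(spike_times, dtype=float)
    lfp = np.asarray(lfp, dtype=float)
    spike_idx = np.round(spike_times * fs).astype(int)
    valid = (spike_idx >= 0) & (spike_idx < lfp.size)
    spike_idx, spike_t = spike_idx[valid], spike_times[valid]
    trial_of_spike = np.full(spike_t.size, -1)
    for ti, (a, b) in enumerate(trials):
        trial_of_spike[(spike_t >= a) & (spike_t < b)] = ti
    spikes_per_trial = np.bincount(trial_of_spike[trial_of_spike >= 0], minlength=len(trials))
    ppc = np.full(len(bands), np.nan)
    for bi, (lo, hi) in enumerate(bands):
        hi = min(hi, 0.99 * fs / 2)
        sos = butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
        phase = np.angle(hilbert(sosfiltfilt(sos, lfp)))
        by_trial = [
            phase[spike_idx[trial_of_spike == ti]]
            for ti in range(len(trials))
            if np.any(trial_of_spike == ti)
        ]
        if len(by_trial) >= 2:
            ppc[bi] = spike_field_ppc(by_trial)
    return PpcSpectrum(
        bands=list(bands),
        ppc=ppc,
        n_trials=len(trials),
        spikes_per_trial=spikes_per_trial,
    )


def _wavelet_coeffs(samples: np.ndarray, fs: float) -> np.ndarray:
    scales = pywt.frequency2scale(fpp_mod.MORLET_NAME, fpp_mod.FREQS / fs)
    coef, _ = pywt.cwt(
        np.asarray(samples, dtype=float), scales, fpp_mod.MORLET_NAME,
        sampling_period=1.0 / fs, method="fft",
    )
    return coef


def lfp_lfp_ppc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    cycles: list[ThetaCycle],
    phase: np.ndarray,
) -> PpcMap:
    """LFP-LFP PPC over (frequency, theta phase) across theta cycles.

    Per cycle the Morlet wavelet cross spectrum Wx * conj(Wy) is binned
    into the 81 x 20 FPP grid; its angle is the per-cycle phase lag
    W_k(f, theta).  PPC = (|sum_k e^{iW_k}|^2 - N) / (N (N-1)), the mean
    pairwise cosine of lag differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must share length and sampling rate")
    n_cycles = len(cycles)
    if n_cycles < 2:
        raise ValueError("need at least 2 cycles")
    cross = _wavelet_coeffs(x, fs) * np.conj(_wavelet_coeffs(y, fs))
    resultant = np.zeros((fpp_mod.N_FREQS, fpp_mod.N_PHASE_BINS), dtype=complex)
    for cyc in cycles:
        bins = fpp_mod.phase_bin_indices(phase[cyc.slice])
        seg = cross[:, cyc.slice]
        sums = np.zeros((fpp_mod.N_FREQS, fpp_mod.N_PHASE_BINS), dtype=complex)
        np.add.at(sums.T, bins, seg.T)
        lag = np.angle(sums)
        resultant += np.exp(1j * lag)
    values = (np.abs(resultant) ** 2 - n_cycles) / (n_cycles * (n_cycles - 1))
    return PpcMap(
        values=np.clip(values, -1.0, 1.0),
        n_cycles=n_cycles,
        freq_axis=fpp_mod.FREQS.copy(),
        phase_bin_centers=fpp_mod.PHASE_BIN_CENTERS.copy(),
    )


def average_ppc_window(ppc_map: PpcMap, field: GammaField) -> np.ndarray:
    """Mean PPC per frequency over the gamma-field-anchored phase window.

    The circular window runs from (gravity phase - 7 * phase SD) to
    (gravity phase + 1 * phase SD); a window catching no bin centers is
    widened to the nearest bin with a warning.
    """
    lo = field.gravity_phase - 7.0 * field.phase_sd
    hi = field.gravity_phase + 1.0 * field.phase_sd
    centers = ppc_map.phase_bin_centers
    width = hi - lo
    if width >= 2.0 * np.pi:
        member = np.ones(centers.size, dtype=bool)
    else:
        # circular membership: offset from window start, wrapped to [0, 2pi)
        offset = np.mod(centers - lo, 2.0 * np.pi)
        member = offset <= width
    if not member.any():
        import warnings

        warnings.warn("phase window covers no bin centers; widening to nearest bin")
        mid = lo + width / 2.0
        nearest = np.argmin(np.abs(np.angle(np.exp(1j * (centers - mid)))))
        member = np.zeros(centers.size, dtype=bool)
        member[nearest] = True
    return ppc_map.values[:, member].mean(axis=1)
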