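"""Place-cell analyses: rate maps, spatial information, place fields,
and theta phase precession, each resolvable by theta-gamma state.

Rate maps use 5 cm bins, 5-bin boxcar smoothing (mass-preserving with
edge renormalization) and a 5 cm/s running-speed mask.  Spatial
information is the Skaggs measure in bits/spike.  Phase precession is a
circular-linear regression whose slope maximizes the mean resultant
length, scored by the circular-linear correlation and its large-sample
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .circstats import circ_lin_corr, circ_mean, wrap_angle

SPEED_MIN = 5.0          # cm/s running threshold
BIN_CM = 5.0
BOXCAR_BINS = 5
LOWESS_WINDOW = 21       # samples (0.525 s at 40 Hz)
#: behavioral speed strata, cm/s: still, walk, run, fast run
SPEED_STRATA = ((0.0, 5.0), (5.0, 15.0), (15.0, 60.0), (60.0, np.inf))


@dataclass(frozen=True)
class RateMap:
    rate: np.ndarray          # Hz per bin
    occupancy: np.ndarray     # s per bin (smoothed)
    spike_counts: np.ndarray  # raw in-mask spike counts per bin
    bin_edges: np.ndarray     # cm
    bin_size: float = BIN_CM


@dataclass(frozen=True)
class PlaceField:
    start_bin: int
    end_bin: int              # inclusive
    entry_cm: float
    exit_cm: float
    peak_rate: float

    def normalize(self, x_cm):
        """Position within the field mapped to [0, 1] (entry -> 0, exit -> 1)."""
        return (np.asarray(x_cm, dtype=float) - self.entry_cm) / (self.exit_cm - self.entry_cm)


@dataclass(frozen=True)
class PrecessionFit:
    slope: float              # rad per field traversal
    phase_offset: float       # rad
    r: float                  # circular-linear correlation
    p: float
    n_spikes: int

    @property
    def significant_precession(self) -> bool:
        return self.r < 0 and self.p < 0.05


def smooth_position(t, x, window: int = LOWESS_WINDOW):
    """Lowess-smoothed track and speed.

    Locally weighted regression over a ``window``-sample neighborhood;
    speed is the absolute first difference of the smoothed positions.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < window:
        raise ValueError(f"need at least {window} position samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("position timestamps must be strictly increasing")
    frac = min(window / t.size, 1.0)
    smoothed = lowess(x, t, frac=frac, it=0, delta=0.0, return_sorted=False)
    speed = np.abs(np.gradient(smoothed, t))
    return smoothed, speed


def speed_stratum(speed) -> np.ndarray:
    """Index of the behavioral stratum for each speed sample (0..3)."""
    speed = np.asarray(speed, dtype=float)
    out = np.zeros(speed.shape, dtype=np.int64)
    for i, (lo, hi) in enumerate(SPEED_STRATA):
        out[(speed >= lo) & (speed < hi)] = i
    return out


def _boxcar(values: np.ndarray, width: int = BOXCAR_BINS) -> np.ndarray:
    """Boxcar smoothing, truncated at the edges and renormalized by the
    actual window coverage (mass-preserving up to the edge policy)."""
    kernel = np.ones(width)
    summed = np.convolve(values, kernel, mode="same")
    coverage = np.convolve(np.ones_like(values), kernel, mode="same")
    return summed / coverage


def compute_rate_map(
    spike_times,
    track_t,
    track_x,
    speed=None,
    speed_min: float = SPEED_MIN,
    bin_cm: float = BIN_CM,
    track_length: float | None = None,
) -> RateMap:
    """Firing-rate map: smoothed spike counts over smoothed occupancy.

    Position samples and spikes at running speed below ``speed_min`` are
    discarded before binning; both maps are 5-bin boxcar smoothed before
    the division.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    track_t = np.asarray(track_t, dtype=float)
    track_x = np.asarray(track_x, dtype=float)
    if speed is None:
        _, speed = smooth_position(track_t, track_x)
    if track_length is None:
        track_length = float(np.max(track_x)) if track_x.size else bin_cm
    edges = np.arange(0.0, track_length + bin_cm, bin_cm)
    if edges.size < 4:
        raise ValueError("track must cover at least 3 bins")
    dt = np.median(np.diff(track_t))
    mask = speed >= speed_min
    occupancy_counts, _ = np.histogram(track_x[mask], bins=edges)
    occupancy = occupancy_counts * dt
    if occupancy.sum() <= 0:
        raise ValueError("zero occupancy above the speed threshold")
    spike_x = np.interp(spike_times, track_t, track_x)
    spike_speed = np.interp(spike_times, track_t, speed)
    in_mask = spike_speed >= speed_min
    spike_counts, _ = np.histogram(spike_x[in_mask], bins=edges)
    smooth_counts = _boxcar(spike_counts.astype(float))
    smooth_occ = _boxcar(occupancy)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(smooth_occ > 0, smooth_counts / np.where(smooth_occ == 0, 1, smooth_occ), 0.0)
    return RateMap(
        rate=rate,
        occupancy=smooth_occ,
        spike_counts=spike_counts,
        bin_edges=edges,
        bin_size=bin_cm,
    )


def spatial_information(rate_map: RateMap) -> float:
    """Skaggs spatial information, bits/spike.

    SI = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda) with p_i
    the occupancy share; zero-rate bins contribute 0.
    """
    occ = rate_map.occupancy
    rate = rate_map.rate
    occupied = occ > 0
    p = np.where(occupied, occ, 0.0)
    p = p / p.sum()
    mean_rate = float(np.sum(p * rate))
    if mean_rate <= 0:
        raise ValueError("mean firing rate is zero")
    ratio = rate / mean_rate
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def place_cell_test(
    spike_times,
    track_t,
    track_x,
    speed=None,
    n_shuffles: int = 100,
    seed: int = 0,
    peak_rate_min: float = 2.0,
    **rate_map_kwargs,
):
    """Shuffle test for place coding.

    Each shuffle circularly shifts the spike train by a uniform draw
    from [20 s, T - 20 s]; the unit is a place cell iff its SI exceeds
    the 95th percentile of shuffled SIs and its peak rate exceeds 2 Hz.
    Returns (is_place_cell, SI, SI 95th percentile, peak rate).
    """
    track_t = np.asarray(track_t, dtype=float)
    duration = float(track_t[-1] - track_t[0])
    if duration <= 40.0:
        raise ValueError("session must be longer than 40 s for the shuffle test")
    spike_times = np.asarray(spike_times, dtype=float)
    if speed is None:
        _, speed = smooth_position(track_t, track_x)
    rmap = compute_rate_map(spike_times, track_t, track_x, speed=speed, **rate_map_kwargs)
    si = spatial_information(rmap)
    peak = float(rmap.rate.max())
    rng = np.random.default_rng(seed)
    t0 = track_t[0]
    shuffled_si = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shift = rng.uniform(20.0, duration - 20.0)
        shifted = t0 + np.mod(spike_times - t0 + shift, duration)
        smap = compute_rate_map(shifted, track_t, track_x, speed=speed, **rate_map_kwargs)
        shuffled_si[s] = spatial_information(smap)
    si_95 = float(np.percentile(shuffled_si, 95))
    return (si > si_95) and (peak > peak_rate_min), si, si_95, peak


def detect_place_fields(rate_map: RateMap, threshold_frac: float = 0.2, min_bins: int = 3):
    """Maximal runs of >= ``min_bins`` contiguous bins above 20% of peak."""
    rate = rate_map.rate
    peak = rate.max()
    if peak <= 0:
        return []
    above = rate > threshold_frac * peak
    fields = []
    i = 0
    n = rate.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_bins:
                fields.append(
                    PlaceField(
                        start_bin=i,
                        end_bin=j,
                        entry_cm=float(rate_map.bin_edges[i]),
                        exit_cm=float(rate_map.bin_edges[j + 1]),
                        peak_rate=float(rate[i : j + 1].max()),
                    )
                )
            i = j + 1
        else:
            i += 1
    return fields


def circular_linear_fit(
    norm_positions,
    phases,
    slope_range: tuple[float, float] = (-2.0, 2.0),
    coarse_step: float = 0.01,
    min_spikes: int = 10,
) -> PrecessionFit:
    """Circular-linear regression of spike phase on field position.

    The slope (in cycles per field traversal within ``slope_range``)
    maximizes the mean resultant length of (phi - 2 pi a x); ties break
    toward 0.  r and p are the circular-linear correlation between phi
    and the fitted circular variable 2 pi a x and its normal-approximation
    test.  The returned slope is in rad per traversal.
    """
    x = np.asarray(norm_positions, dtype=float)
    phi = np.asarray(phases, dtype=float)
    if x.size < min_spikes:
        raise ValueError(f"need at least {min_spikes} spikes")
    if np.ptp(x) == 0:
        raise ValueError("all positions identical")
    grid = np.arange(slope_range[0], slope_range[1] + coarse_step / 2, coarse_step)
    resultants = np.abs(np.mean(np.exp(1j * (phi[None, :] - 2.0 * np.pi * grid[:, None] * x[None, :])), axis=1))
    best = resultants.max()
    candidates = grid[resultants >= best - 1e-12]
    a = float(candidates[np.argmin(np.abs(candidates))])
    # local refinement around the winner
    fine = np.arange(a - coarse_step, a + coarse_step, coarse_step / 10)
    fine_res = np.abs(np.mean(np.exp(1j * (phi[None, :] - 2.0 * np.pi * fine[:, None] * x[None, :])), axis=1))
    best_f = fine_res.max()
    cand_f = fine[fine_res >= best_f - 1e-12]
    a = float(cand_f[np.argmin(np.abs(cand_f))])
    offset = circ_mean(phi - 2.0 * np.pi * a * x)
    # correlation against 2 pi |a| x so that decreasing phase across the
    # field (precession) yields a negative r
    r, p = circ_lin_corr(wrap_angle(2.0 * np.pi * abs(a) * x), phi)
    if a == 0:
        r, p = 0.0, 1.0
    return PrecessionFit(
        slope=2.0 * np.pi * a,
        phase_offset=float(offset),
        r=float(r),
        p=float(p),
        n_spikes=int(x.size),
    )


def precession_by_state(
    norm_positions,
    phases,
    spike_states,
    n_states: int = 4,
    n_deletions: int = 100,
    seed: int = 0,
    min_spikes_per_state: int = 10,
    min_spikes_total: int = 100,
):
    """Per-state precession fits plus the spike-count-matched control.

    Eligibility: the pooled fit shows significant precession, the field
    holds >= 100 spikes, and every state holds >= 10.  The control
    repeatedly (``n_deletions`` times) deletes spikes at random from
    each state down to the minimum state count, refits, and averages
    slope and r across repetitions.

    Returns (overall_fit, per_state_fits, controlled) where controlled
    maps state -> (mean slope, mean r), or raises ValueError naming the
    failed eligibility rule.
    """
    x = np.asarray(norm_positions, dtype=float)
    phi = np.asarray(phases, dtype=float)
    st = np.asarray(spike_states, dtype=np.int64)
    if x.size < min_spikes_total:
        raise ValueError(f"only {x.size} spikes in field (<{min_spikes_total})")
    counts = np.bincount(st, minlength=n_states)
    if counts.min() < min_spikes_per_state:
        lacking = int(np.argmin(counts))
        raise ValueError(f"state {lacking} has {counts[lacking]} spikes (<{min_spikes_per_state})")
    overall = circular_linear_fit(x, phi)
    if not overall.significant_precession:
        raise ValueError("no significant precession across all spikes")
    per_state = {s: circular_linear_fit(x[st == s], phi[st == s]) for s in range(n_states)}
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    slope_acc = np.zeros(n_states)
    r_acc = np.zeros(n_states)
    for _ in range(n_deletions):
        for s in range(n_states):
            idx = np.flatnonzero(st == s)
            keep = rng.choice(idx, size=target, replace=False) if idx.size > target else idx
            fit = circular_linear_fit(x[keep], phi[keep])
            slope_acc[s] += fit.slope
            r_acc[s] += fit.r
    controlled = {
        s: (slope_acc[s] / n_deletions, r_acc[s] / n_deletions) for s in range(n_states)
    }
    return overall, per_state, controlled


def state_event_spatial_information(
    event_times,
    track_t,
    track_x,
    speed=None,
    **rate_map_kwargs,
) -> float:
    """Skaggs information of state occurrences treated as point events.

    Each theta cycle of a given state is an event at the animal's
    position at the cycle midpoint; the same speed filter and map
    construction as for place cells applies.  Returns bits/event.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no state events")
    rmap = compute_rate_map(event_times, track_t, track_x, speed=speed, **rate_map_kwargs)
    return spatial_information(rmap)
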