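"""Synthetic hippocampal sessions with planted theta-gamma coupling states.

Generates multichannel LFP in which every theta cycle carries one gamma
burst whose frequency and preferred theta phase are drawn from one of
four states selected by a Markov chain, together with place-cell and
interneuron spike trains and a linear-track position trace.  All ground
truth (cycle boundaries, state sequence, burst parameters) is retained
so each downstream analysis stage has a recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .circstats import wrap_angle

#: gravity frequency (Hz) and theta phase (rad) of the four wake states:
#: slow, medium, early-fast, and late-fast gamma.
WAKE_GRAVITY = {
    "S": (36.07, 0.58),
    "M": (99.12, -0.04),
    "EF": (127.72, -2.57),
    "LF": (131.83, 2.12),
}

STATE_NAMES = ("S", "M", "EF", "LF")


@dataclass(frozen=True)
class StatePreset:
    """One planted theta-gamma coupling state."""

    name: str
    burst_freq: float          # Hz, carrier of the per-cycle gamma burst
    burst_phase: float         # rad in (-pi, pi], preferred theta phase
    burst_amp: float = 0.5     # amplitude relative to the theta carrier
    phase_jitter_sd: float = 0.2   # rad, per-cycle jitter of the burst center
    freq_jitter_sd: float = 2.0    # Hz, per-cycle jitter of the carrier

    def __post_init__(self):
        if not (20.0 <= self.burst_freq <= 180.0):
            raise ValueError(f"burst_freq {self.burst_freq} outside [20, 180] Hz")
        if not (-np.pi < self.burst_phase <= np.pi):
            raise ValueError("burst_phase must lie in (-pi, pi]")
        if self.phase_jitter_sd < 0 or self.freq_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")


def default_wake_presets() -> list[StatePreset]:
    """The four wake presets at the reference gravity values.

    S 36.07 Hz @ 0.58 rad, M 99.12 Hz @ -0.04 rad, EF 127.72 Hz @ -2.57 rad,
    LF 131.83 Hz @ 2.12 rad, each with default jitter (2 Hz, 0.2 rad).
    """
    return [
        StatePreset(name, WAKE_GRAVITY[name][0], WAKE_GRAVITY[name][1])
        for name in STATE_NAMES
    ]


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic session.

    Amplitudes are relative to the theta carrier (amplitude 1 by default).
    The background terms — pink noise plus phase-random gamma bursts spread
    uniformly over 20-200 Hz — give every wavelet frequency row its own
    background variance, the statistical property of real LFP that the
    per-frequency z-scoring of the analysis relies on.
    """

    duration: float = 600.0
    fs: float = 625.0
    theta_freq_range: tuple[float, float] = (6.0, 10.0)
    theta_amp: float = 1.0
    theta_freq_walk_sd: float = 0.002   # Hz per sample random walk step
    noise_exponent: float = 1.0         # 1/f^e power slope of the pink noise
    noise_amp: float = 0.15
    burst_phase_sd: float = np.pi / 3   # rad, Gaussian burst envelope SD
    bg_burst_rate: float = 4.0          # background bursts per theta cycle
    bg_burst_amp: float = 0.35
    bg_freq_range: tuple[float, float] = (20.0, 200.0)
    presets: Sequence[StatePreset] = field(default_factory=default_wake_presets)
    transition_matrix: np.ndarray | None = None   # default: uniform 0.25
    n_channels: int = 1
    channel_delay_samples: int = 3      # lag of secondary channels (LFP-LFP PPC)
    n_place_cells: int = 8
    n_interneurons: int = 4
    place_peak_rate: float = 8.0        # Hz at field center
    place_baseline_rate: float = 0.1    # Hz off field
    place_field_sd: float = 12.0        # cm
    precession_slope: float = -2.0 * np.pi  # rad per field traversal
    interneuron_rate: float = 12.0      # Hz mean
    interneuron_kappa: float = 4.0      # von Mises gamma-phase locking depth
    track_length: float = 200.0         # cm
    run_speed: float = 20.0             # cm/s plateau of the trapezoid
    speed_cap: float = 100.0            # cm/s, generated speed never exceeds
    position_fs: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.fs < 625:
            raise ValueError("fs must be >= 625 Hz")
        if self.transition_matrix is None:
            k = len(self.presets)
            self.transition_matrix = np.full((k, k), 1.0 / k)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        _check_stochastic(self.transition_matrix)


@dataclass
class SyntheticSession:
    """A generated session with full ground truth."""

    lfp: np.ndarray                  # (n_channels, n_samples), a.u.
    fs: float
    spike_trains: dict[str, dict]    # unit_id -> {"times": array, "cell_type": str, ...}
    position_t: np.ndarray           # s
    position_x: np.ndarray           # cm
    true_state_seq: np.ndarray       # per-cycle state index
    true_cycle_bounds: np.ndarray    # sample indices, len = n_cycles + 1
    true_theta_phase: np.ndarray     # generator phase per sample, wrapped
    true_burst_freqs: np.ndarray     # per-cycle carrier after jitter, Hz
    true_burst_phases: np.ndarray    # per-cycle center after jitter, rad
    config: SyntheticConfig

    @property
    def n_cycles(self) -> int:
        return len(self.true_state_seq)

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.fs


def _check_stochastic(P: np.ndarray) -> None:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must be nonnegative and sum to 1")


def markov_sequence(P: np.ndarray, n: int, seed, start: int | None = None) -> np.ndarray:
    """Sample a state-index sequence of length ``n`` from the chain ``P``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    P = np.asarray(P, dtype=float)
    _check_stochastic(P)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = P.shape[0]
    out = np.empty(n, dtype=np.int64)
    if n == 0:
        return out
    state = rng.integers(k) if start is None else int(start)
    # cumulative rows + uniform draws: fast inverse-CDF sampling
    cum = np.cumsum(P, axis=1)
    u = rng.random(n)
    for i in range(n):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, k - 1)
        out[i] = state
    return out


def _pink_noise(n: int, exponent: float, rng: np.random.Generator, fs: float) -> np.ndarray:
    white = rng.normal(0.0, 1.0, n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spectrum *= freqs ** (-exponent / 2.0)
    noise = np.fft.irfft(spectrum, n)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _theta_phase_track(cfg: SyntheticConfig, rng: np.random.Generator):
    """Random-walk instantaneous theta frequency, reflected at the band edges."""
    n = int(round(cfg.duration * cfg.fs))
    lo, hi = cfg.theta_freq_range
    steps = rng.normal(0.0, cfg.theta_freq_walk_sd, n)
    freq = np.empty(n)
    f = 0.5 * (lo + hi)
    for i in range(n):
        f += steps[i]
        if f < lo:
            f = 2 * lo - f
        elif f > hi:
            f = 2 * hi - f
        freq[i] = f
    phase = np.cumsum(2.0 * np.pi * freq / cfg.fs)
    return phase, freq


def _gaussian_burst(phase_seg, t_seg, center_phase, carrier_hz, amp, sd_phase, rng):
    dphi = np.angle(np.exp(1j * (phase_seg - center_phase)))
    envelope = amp * np.exp(-(dphi**2) / (2.0 * sd_phase**2))
    return envelope * np.cos(2.0 * np.pi * carrier_hz * t_seg + rng.uniform(0, 2 * np.pi))


def _position_track(cfg: SyntheticConfig, rng: np.random.Generator):
    """Back-and-forth runs on a linear track with a trapezoidal speed profile."""
    dt = 1.0 / cfg.position_fs
    n = int(round(cfg.duration * cfg.position_fs))
    t = np.arange(n) * dt
    x = np.empty(n)
    pos = 0.0
    direction = 1.0
    v = 0.0
    accel = cfg.run_speed / 1.0  # reach plateau in 1 s
    pause = 0.0
    for i in range(n):
        if pause > 0:
            pause -= dt
            v = 0.0
        else:
            v = min(v + accel * dt, cfg.run_speed, cfg.speed_cap)
            pos += direction * v * dt
            if pos >= cfg.track_length:
                pos = cfg.track_length
                direction = -1.0
                v = 0.0
                pause = rng.uniform(0.5, 2.0)
            elif pos <= 0.0:
                pos = 0.0
                direction = 1.0
                v = 0.0
                pause = rng.uniform(0.5, 2.0)
        x[i] = pos
    return t, x


def _place_cell_spikes(cfg, rng, t_pos, x_pos, phase, fs, centers):
    """Inhomogeneous-Poisson place cells with linear phase precession.

    Rate is Gaussian in position; each spike's theta phase advances
    linearly with the normalized position within +/-2 SD of the center.
    Spikes are drawn by thinning at the LFP sample resolution.
    """
    n = phase.size
    t_hi = np.arange(n) / fs
    x_hi = np.interp(t_hi, t_pos, x_pos)
    trains = {}
    for ci, center in enumerate(centers):
        rate = cfg.place_baseline_rate + (cfg.place_peak_rate - cfg.place_baseline_rate) * np.exp(
            -((x_hi - center) ** 2) / (2.0 * cfg.place_field_sd**2)
        )
        p_spike = rate / fs
        draws = rng.random(n)
        idx = np.flatnonzero(draws < p_spike)
        if idx.size:
            # phase precession: target phase decreases across the field
            frac = (x_hi[idx] - (center - 2 * cfg.place_field_sd)) / (4 * cfg.place_field_sd)
            frac = np.clip(frac, 0.0, 1.0)
            target = np.pi + cfg.precession_slope * frac
            current = wrap_angle(phase[idx])
            # accept spikes whose theta phase is near the precession target
            keep = np.abs(np.angle(np.exp(1j * (current - target)))) < 1.2
            off_field = np.abs(x_hi[idx] - center) > 2.5 * cfg.place_field_sd
            idx = idx[keep | off_field]
        times = np.unique(idx / fs + rng.uniform(0, 0.5 / fs, idx.size))
        trains[f"pc{ci:02d}"] = {
            "times": times,
            "cell_type": "pyramidal",
            "field_center_cm": float(center),
        }
    return trains


def _interneuron_spikes(cfg, rng, gamma_env, carrier_phase, fs):
    """Interneurons locked to the ongoing gamma burst.

    Thinned inhomogeneous Poisson with rate proportional to the burst
    envelope times (1 + cos of the burst carrier phase), so spikes
    cluster on gamma cycles of the state's burst.
    """
    n = gamma_env.size
    env = gamma_env / max(gamma_env.mean(), 1e-12)
    modulation = env * np.exp(cfg.interneuron_kappa * (np.cos(carrier_phase) - 1.0))
    modulation /= max(modulation.mean(), 1e-12)
    trains = {}
    for ii in range(cfg.n_interneurons):
        rate = cfg.interneuron_rate * modulation
        idx = np.flatnonzero(rng.random(n) < rate / fs)
        times = np.unique(idx / fs + rng.uniform(0, 0.5 / fs, idx.size))
        trains[f"int{ii:02d}"] = {"times": times, "cell_type": "interneuron"}
    return trains


def simulate_session(config: SyntheticConfig) -> SyntheticSession:
    """Generate a session; identical config and seed give identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration * fs))
    t = np.arange(n) / fs

    phase, _ = _theta_phase_track(cfg, rng)
    theta = cfg.theta_amp * np.cos(phase)

    cycle_index = np.floor(phase / (2.0 * np.pi)).astype(np.int64)
    bounds = np.flatnonzero(np.diff(cycle_index) > 0) + 1
    if len(bounds) < 51:
        raise ValueError(
            f"duration {cfg.duration} s yields only {max(len(bounds) - 1, 0)} theta "
            "cycles; at least 50 are required"
        )
    n_cycles = len(bounds) - 1

    k = len(cfg.presets)
    states = markov_sequence(cfg.transition_matrix, n_cycles, rng)

    gamma = np.zeros(n)
    gamma_env = np.zeros(n)
    carrier_phase = np.zeros(n)
    burst_freqs = np.empty(n_cycles)
    burst_phases = np.empty(n_cycles)
    lo_bg, hi_bg = cfg.bg_freq_range
    for i in range(n_cycles):
        a, b = bounds[i], bounds[i + 1]
        preset = cfg.presets[states[i]]
        f_burst = preset.burst_freq + rng.normal(0.0, preset.freq_jitter_sd)
        p_burst = wrap_angle(preset.burst_phase + rng.normal(0.0, preset.phase_jitter_sd))
        burst_freqs[i] = f_burst
        burst_phases[i] = p_burst
        phi0 = rng.uniform(0, 2 * np.pi)
        psi = 2.0 * np.pi * f_burst * t[a:b] + phi0
        dphi = np.angle(np.exp(1j * (phase[a:b] - p_burst)))
        envelope = preset.burst_amp * np.exp(-(dphi**2) / (2.0 * cfg.burst_phase_sd**2))
        gamma[a:b] += envelope * np.cos(psi)
        gamma_env[a:b] += envelope
        carrier_phase[a:b] = psi
        for _ in range(rng.poisson(cfg.bg_burst_rate)):
            f_bg = rng.uniform(lo_bg, hi_bg)
            p_bg = rng.uniform(-np.pi, np.pi)
            gamma[a:b] += _gaussian_burst(
                phase[a:b], t[a:b], p_bg, f_bg, cfg.bg_burst_amp, cfg.burst_phase_sd, rng
            )

    clean = theta + gamma
    channels = []
    for ch in range(cfg.n_channels):
        noise = cfg.noise_amp * _pink_noise(n, cfg.noise_exponent, rng, fs)
        if ch == 0:
            channels.append(clean + noise)
        else:
            lag = cfg.channel_delay_samples * ch
            delayed = np.roll(clean, lag)
            delayed[:lag] = clean[0]
            channels.append(delayed + noise)
    lfp = np.vstack(channels)

    t_pos, x_pos = _position_track(cfg, rng)
    spikes: dict[str, dict] = {}
    if cfg.n_place_cells > 0:
        margin = 2.0 * cfg.place_field_sd
        centers = np.linspace(margin, cfg.track_length - margin, cfg.n_place_cells)
        spikes.update(_place_cell_spikes(cfg, rng, t_pos, x_pos, phase, fs, centers))
    if cfg.n_interneurons > 0:
        spikes.update(_interneuron_spikes(cfg, rng, gamma_env, carrier_phase, fs))

    return SyntheticSession(
        lfp=lfp,
        fs=fs,
        spike_trains=spikes,
        position_t=t_pos,
        position_x=x_pos,
        true_state_seq=states,
        true_cycle_bounds=bounds,
        true_theta_phase=wrap_angle(phase),
        true_burst_freqs=burst_freqs,
        true_burst_phases=burst_phases,
        config=cfg,
    )
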