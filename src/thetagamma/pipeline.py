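"""End-to-end session processing.

`run_session` takes an in-memory session (or the arrays read from a
session bundle) through cycle detection, FPP computation, state
clustering, and dynamics; `run_pipeline` orchestrates the on-disk
stages used by the CLI, stamping every output directory with
provenance (package version, seed, parameter hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__, dynamics, fpp, io, preprocess, states, synchrony
from .synth import SyntheticConfig, SyntheticSession, simulate_session

log = logging.getLogger("thetagamma")


@dataclass
class SessionResult:
    cycles: list
    phase: np.ndarray
    zpower: np.ndarray
    fpps: np.ndarray
    model: states.StateModel
    stats: dynamics.TransitionStats
    channel: int


def analyze_lfp(
    lfp: np.ndarray,
    fs: float,
    seed: int = 0,
    channel: int | None = None,
    k: int | None = None,
    keep_intervals=None,
) -> SessionResult:
    """Cycle detection -> FPP -> clustering -> dynamics for one epoch.

    ``keep_intervals`` ((start_s, end_s) pairs, e.g. wake or REM epochs)
    restricts the analysis to cycles fully inside those intervals.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if fs != preprocess.ANALYSIS_FS:
        lfp = np.vstack([preprocess.downsample(c, fs) for c in lfp])
        fs = preprocess.ANALYSIS_FS
    if channel is None:
        channel = preprocess.select_pyramidal_channel(lfp, fs)
    trace = lfp[channel]
    t0 = time.time()
    phase = preprocess.theta_phase(trace, fs)
    cycles = preprocess.detect_theta_cycles(phase, fs)
    if keep_intervals is not None:
        cycles = [
            c for c in cycles
            if any(a <= c.start / fs and c.end / fs <= b for a, b in keep_intervals)
        ]
    log.info("detected %d theta cycles (%.1f s)", len(cycles), time.time() - t0)
    power = fpp.wavelet_power(trace, fs)
    zpower = fpp.smooth_and_zscore(power)
    fpps = fpp.fpp_stack(cycles, zpower, phase)
    log.info("FPP stack %s (%.1f s)", fpps.shape, time.time() - t0)
    model = states.fit_states(fpps, seed=seed, k=k)
    # contiguity: consecutive retained cycles share a boundary sample
    ids = np.zeros(len(cycles), dtype=np.int64)
    for i in range(1, len(cycles)):
        ids[i] = ids[i - 1] + (1 if cycles[i].start == cycles[i - 1].end else 2)
    stats = dynamics.transition_matrix(model.assignments, cycle_ids=ids, n_states=model.k)
    log.info("k=%d, Q=%.3f (%.1f s)", model.k, model.modularity, time.time() - t0)
    return SessionResult(
        cycles=cycles, phase=phase, zpower=zpower, fpps=fpps,
        model=model, stats=stats, channel=channel,
    )


def _provenance(seed, params: dict) -> dict:
    digest = hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()
    return {"version": __version__, "seed": seed, "parameters_sha256": digest[:16]}


def write_simulation(out_dir, config: SyntheticConfig) -> SyntheticSession:
    """Simulate a session and write the bundle (LFP, spikes, position,
    ground truth) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session = simulate_session(config)
    io.write_lfp(out / "lfp.dat", session.lfp, session.fs)
    io.write_spikes_tsv(out / "spikes.tsv", session.spike_trains)
    io.write_position_tsv(out / "position.tsv", session.position_t, session.position_x)
    io.write_truth_tsv(
        out / "ground_truth.tsv",
        session.true_cycle_bounds / session.fs,
        session.true_state_seq,
    )
    io.write_epochs_tsv(out / "epochs.tsv", [(0.0, session.duration, "wake")])
    provenance = _provenance(config.seed, {"duration": config.duration, "fs": config.fs})
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return session


def run_cluster_stage(bundle_dir, out_dir, seed: int = 0, epoch_label: str | None = None) -> SessionResult:
    """Cluster stage; ``epoch_label`` ('wake' or 'REM') restricts the
    analysis to matching intervals of the bundle's epochs.tsv."""
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lfp, fs = io.read_lfp(bundle / "lfp.dat")
    keep = None
    if epoch_label is not None:
        epochs_path = bundle / "epochs.tsv"
        if not epochs_path.exists():
            raise FileNotFoundError(
                f"epoch-restricted analysis ('{epoch_label}') requested but "
                f"{epochs_path} does not exist"
            )
        epochs = io.read_epochs_tsv(epochs_path)
        matching = epochs[epochs["label"] == epoch_label]
        keep = list(zip(matching["start_s"], matching["end_s"]))
    result = analyze_lfp(lfp, fs, seed=seed, keep_intervals=keep)
    io.write_assignments_tsv(
        out / "assignments.tsv", result.cycles, preprocess.ANALYSIS_FS,
        result.model.assignments, result.model.labels,
    )
    io.write_fpp_h5(out / "mean_fpps.h5", result.model.mean_fpps, fpp.FREQS, fpp.PHASE_BIN_CENTERS)
    report = {
        "k": result.model.k,
        "modularity": result.model.modularity,
        "channel": result.channel,
        "gravity": {
            result.model.label_of(j): {
                "freq_hz": result.model.fields[j].gravity_freq,
                "phase_rad": result.model.fields[j].gravity_phase,
                "phase_sd_rad": result.model.fields[j].phase_sd,
            }
            for j in range(result.model.k)
        },
        "provenance": _provenance(seed, {"bundle": str(bundle)}),
    }
    (out / "cluster_report.json").write_text(json.dumps(report, indent=1))
    return result


def run_transitions_stage(result: SessionResult, out_dir) -> None:
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = [result.model.label_of(j) for j in range(result.model.k)]
    pd.DataFrame([result.stats.occurrence], columns=labels).to_csv(
        out / "occurrence.csv", index=False
    )
    pd.DataFrame(result.stats.transitions, index=labels, columns=labels).to_csv(
        out / "transitions.csv"
    )


def run_ppc_stage(bundle_dir, result: SessionResult, out_dir) -> None:
    import pandas as pd

    bundle = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lfp, fs = io.read_lfp(bundle / "lfp.dat")
    if lfp.shape[0] < 2:
        raise RuntimeError("ppc stage needs at least 2 LFP channels")
    other = 0 if result.channel != 0 else 1
    ppc_map = synchrony.lfp_lfp_ppc(
        lfp[result.channel], lfp[other], fs, result.cycles, result.phase
    )
    profiles = {}
    for j in range(result.model.k):
        label = result.model.label_of(j)
        profiles[label] = synchrony.average_ppc_window(ppc_map, result.model.fields[j])
    frame = pd.DataFrame(profiles, index=fpp.FREQS)
    frame.index.name = "freq_hz"
    frame.to_csv(out / "ppc_profiles.csv")


def run_placecells_stage(bundle_dir, result: SessionResult, out_dir) -> None:
    import pandas as pd

    from . import spatial

    bundle = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes = io.read_spikes_tsv(bundle / "spikes.tsv")
    position = io.read_position_tsv(bundle / "position.tsv")
    track_t = position["t_s"].to_numpy()
    track_x = position["x_cm"].to_numpy()
    smoothed, speed = spatial.smooth_position(track_t, track_x)
    rows = []
    for unit_id, group in spikes.groupby("unit_id"):
        if group["cell_type"].iloc[0] != "pyramidal":
            continue
        times = group["t_s"].to_numpy()
        try:
            is_pc, si, si95, peak = spatial.place_cell_test(times, track_t, smoothed, speed=speed)
        except ValueError as exc:
            log.warning("unit %s skipped: %s", unit_id, exc)
            continue
        rows.append((unit_id, si, si95, peak, is_pc))
    pd.DataFrame(
        rows, columns=["unit_id", "si_bits_per_spike", "si_shuffle_95", "peak_rate_hz", "is_place_cell"]
    ).to_csv(out / "place_cells.csv", index=False)


def run_pipeline(bundle_dir, out_dir, seed: int = 0, config: SyntheticConfig | None = None):
    """Run simulate (optional) -> cluster -> transitions -> ppc -> placecells.

    Any stage failure aborts with the stage name and cause.
    """
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    stage = "simulate"
    try:
        if config is not None:
            write_simulation(bundle, config)
        stage = "cluster"
        result = run_cluster_stage(bundle, out, seed=seed)
        stage = "transitions"
        run_transitions_stage(result, out)
        stage = "ppc"
        run_ppc_stage(bundle, result, out)
        stage = "placecells"
        run_placecells_stage(bundle, result, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return result
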