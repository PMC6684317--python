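"""Readers and writers for the package's on-disk formats.

LFP lives in flat binary int16 (sample-major interleaved frames) with a
JSON sidecar {fs, n_channels, gain}, or in HDF5 with the same
attributes.  Event tables (spikes, position, behavioral epochs, state
assignments, ground truth) are TSV with fixed headers.  Array stacks
(FPPs, PPC maps) go to HDF5 with axis attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SPIKES_COLUMNS = ["unit_id", "t_s", "cell_type"]
POSITION_COLUMNS = ["t_s", "x_cm"]
EPOCHS_COLUMNS = ["start_s", "end_s", "label"]
TRUTH_COLUMNS = ["cycle_start_s", "cycle_end_s", "true_state"]
ASSIGN_COLUMNS = ["cycle_start_s", "cycle_end_s", "state_index", "label"]
EPOCH_LABELS = {"wake", "REM", "NREM"}


def write_lfp(path, lfp: np.ndarray, fs: float, gain: float = 1e-3) -> None:
    """Write (n_channels, n_samples) to int16 flat binary + JSON sidecar.

    Samples are quantized as round(value / gain); pick ``gain`` so the
    signal fits int16.
    """
    path = Path(path)
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    quantized = np.round(lfp / gain)
    if np.abs(quantized).max() > 32767:
        raise ValueError("gain too small: signal overflows int16")
    frames = quantized.astype("<i2").T  # sample-major interleaved
    frames.tofile(path)
    sidecar = {"fs": float(fs), "n_channels": int(lfp.shape[0]), "gain": float(gain)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_lfp(path):
    """Read LFP written by :func:`write_lfp` (or HDF5 with a ``/lfp``
    dataset carrying fs/gain attributes).  Returns (lfp, fs) with lfp of
    shape (n_channels, n_samples), scaled by gain."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as handle:
            dataset = handle["lfp"]
            return np.asarray(dataset, dtype=float) * float(dataset.attrs.get("gain", 1.0)), float(
                dataset.attrs["fs"]
            )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("fs", "n_channels", "gain"):
        if key not in sidecar:
            raise KeyError(f"sidecar missing required key '{key}'")
    raw = np.fromfile(path, dtype="<i2")
    n_channels = int(sidecar["n_channels"])
    if raw.size % n_channels:
        raise ValueError(
            f"file length {raw.size} not divisible by n_channels {n_channels}"
        )
    lfp = raw.reshape(-1, n_channels).T.astype(float) * float(sidecar["gain"])
    return lfp, float(sidecar["fs"])


def write_lfp_h5(path, lfp: np.ndarray, fs: float, gain: float = 1.0) -> None:
    with h5py.File(path, "w") as handle:
        dataset = handle.create_dataset("lfp", data=np.atleast_2d(lfp) / gain)
        dataset.attrs["fs"] = float(fs)
        dataset.attrs["gain"] = float(gain)


def _read_tsv(path, columns, numeric):
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in numeric:
        converted = pd.to_numeric(table[col], errors="coerce")
        if converted.isna().any() and len(table):
            row = int(converted.isna().idxmax())
            raise ValueError(f"{path}: non-numeric value in column '{col}' at data row {row}")
        table[col] = converted
    if len(table) == 0:
        import warnings

        warnings.warn(f"{path}: empty data section")
    return table


def read_spikes_tsv(path) -> pd.DataFrame:
    table = _read_tsv(path, SPIKES_COLUMNS, ["t_s"])
    for unit_id, group in table.groupby("unit_id"):
        diffs = np.diff(group["t_s"].to_numpy())
        if np.any(diffs < 0):
            row = int(group.index[np.argmax(diffs < 0) + 1])
            raise ValueError(f"{path}: unit {unit_id} timestamps decrease at data row {row}")
    return table


def read_position_tsv(path) -> pd.DataFrame:
    table = _read_tsv(path, POSITION_COLUMNS, ["t_s", "x_cm"])
    diffs = np.diff(table["t_s"].to_numpy())
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0) + 1)
        raise ValueError(f"{path}: position timestamps not increasing at data row {row}")
    return table


def read_epochs_tsv(path) -> pd.DataFrame:
    table = _read_tsv(path, EPOCHS_COLUMNS, ["start_s", "end_s"])
    bad = ~table["label"].isin(EPOCH_LABELS)
    if bad.any():
        raise ValueError(f"{path}: unknown epoch label at data row {int(bad.idxmax())}")
    return table


def write_spikes_tsv(path, spike_trains: dict) -> None:
    rows = []
    for unit_id, info in spike_trains.items():
        for t in info["times"]:
            rows.append((unit_id, float(t), info["cell_type"]))
    frame = pd.DataFrame(rows, columns=SPIKES_COLUMNS).sort_values(["unit_id", "t_s"])
    frame.to_csv(path, sep="\t", index=False)


def write_position_tsv(path, t, x) -> None:
    pd.DataFrame({"t_s": t, "x_cm": x}).to_csv(path, sep="\t", index=False)


def write_epochs_tsv(path, epochs) -> None:
    pd.DataFrame(epochs, columns=EPOCHS_COLUMNS).to_csv(path, sep="\t", index=False)


def write_truth_tsv(path, bounds_s, states) -> None:
    frame = pd.DataFrame(
        {
            "cycle_start_s": bounds_s[:-1],
            "cycle_end_s": bounds_s[1:],
            "true_state": np.asarray(states, dtype=int),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_assignments_tsv(path, cycles, fs, assignments, labels) -> None:
    frame = pd.DataFrame(
        {
            "cycle_start_s": [c.start / fs for c in cycles],
            "cycle_end_s": [c.end / fs for c in cycles],
            "state_index": np.asarray(assignments, dtype=int),
            "label": [labels.get(int(a), str(int(a))) for a in assignments],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_fpp_h5(path, stack: np.ndarray, freqs: np.ndarray, phase_centers: np.ndarray) -> None:
    with h5py.File(path, "w") as handle:
        dataset = handle.create_dataset("fpp", data=stack)
        dataset.attrs["freq_hz"] = freqs
        dataset.attrs["phase_bin_centers_rad"] = phase_centers


def read_fpp_h5(path):
    with h5py.File(path, "r") as handle:
        dataset = handle["fpp"]
        return (
            np.asarray(dataset),
            np.asarray(dataset.attrs["freq_hz"]),
            np.asarray(dataset.attrs["phase_bin_centers_rad"]),
        )
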