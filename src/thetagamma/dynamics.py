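"""State-sequence dynamics: occurrences, transitions, time courses.

Treats the per-cycle state labels as a Markov chain: occurrence
probabilities, the row-stochastic transition matrix (with gap-aware pair
counting), and occurrence time courses binned from epoch onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TransitionStats:
    occurrence: np.ndarray     # (k,) probabilities, sums to 1
    transitions: np.ndarray    # (k, k) row-stochastic; NaN rows where no counts
    counts: np.ndarray         # (k, k) integer pair counts
    n_cycles: int


def occurrence_probabilities(states, n_states: int = 4) -> np.ndarray:
    """Fraction of cycles in each state."""
    states = np.asarray(states, dtype=np.int64)
    if states.size == 0:
        raise ValueError("empty state sequence")
    counts = np.bincount(states, minlength=n_states).astype(float)
    return counts / counts.sum()


def transition_matrix(
    states,
    cycle_ids=None,
    contiguous_only: bool = True,
    n_states: int = 4,
) -> TransitionStats:
    """Pair counts and row-normalized transition probabilities.

    ``cycle_ids`` are the cycles' positions in the original recording
    (e.g. indices into the detected boundary sequence); when
    ``contiguous_only`` is set, pairs separated by a gap — a rejected
    cycle or an epoch boundary — are excluded.  Rows with no observed
    pairs are emitted as NaN rather than fake probabilities.
    """
    states = np.asarray(states, dtype=np.int64)
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    if states.size >= 2:
        src, dst = states[:-1], states[1:]
        if contiguous_only and cycle_ids is not None:
            ids = np.asarray(cycle_ids, dtype=np.int64)
            keep = np.diff(ids) == 1
            src, dst = src[keep], dst[keep]
        np.add.at(counts, (src, dst), 1)
    row_sums = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        transitions = np.where(row_sums > 0, counts / np.where(row_sums == 0, 1, row_sums), np.nan)
    return TransitionStats(
        occurrence=occurrence_probabilities(states, n_states),
        transitions=transitions,
        counts=counts,
        n_cycles=int(states.size),
    )


def occurrence_time_course(
    states,
    cycle_times,
    epoch_onsets,
    bin_s: float = 4.0,
    horizon_s: float = 120.0,
    n_states: int = 4,
) -> np.ndarray:
    """Per-state occurrence rate in bins from each epoch onset.

    Returns (n_states, n_bins) with the fraction of cycles per state in
    each ``bin_s`` bin from onset to ``horizon_s``, averaged across
    epochs; bins never covered by any cycle are NaN.
    """
    states = np.asarray(states, dtype=np.int64)
    cycle_times = np.asarray(cycle_times, dtype=float)
    epoch_onsets = np.asarray(epoch_onsets, dtype=float)
    if epoch_onsets.size == 0:
        raise ValueError("no epochs supplied")
    n_bins = int(round(horizon_s / bin_s))
    frac_sum = np.zeros((n_states, n_bins))
    bin_seen = np.zeros(n_bins)
    for onset in epoch_onsets:
        rel = cycle_times - onset
        in_epoch = (rel >= 0) & (rel < horizon_s)
        if not in_epoch.any():
            continue
        bins = np.minimum((rel[in_epoch] / bin_s).astype(int), n_bins - 1)
        epoch_states = states[in_epoch]
        for b in np.unique(bins):
            sel = bins == b
            frac = np.bincount(epoch_states[sel], minlength=n_states) / sel.sum()
            frac_sum[:, b] += frac
            bin_seen[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bin_seen > 0, frac_sum / np.where(bin_seen == 0, 1, bin_seen), np.nan)
    return out
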