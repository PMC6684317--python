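"""Clustering theta cycles into theta-gamma coupling states.

Two-stage procedure: Louvain community detection on the correlation
graph of FPP vectors chooses the number of states k, then k-means with
Pearson-correlation distance assigns every cycle.  Each cluster's mean
FPP is summarized by its gamma field (bins above 95% of the peak) and
the field's power-weighted gravity frequency and circular gravity
phase, which drive the S/M/EF/LF labeling.
"""

from __future__ import annotations

import random as _pyrandom
from collections import Counter
from dataclasses import dataclass, field

import igraph
import numpy as np
from sklearn.cluster import kmeans_plusplus
from sklearn.model_selection import KFold

from . import fpp as fpp_mod
from .circstats import circ_mean, circ_sd

STATE_LABELS = ("S", "M", "EF", "LF")


@dataclass(frozen=True)
class AffinityGraph:
    """Pearson correlation matrix C and adjacency B = C + 1."""

    C: np.ndarray
    B: np.ndarray
    node_ids: np.ndarray


@dataclass(frozen=True)
class GammaField:
    """Thresholded high-power region of a mean FPP with gravity features."""

    mask: np.ndarray            # component containing the peak (81 x 20 bool)
    full_mask: np.ndarray       # all bins >= 95% of peak
    gravity_freq: float         # Hz
    gravity_phase: float        # rad in (-pi, pi]
    phase_sd: float             # rad, power-weighted circular SD over the mask
    peak_value: float           # z-units


@dataclass
class StateModel:
    """Fitted state model for one epoch."""

    k: int
    mean_fpps: np.ndarray               # (k, 81, 20)
    assignments: np.ndarray             # per-cycle state index
    fields: list[GammaField]
    labels: dict[int, str] = field(default_factory=dict)   # state index -> S/M/EF/LF
    modularity: float = np.nan

    def label_of(self, state_index: int) -> str:
        return self.labels.get(state_index, str(state_index))


def _flatten(fpps) -> np.ndarray:
    """Accepts FppMatrix sequences, (n, 81, 20) stacks, or (n, 1620) arrays."""
    rows = [np.ravel(np.asarray(getattr(f, "values", f), dtype=float)) for f in fpps]
    return np.asarray(rows)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows; zero-variance rows become all-zero."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    return np.where(norms > 0, Xc / np.where(norms == 0, 1.0, norms), 0.0)


def build_affinity(fpps) -> AffinityGraph:
    """Pairwise Pearson correlations of flattened FPPs; B = C + 1.

    Zero-variance vectors get correlation 0 with everything (diagonal 1).
    """
    X = _flatten(fpps)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 FPPs")
    Xs = _standardize_rows(X)
    C = Xs @ Xs.T
    np.fill_diagonal(C, 1.0)
    B = C + 1.0
    return AffinityGraph(C=C, B=B, node_ids=np.arange(X.shape[0]))


def modularity(B: np.ndarray, labels: np.ndarray) -> float:
    """Plain Q-modularity of a weighted partition.

    Q = (1/m) sum_ij (B_ij - k_i k_j / m) delta(sigma_i, sigma_j) over the
    off-diagonal adjacency (self-loops excluded), with m the total weight
    sum and k_i the weighted degree.
    """
    B = np.asarray(B, dtype=float).copy()
    np.fill_diagonal(B, 0.0)
    labels = np.asarray(labels)
    m = B.sum()
    if m <= 0:
        return 0.0
    k = B.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(np.sum((B - np.outer(k, k) / m)[same]) / m)


def community_k(
    graph: AffinityGraph,
    n_runs: int = 10,
    seed: int = 0,
    min_size_frac: float = 0.01,
) -> tuple[int, float]:
    """Louvain community detection; returns (modal k, best Q).

    k per run counts communities holding at least ``min_size_frac`` of
    nodes; the returned k is the mode over ``n_runs`` seeded restarts.
    """
    n = graph.B.shape[0]
    if n < 10:
        raise ValueError("community detection needs >= 10 nodes")
    B = graph.B.copy()
    np.fill_diagonal(B, 0.0)
    g = igraph.Graph.Weighted_Adjacency(B.tolist(), mode="undirected", attr="weight", loops=False)
    ks = []
    best_q = -np.inf
    for run in range(n_runs):
        igraph.set_random_number_generator(_pyrandom.Random(int(seed) * 1000 + run))
        part = g.community_multilevel(weights="weight")
        sizes = np.asarray(part.sizes())
        ks.append(int(np.sum(sizes >= min_size_frac * n)))
        q = part.modularity
        if q > best_q:
            best_q = q
    modal_k = Counter(ks).most_common(1)[0][0]
    return modal_k, float(best_q)


def kmeans_correlation(
    fpps,
    k: int,
    n_replicates: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means with Pearson-correlation distance D = 1 - C.

    Vectors are standardized to zero mean and unit norm, making the
    objective spherical k-means; seeding is k-means++ and the best of
    ``n_replicates`` by total within-cluster distance wins.  Returns
    (assignments, mean FPPs of shape (k, 81, 20) as unstandardized
    member means).
    """
    X = _flatten(fpps)
    n = X.shape[0]
    if k < 1 or n < k:
        raise ValueError("need k >= 1 and at least k FPPs")
    Xs = _standardize_rows(X)
    degenerate = ~Xs.any(axis=1)
    rng = np.random.default_rng(seed)
    best_obj, best_labels = np.inf, None
    for rep in range(n_replicates):
        centroids, _ = kmeans_plusplus(Xs, k, random_state=int(rng.integers(2**31 - 1)))
        centroids = _standardize_rows(centroids)
        prev_obj = np.inf
        for _ in range(max_iter):
            sim = Xs @ centroids.T
            labels = np.argmax(sim, axis=1)
            obj = float(np.sum(1.0 - sim[np.arange(n), labels]))
            new_centroids = np.empty_like(centroids)
            for j in range(k):
                members = labels == j
                if not members.any():
                    # re-seed an empty cluster at the farthest point
                    farthest = int(np.argmin(sim.max(axis=1)))
                    new_centroids[j] = Xs[farthest]
                else:
                    new_centroids[j] = Xs[members].mean(axis=0)
            new_centroids = _standardize_rows(new_centroids)
            if abs(prev_obj - obj) <= tol:
                centroids = new_centroids
                break
            prev_obj = obj
            centroids = new_centroids
        if obj < best_obj:
            best_obj, best_labels = obj, labels.copy()
            best_centroids = centroids.copy()
    labels = best_labels
    if degenerate.any():
        # zero-variance cycles: nearest centroid in Euclidean distance on raw vectors
        raw_centroids = np.vstack(
            [X[labels == j].mean(axis=0) if np.any(labels == j) else np.zeros(X.shape[1]) for j in range(k)]
        )
        for i in np.flatnonzero(degenerate):
            labels[i] = int(np.argmin(np.linalg.norm(raw_centroids - X[i], axis=1)))
    mean_fpps = np.stack(
        [
            X[labels == j].mean(axis=0).reshape(fpp_mod.N_FREQS, fpp_mod.N_PHASE_BINS)
            if np.any(labels == j)
            else np.zeros((fpp_mod.N_FREQS, fpp_mod.N_PHASE_BINS))
            for j in range(k)
        ]
    )
    return labels, mean_fpps


def _peak_component(mask: np.ndarray, peak_idx: tuple[int, int]) -> np.ndarray:
    """Connected component of ``mask`` containing ``peak_idx``.

    4-connectivity, circular in the phase direction (columns), not in
    frequency (rows).
    """
    from collections import deque

    n_f, n_p = mask.shape
    component = np.zeros_like(mask, dtype=bool)
    queue = deque([peak_idx])
    component[peak_idx] = True
    while queue:
        f, p = queue.popleft()
        neighbors = [
            (f - 1, p),
            (f + 1, p),
            (f, (p - 1) % n_p),
            (f, (p + 1) % n_p),
        ]
        for nf, np_ in neighbors:
            if 0 <= nf < n_f and mask[nf, np_] and not component[nf, np_]:
                component[nf, np_] = True
                queue.append((nf, np_))
    return component


def extract_gamma_field(mean_fpp: np.ndarray, threshold_frac: float = 0.95) -> GammaField:
    """Gamma field of a mean FPP: >=95%-of-peak bins around the peak.

    Gravity frequency is the power-weighted mean of the masked bins'
    frequencies; gravity phase the power-weighted circular mean of their
    phase centers; phase SD the power-weighted circular SD.  The mask is
    restricted to the phase-circularly connected component containing
    the global peak (the full thresholded mask is kept for inspection).
    """
    mean_fpp = np.asarray(mean_fpp, dtype=float)
    peak = mean_fpp.max()
    if peak <= 0:
        raise ValueError("mean FPP has no positive peak")
    full_mask = mean_fpp >= threshold_frac * peak
    peak_idx = np.unravel_index(np.argmax(mean_fpp), mean_fpp.shape)
    mask = _peak_component(full_mask, peak_idx)
    weights = mean_fpp[mask]
    freqs = np.broadcast_to(fpp_mod.FREQS[:, None], mean_fpp.shape)[mask]
    phases = np.broadcast_to(fpp_mod.PHASE_BIN_CENTERS[None, :], mean_fpp.shape)[mask]
    gravity_freq = float(np.sum(weights * freqs) / weights.sum())
    gravity_phase = circ_mean(phases, weights)
    phase_sd = circ_sd(phases, weights)
    return GammaField(
        mask=mask,
        full_mask=full_mask,
        gravity_freq=gravity_freq,
        gravity_phase=gravity_phase,
        phase_sd=phase_sd,
        peak_value=float(peak),
    )


def label_states(fields: list[GammaField]) -> dict[int, str]:
    """Map 4 gamma fields to S/M/EF/LF.

    The two lowest gravity frequencies are S and M; of the two fast
    fields, EF is the one whose gravity phase follows the theta trough
    (phase pi) by the smaller offset.
    """
    if len(fields) != 4:
        raise ValueError("labeling requires exactly 4 fields")
    freqs = np.array([f.gravity_freq for f in fields])
    if np.min(np.diff(np.sort(freqs))) < 1e-9:
        raise ValueError("degenerate clustering: tied gravity frequencies")
    order = np.argsort(freqs)
    labels = {int(order[0]): "S", int(order[1]): "M"}
    fast = [int(order[2]), int(order[3])]
    offsets = [
        float(np.mod(fields[i].gravity_phase - np.pi, 2.0 * np.pi)) for i in fast
    ]
    ef = fast[int(np.argmin(offsets))]
    lf = fast[1 - int(np.argmin(offsets))]
    labels[ef] = "EF"
    labels[lf] = "LF"
    return labels


def fit_states(
    fpps,
    seed: int = 0,
    community_subsample: int = 2000,
    n_community_runs: int = 10,
    n_replicates: int = 10,
    k: int | None = None,
) -> StateModel:
    """Full clustering stage: pick k by community detection (on a
    subsample of at most ``community_subsample`` cycles), assign by
    correlation k-means, extract gamma fields, and label S/M/EF/LF when
    k = 4."""
    X = _flatten(fpps)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    q = np.nan
    if k is None:
        idx = rng.choice(n, size=min(community_subsample, n), replace=False)
        graph = build_affinity(X[idx])
        k, q = community_k(graph, n_runs=n_community_runs, seed=int(rng.integers(2**31 - 1)))
    labels, mean_fpps = kmeans_correlation(
        X, k, n_replicates=n_replicates, seed=int(rng.integers(2**31 - 1))
    )
    fields = [extract_gamma_field(mean_fpps[j]) for j in range(k)]
    name_map = label_states(fields) if k == 4 else {}
    return StateModel(
        k=k,
        mean_fpps=mean_fpps,
        assignments=labels,
        fields=fields,
        labels=name_map,
        modularity=q,
    )


def intra_inter_correlations(
    fpps,
    assignments: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
):
    """Cross-validated intra- vs max-inter-cluster correlation per cycle.

    Mean FPPs come from training folds only; for each held-out cycle,
    rho_intra is its correlation with its own state's training mean,
    rho_max_inter the maximum over the other states.  Returns
    (rho_intra, rho_max_inter, delta) arrays aligned with the input.
    """
    X = _flatten(fpps)
    assignments = np.asarray(assignments)
    states = np.unique(assignments)
    if states.size < 2:
        raise ValueError("need at least 2 clusters")
    n = X.shape[0]
    Xs = _standardize_rows(X)
    rho_intra = np.full(n, np.nan)
    rho_max_inter = np.full(n, np.nan)
    global_means = {s: X[assignments == s].mean(axis=0) for s in states}
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(X):
        means = {}
        for s in states:
            members = train_idx[assignments[train_idx] == s]
            if members.size == 0:
                import warnings

                warnings.warn(f"state {s} empty in a training fold; using all-fold mean")
                means[s] = global_means[s]
            else:
                means[s] = X[members].mean(axis=0)
        mean_mat = _standardize_rows(np.vstack([means[s] for s in states]))
        corr = Xs[test_idx] @ mean_mat.T
        for row, i in enumerate(test_idx):
            own = np.flatnonzero(states == assignments[i])[0]
            rho_intra[i] = corr[row, own]
            others = np.delete(corr[row], own)
            rho_max_inter[i] = others.max()
    return rho_intra, rho_max_inter, rho_intra - rho_max_inter


def cross_validate_assignments(
    reference_means: np.ndarray,
    test_fpps,
    test_labels: np.ndarray,
) -> float:
    """Accuracy of max-correlation assignment against reference means.

    Reference and test state indices must already correspond (match by
    S/M/EF/LF label before calling).
    """
    reference_means = np.asarray(reference_means, dtype=float)
    X = _flatten(test_fpps)
    test_labels = np.asarray(test_labels)
    k = reference_means.shape[0]
    if test_labels.max(initial=-1) >= k:
        raise ValueError("test labels exceed reference k")
    refs = _standardize_rows(reference_means.reshape(k, -1))
    sim = _standardize_rows(X) @ refs.T
    predicted = np.argmax(sim, axis=1)
    return float(np.mean(predicted == test_labels))
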