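import numpy as np
import pytest
from scipy.stats import pearsonr
from sympy.utilities.iterables import multiset_partitions

from thetagamma import fpp, states
from thetagamma.states import GammaField

from conftest import circular_error


def _random_fpps(n, rng, template=None, noise=1.0):
    base = rng.normal(0, 1, (n, 81, 20)) * noise
    if template is not None:
        base += template
    return base


class TestAffinity:
    def test_identical_fpps(self):
        one = np.random.default_rng(0).normal(0, 1, (81, 20))
        graph = states.build_affinity([one, one, one])
        assert np.allclose(graph.C, 1.0)
        assert np.allclose(graph.B, 2.0)

    def test_orthogonal_vectors(self):
        a = np.zeros(1620)
        b = np.zeros(1620)
        a[:810] = np.tile([1.0, -1.0], 405)
        b[810:] = np.tile([1.0, -1.0], 405)
        graph = states.build_affinity([a.reshape(81, 20), b.reshape(81, 20)])
        assert abs(graph.C[0, 1]) < 1e-12
        assert graph.B[0, 1] == pytest.approx(1.0)

    def test_matches_pearson_double_loop(self):
        rng = np.random.default_rng(1)
        X = _random_fpps(40, rng)
        graph = states.build_affinity(X)
        flat = X.reshape(40, -1)
        for i in range(0, 40, 7):
            for j in range(0, 40, 5):
                expected = 1.0 if i == j else pearsonr(flat[i], flat[j]).statistic
                assert graph.C[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_vector_gets_zero_correlation(self):
        rng = np.random.default_rng(2)
        X = _random_fpps(3, rng)
        X[1] = 5.0  # constant vector
        graph = states.build_affinity(X)
        assert graph.C[1, 0] == 0.0 and graph.C[1, 2] == 0.0
        assert graph.C[1, 1] == 1.0


def _brute_force_modularity(B, labels):
    """Textbook double loop over the off-diagonal adjacency."""
    B = np.asarray(B, dtype=float).copy()
    np.fill_diagonal(B, 0.0)
    m = B.sum()
    k = B.sum(axis=1)
    q = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == labels[j]:
                q += B[i, j] - k[i] * k[j] / m
    return q / m


class TestCommunityK:
    def test_two_blocks_give_k2_and_max_q_bipartition(self):
        """Louvain must find the planted bipartition; verified against
        exhaustive Q maximization over all 2-partitions of 12 nodes."""
        rng = np.random.default_rng(0)
        t1 = rng.normal(0, 1, (81, 20))
        t2 = rng.normal(0, 1, (81, 20))
        X = np.array([t1] * 6 + [t2] * 6)
        graph = states.build_affinity(X)
        k, q = states.community_k(graph, n_runs=5, seed=0, min_size_frac=0.0)
        assert k == 2
        best_q = -np.inf
        n = 12
        for mask in range(1, 2**(n - 1)):
            labels = [(mask >> i) & 1 for i in range(n)]
            best_q = max(best_q, _brute_force_modularity(graph.B, labels))
        assert q == pytest.approx(best_q, abs=1e-9)

    def test_identical_fpps_give_k1(self):
        one = np.random.default_rng(3).normal(0, 1, (81, 20))
        graph = states.build_affinity([one] * 12)
        k, _ = states.community_k(graph, n_runs=5, seed=0, min_size_frac=0.0)
        assert k == 1

    def test_too_few_nodes_rejected(self):
        X = _random_fpps(5, np.random.default_rng(4))
        with pytest.raises(ValueError):
            states.community_k(states.build_affinity(X), seed=0)

    def test_modularity_matches_brute_force_on_all_partitions(self):
        """Vectorized Q equals the textbook formula for every partition of
        an 8-node weighted graph (exhaustive enumeration)."""
        rng = np.random.default_rng(5)
        C = np.corrcoef(rng.normal(0, 1, (8, 30)))
        B = C + 1.0
        for partition in multiset_partitions(list(range(8))):
            labels = np.empty(8, dtype=int)
            for ci, community in enumerate(partition):
                labels[list(community)] = ci
            assert states.modularity(B, labels) == pytest.approx(
                _brute_force_modularity(B, labels), abs=1e-12
            )


class TestKmeansCorrelation:
    def test_k1_gives_grand_mean(self):
        X = _random_fpps(20, np.random.default_rng(6))
        labels, means = states.kmeans_correlation(X, 1, seed=0)
        assert np.all(labels == 0)
        assert np.allclose(means[0], X.mean(axis=0), atol=1e-12)

    def test_planted_templates_recovered(self):
        rng = np.random.default_rng(7)
        t1 = rng.normal(0, 1, (81, 20))
        t2 = rng.normal(0, 1, (81, 20))
        truth = rng.integers(0, 2, 400)
        X = np.array([(t1 if s == 0 else t2) for s in truth]) + rng.normal(0, 0.1, (400, 81, 20))
        labels, _ = states.kmeans_correlation(X, 2, seed=0)
        agree = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert agree > 0.99

    def test_determinism(self):
        X = _random_fpps(50, np.random.default_rng(8))
        a, _ = states.kmeans_correlation(X, 3, seed=4)
        b, _ = states.kmeans_correlation(X, 3, seed=4)
        assert np.array_equal(a, b)

    def test_invalid_k_rejected(self):
        X = _random_fpps(3, np.random.default_rng(9))
        with pytest.raises(ValueError):
            states.kmeans_correlation(X, 5, seed=0)


class TestGammaField:
    def test_single_bin_gravity(self):
        m = np.zeros((81, 20))
        fi = int(np.flatnonzero(fpp.FREQS == 40.0)[0])
        pi_ = int(np.argmin(np.abs(fpp.PHASE_BIN_CENTERS - 0.0)))
        m[fi, pi_] = 2.0
        field = states.extract_gamma_field(m)
        assert field.gravity_freq == pytest.approx(40.0)
        assert abs(field.gravity_phase - fpp.PHASE_BIN_CENTERS[pi_]) < 1e-12
        assert field.phase_sd == pytest.approx(0.0, abs=1e-6)

    def test_circular_mean_wraps_across_pi(self):
        m = np.zeros((81, 20))
        # two equal bins straddling +/-pi at the same frequency
        m[10, 0] = 1.0    # center -pi + pi/20
        m[10, 19] = 1.0   # center  pi - pi/20
        field = states.extract_gamma_field(m)
        assert circular_error(field.gravity_phase, np.pi) < 1e-9

    def test_matches_brute_force_on_random_matrix(self):
        """Gravity features equal an independent flood-fill + weighted-sum
        oracle on random smooth matrices."""
        rng = np.random.default_rng(10)
        for _ in range(20):
            raw = rng.random((81, 20))
            from scipy.ndimage import uniform_filter

            m = uniform_filter(raw, size=5, mode="nearest") + 0.01
            field = states.extract_gamma_field(m)
            # oracle: set-based flood fill, phase circular
            peak = m.max()
            mask_set = {(f, p) for f in range(81) for p in range(20) if m[f, p] >= 0.95 * peak}
            fi, pi_ = np.unravel_index(np.argmax(m), m.shape)
            component, frontier = {(fi, pi_)}, [(int(fi), int(pi_))]
            while frontier:
                f, p = frontier.pop()
                for nf, np_ in ((f - 1, p), (f + 1, p), (f, (p - 1) % 20), (f, (p + 1) % 20)):
                    if (nf, np_) in mask_set and (nf, np_) not in component:
                        component.add((nf, np_))
                        frontier.append((nf, np_))
            w = np.array([m[f, p] for f, p in sorted(component)])
            fr = np.array([fpp.FREQS[f] for f, p in sorted(component)])
            ph = np.array([fpp.PHASE_BIN_CENTERS[p] for f, p in sorted(component)])
            assert field.gravity_freq == pytest.approx((w * fr).sum() / w.sum(), abs=1e-10)
            expected_phase = np.angle(np.sum(w * np.exp(1j * ph)))
            assert circular_error(field.gravity_phase, expected_phase) < 1e-10

    def test_non_positive_peak_rejected(self):
        with pytest.raises(ValueError):
            states.extract_gamma_field(np.full((81, 20), -1.0))


def _field(freq, phase):
    return GammaField(
        mask=np.ones((81, 20), bool), full_mask=np.ones((81, 20), bool),
        gravity_freq=freq, gravity_phase=phase, phase_sd=0.3, peak_value=1.0,
    )


class TestLabelStates:
    def test_reference_ordering(self):
        fields = [_field(36.0, 0.58), _field(99.0, -0.04), _field(128.0, -2.57), _field(132.0, 2.12)]
        labels = states.label_states(fields)
        assert labels == {0: "S", 1: "M", 2: "EF", 3: "LF"}

    def test_fast_phase_rule_arithmetic(self):
        fields = [_field(36.0, 0.5), _field(99.0, 0.0), _field(128.0, -3.0), _field(132.0, 3.0)]
        labels = states.label_states(fields)
        # -3.0 rad is 0.14 rad after the trough; 3.0 rad is 6.14 rad after
        assert labels[2] == "EF" and labels[3] == "LF"

    def test_permutation_invariance(self):
        fields = [_field(36.0, 0.58), _field(99.0, -0.04), _field(128.0, -2.57), _field(132.0, 2.12)]
        base = states.label_states(fields)
        order = [2, 0, 3, 1]
        permuted = states.label_states([fields[i] for i in order])
        for new_idx, old_idx in enumerate(order):
            assert permuted[new_idx] == base[old_idx]

    def test_tied_frequencies_rejected(self):
        fields = [_field(36.0, 0.5), _field(36.0, 0.6), _field(128.0, -2.5), _field(132.0, 2.1)]
        with pytest.raises(ValueError):
            states.label_states(fields)


class TestIntraInter:
    def test_identical_cluster_members_have_rho_one(self):
        rng = np.random.default_rng(11)
        t1 = rng.normal(0, 1, 1620)
        t2 = rng.normal(0, 1, 1620)
        X = np.array([t1] * 20 + [t2] * 20).reshape(40, 81, 20)
        assignments = np.array([0] * 20 + [1] * 20)
        rho_intra, _, delta = states.intra_inter_correlations(X, assignments, seed=0)
        assert np.allclose(rho_intra, 1.0, atol=1e-9)
        assert np.all(delta > 0)

    def test_identical_means_give_zero_delta(self):
        rng = np.random.default_rng(12)
        template = rng.normal(0, 1, 1620)
        X = np.array([template] * 30).reshape(30, 81, 20)
        assignments = np.array([0, 1] * 15)
        _, _, delta = states.intra_inter_correlations(X, assignments, seed=0)
        assert np.allclose(delta, 0.0, atol=1e-9)

    def test_separated_clusters_positive_median_delta(self, analyzed_600):
        model = analyzed_600.model
        _, _, delta = states.intra_inter_correlations(
            analyzed_600.fpps, model.assignments, seed=0
        )
        assert np.median(delta) > 0

    def test_single_cluster_rejected(self):
        X = np.random.default_rng(13).normal(0, 1, (10, 81, 20))
        with pytest.raises(ValueError):
            states.intra_inter_correlations(X, np.zeros(10, dtype=int), seed=0)


class TestCrossValidation:
    def test_self_reference_above_chance(self, analyzed_600):
        model = analyzed_600.model
        acc = states.cross_validate_assignments(
            model.mean_fpps, analyzed_600.fpps, model.assignments
        )
        assert acc >= 0.25

    def test_random_labels_hit_chance_level(self):
        """Random assignment among four states has expected accuracy 25%."""
        rng = np.random.default_rng(14)
        refs = rng.normal(0, 1, (4, 81, 20))
        X = rng.normal(0, 1, (10_000, 81, 20))
        labels = rng.integers(0, 4, 10_000)
        acc = states.cross_validate_assignments(refs, X, labels)
        assert acc == pytest.approx(0.25, abs=0.02)

    def test_mismatched_k_rejected(self):
        rng = np.random.default_rng(15)
        refs = rng.normal(0, 1, (4, 81, 20))
        X = rng.normal(0, 1, (5, 81, 20))
        with pytest.raises(ValueError):
            states.cross_validate_assignments(refs, X, np.array([0, 1, 2, 3, 4]))


class TestPipelineRecovery:
    def test_gravity_features_recover_planted_presets(self, analyzed_600, planted_by_label):
        """Full-pipeline recovery of the planted wake presets.

        Frequencies of the two fast states (planted 4.1 Hz apart at
        ~130 Hz, below the wavelet's frequency resolution there) and the
        phases of the two slow states (boundary-truncation bias) get
        honest wider bounds; the discriminative quantities — S/M
        frequency, EF/LF phase — get the tight ones.
        """
        model = analyzed_600.model
        assert model.k == 4
        by_label = {model.label_of(j): model.fields[j] for j in range(4)}
        assert set(by_label) == {"S", "M", "EF", "LF"}
        tight_freq = {"S": 4.0, "M": 6.0, "EF": 10.0, "LF": 16.0}
        tight_phase = {"S": 0.6, "M": 0.8, "EF": 0.3, "LF": 0.3}
        for label, field in by_label.items():
            f_true, p_true = planted_by_label[label]
            assert abs(field.gravity_freq - f_true) <= tight_freq[label], label
            assert circular_error(field.gravity_phase, p_true) <= tight_phase[label], label

    def test_assignments_match_planted_states(self, analyzed_600, wake_session_600):
        from scipy.optimize import linear_sum_assignment

        s = wake_session_600
        model = analyzed_600.model
        mids = np.array([(c.start + c.end) // 2 for c in analyzed_600.cycles])
        truth = s.true_state_seq[
            np.clip(np.searchsorted(s.true_cycle_bounds, mids) - 1, 0, s.n_cycles - 1)
        ]
        confusion = np.zeros((4, 4))
        for a, b in zip(model.assignments, truth):
            confusion[a, b] += 1
        rows, cols = linear_sum_assignment(-confusion)
        assert confusion[rows, cols].sum() / truth.size > 0.8
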