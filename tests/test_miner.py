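import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from cosplice.miner import (
    DegenerateSliceError,
    FrequentCoSplicingCluster,
    MiningConfig,
    RelaxationState,
    extract_representative_patterns,
    mask_pattern,
    mine_all,
    mine_fixed_size,
    norm_f,
    norm_g,
    objective_heaviness,
    optimize_memberships,
    pattern_heaviness,
    refresh_relaxation_weights,
    update_exon_memberships,
    update_network_memberships,
)
from cosplice.network import NetworkTensor

from conftest import planted_clique_tensor, random_tensor


def tensor_from_weights(weights):
    weights = np.asarray(weights, dtype=float)
    m, n = weights.shape[0], weights.shape[1]
    return NetworkTensor(
        [f"e{i:03d}" for i in range(n)], [f"n{k:02d}" for k in range(m)], weights
    )


class TestObjectiveAndNorms:
    def test_single_edge_counted_once(self):
        t = tensor_from_weights([[[0, 0.8], [0.8, 0]]])
        assert objective_heaviness(t, np.ones(2), np.ones(1)) == pytest.approx(0.8)

    def test_all_ones_tensor(self):
        w = np.ones((2, 3, 3))
        for k in range(2):
            np.fill_diagonal(w[k], 0.0)
        t = tensor_from_weights(w)
        assert objective_heaviness(t, np.ones(3), np.ones(2)) == pytest.approx(6.0)

    def test_zero_network_vector(self):
        t = tensor_from_weights([[[0, 0.8], [0.8, 0]]])
        assert objective_heaviness(t, np.ones(2), np.zeros(1)) == 0.0

    def test_dimension_mismatch_rejected(self):
        t = tensor_from_weights([[[0, 0.8], [0.8, 0]]])
        with pytest.raises(ValueError):
            objective_heaviness(t, np.ones(3), np.ones(1))

    def test_unit_basis_vector_norms(self):
        e = np.array([0.0, 1.0, 0.0])
        assert norm_f(e, p=0.8, alpha=0.2) == pytest.approx(1.0)
        assert norm_g(e, q=10.0) == pytest.approx(1.0)

    def test_mixed_norm_direct_evaluation(self):
        # 0.2 * 2^(1/0.8) + 0.8 * 2^(1/2)
        expected = 0.2 * 2 ** 1.25 + 0.8 * 2 ** 0.5
        assert norm_f(np.ones(2), p=0.8, alpha=0.2) == pytest.approx(expected, rel=1e-12)
        assert norm_g(np.ones(2), q=10.0) == pytest.approx(2 ** 0.1, rel=1e-12)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            norm_f(np.array([1.0, -0.1]), p=0.8, alpha=0.2)
        with pytest.raises(ValueError):
            norm_g(np.array([-1.0]), q=10.0)

    def test_norms_positively_homogeneous(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 6)
        for c in (0.5, 2.0, 7.3):
            assert norm_f(c * x, 0.8, 0.2) == pytest.approx(c * norm_f(x, 0.8, 0.2))
            assert norm_g(c * x, 10.0) == pytest.approx(c * norm_g(x, 10.0))


def numeric_y_max(w, q):
    """Constrained maximization of sum w_k y_k over ||y||_q = 1, y >= 0."""
    m = len(w)
    res = minimize(
        lambda y: -float(w @ y),
        np.full(m, (1.0 / m) ** (1.0 / q)),
        method="SLSQP",
        bounds=[(0, 1)] * m,
        constraints={"type": "eq", "fun": lambda y: np.sum(y**q) - 1.0},
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x


class TestNetworkUpdate:
    def test_mass_on_only_nonzero_slice(self):
        w = np.zeros((2, 3, 3))
        w[0, 0, 1] = w[0, 1, 0] = 1.0
        t = tensor_from_weights(w)
        y = update_network_memberships(t, np.array([1.0, 1.0, 0.0]), q=10.0)
        assert y == pytest.approx([1.0, 0.0])

    def test_equal_scores_give_equal_components(self):
        w = np.zeros((2, 2, 2))
        w[:, 0, 1] = w[:, 1, 0] = 1.0
        t = tensor_from_weights(w)
        y = update_network_memberships(t, np.ones(2), q=10.0)
        assert y == pytest.approx([2 ** -0.1, 2 ** -0.1])

    def test_two_to_one_scores(self):
        w = np.zeros((2, 2, 2))
        w[0, 0, 1] = w[0, 1, 0] = 1.0
        w[1, 0, 1] = w[1, 1, 0] = 0.5
        t = tensor_from_weights(w)
        y = update_network_memberships(t, np.ones(2), q=10.0)
        z = 2 ** (1 / 9)
        denom = (z**10 + 1) ** 0.1
        assert y == pytest.approx([z / denom, 1 / denom], abs=1e-9)

    def test_closed_form_matches_numeric_maximizer(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = rng.integers(2, 6)
            scores = rng.uniform(0, 2, m)
            q = 10.0
            y_closed = scores ** (1 / (q - 1))
            y_closed = y_closed / norm_g(y_closed, q)
            y_num = numeric_y_max(scores, q)
            y_num = y_num / norm_g(y_num, q)
            assert float(scores @ y_closed) >= float(scores @ y_num) - 1e-8


class TestRelaxationWeights:
    def test_permutation_symmetry(self):
        v = refresh_relaxation_weights(np.full(4, 0.3), p=0.8, alpha=0.2)
        assert np.allclose(v, v[0])

    def test_zero_component_stays_finite(self):
        v = refresh_relaxation_weights(np.array([1.0, 0.0]), p=0.8, alpha=0.2)
        assert np.all(np.isfinite(v)) and np.all(v > 0)
        assert v[0] == pytest.approx(0.5, abs=1e-3)

    def test_matches_finite_difference_gradient(self):
        p, alpha, eps = 0.8, 0.2, 1e-10

        def fbar(u):
            return alpha * np.sum((u + eps) ** (p / 2)) ** (1 / p) + (
                1 - alpha
            ) * np.sqrt(np.sum(u) + eps)

        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 1.0, 5)
        u = x**2
        v = refresh_relaxation_weights(x, p, alpha, eps)
        h = 1e-7
        for i in range(len(u)):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            fd = (fbar(up) - fbar(um)) / (2 * h)
            assert v[i] == pytest.approx(fd, rel=1e-4)


class TestExonUpdate:
    def state(self, x, cfg):
        return RelaxationState(v=refresh_relaxation_weights(x, cfg.p, cfg.alpha))

    def test_symmetric_input_stays_symmetric(self):
        cfg = MiningConfig()
        t = tensor_from_weights([[[0, 1.0], [1.0, 0]]])
        x = np.array([0.5, 0.5])
        x2 = update_exon_memberships(t, x, np.ones(1), self.state(x, cfg), cfg)
        assert x2[0] == pytest.approx(x2[1])
        assert norm_f(x2, cfg.p, cfg.alpha) == pytest.approx(1.0, abs=1e-9)

    def test_zero_gradient_signals_degenerate_slice(self):
        cfg = MiningConfig()
        t = tensor_from_weights([np.zeros((3, 3))])
        x = np.full(3, 0.4)
        with pytest.raises(DegenerateSliceError):
            update_exon_memberships(t, x, np.ones(1), self.state(x, cfg), cfg)

    def test_heavy_block_dominates_at_convergence(self):
        cfg = MiningConfig()
        w = np.zeros((1, 6, 6))
        heavy, light = [0, 1, 2], [3, 4, 5]
        for a, b in itertools.combinations(heavy, 2):
            w[0, a, b] = w[0, b, a] = 0.9
        for a, b in itertools.combinations(light, 2):
            w[0, a, b] = w[0, b, a] = 0.1
        t = tensor_from_weights(w)
        x = np.full(6, 1.0)
        x /= norm_f(x, cfg.p, cfg.alpha)
        y = np.ones(1)
        for _ in range(200):
            x = update_exon_memberships(t, x, y, self.state(x, cfg), cfg)
        assert x[heavy].min() > x[light].max()


class TestOptimize:
    def test_feasibility_of_solution(self):
        t = random_tensor(10, 4, seed=5)
        cfg = MiningConfig(seed=0)
        sol = optimize_memberships(t, cfg)
        assert abs(norm_f(sol.x, cfg.p, cfg.alpha) - 1) <= 1e-6
        assert abs(norm_g(sol.y, cfg.q) - 1) <= 1e-6

    def test_objective_trace_non_decreasing(self):
        t = random_tensor(15, 5, seed=11)
        sol = optimize_memberships(t, MiningConfig(seed=0))
        trace = np.array(sol.objective_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_planted_clique_tops_rankings(self, clique_tensor):
        sol = optimize_memberships(clique_tensor, MiningConfig(seed=0))
        top5 = set(np.argsort(-sol.x)[:5])
        assert top5 == {0, 1, 2, 3, 4}
        assert set(np.argsort(-sol.y)[:2]) == {0, 1}

    def test_all_zero_tensor_flags_no_signal(self):
        t = tensor_from_weights(np.zeros((2, 4, 4)))
        sol = optimize_memberships(t, MiningConfig(seed=0))
        assert sol.no_signal and sol.objective == 0.0

    def test_deterministic_per_seed(self):
        t = random_tensor(12, 4, seed=2)
        s1 = optimize_memberships(t, MiningConfig(seed=9, restarts=3))
        s2 = optimize_memberships(t, MiningConfig(seed=9, restarts=3))
        assert np.array_equal(s1.x, s2.x) and np.array_equal(s1.y, s2.y)

    def test_permutation_equivariance(self):
        t = random_tensor(9, 3, seed=21)
        sol = optimize_memberships(t, MiningConfig(seed=0))
        rng = np.random.default_rng(4)
        perm = rng.permutation(t.n_nodes)
        pw = t.weights[:, perm][:, :, perm]
        tp = NetworkTensor([t.node_ids[i] for i in perm], list(t.network_ids), pw)
        sol_p = optimize_memberships(tp, MiningConfig(seed=0))
        assert np.allclose(sol_p.x, sol.x[perm], atol=1e-8)
        assert np.allclose(sol_p.y, sol.y, atol=1e-8)


class TestPatternHeaviness:
    def test_constant_weights(self):
        w = np.full((2, 4, 4), 0.5)
        for k in range(2):
            np.fill_diagonal(w[k], 0.0)
        t = tensor_from_weights(w)
        assert pattern_heaviness(t, t.node_ids[:3], t.network_ids) == pytest.approx(0.5)

    def test_mean_of_three_edges(self):
        w = np.zeros((1, 3, 3))
        w[0, 0, 1] = w[0, 1, 0] = 0.9
        w[0, 0, 2] = w[0, 2, 0] = 0.6
        w[0, 1, 2] = w[0, 2, 1] = 0.3
        t = tensor_from_weights(w)
        assert pattern_heaviness(t, t.node_ids, t.network_ids) == pytest.approx(0.6)

    def test_two_network_mean_decomposition(self):
        t = random_tensor(5, 2, seed=8)
        exons = t.node_ids[:4]
        h01 = pattern_heaviness(t, exons, t.network_ids)
        h0 = pattern_heaviness(t, exons, [t.network_ids[0]])
        h1 = pattern_heaviness(t, exons, [t.network_ids[1]])
        assert h01 == pytest.approx((h0 + h1) / 2)

    def test_degenerate_patterns_rejected(self):
        t = random_tensor(4, 2, seed=0)
        with pytest.raises(ValueError):
            pattern_heaviness(t, t.node_ids[:1], t.network_ids)
        with pytest.raises(ValueError):
            pattern_heaviness(t, t.node_ids[:2], [])


class TestExtraction:
    def cfg(self):
        return MiningConfig(min_exons=5, min_networks=2, seed=0)

    def test_planted_clique_recovered_exactly(self, clique_tensor):
        cfg = self.cfg()
        sol = optimize_memberships(clique_tensor, cfg)
        patterns = extract_representative_patterns(clique_tensor, sol, cfg)
        assert len(patterns) == 1
        (p,) = patterns
        assert p.exon_ids == frozenset(clique_tensor.node_ids[i] for i in range(5))
        assert p.network_ids == frozenset(clique_tensor.network_ids[:2])
        assert p.heaviness == pytest.approx(0.9)

    def test_light_tensor_yields_nothing(self):
        t = random_tensor(10, 3, seed=1, low=0.1, high=0.1)
        cfg = self.cfg()
        sol = optimize_memberships(t, cfg)
        assert extract_representative_patterns(t, sol, cfg) == []

    def test_two_representatives_for_nested_structure(self):
        # 8-exon pattern in 3 networks; its 5-exon core also heavy in a 4th
        t = planted_clique_tensor(
            n=16, m=4, clique=tuple(range(8)), networks=(0, 1, 2), weight=0.8
        )
        core = np.array(range(5))
        block = np.full((5, 5), 0.8)
        np.fill_diagonal(block, 0.0)
        t.weights[np.ix_([3], core, core)] = block
        cfg = MiningConfig(min_exons=5, min_networks=3, seed=0)
        sol = optimize_memberships(t, cfg)
        patterns = extract_representative_patterns(t, sol, cfg)
        assert len(patterns) == 2
        sizes = sorted((len(p.exon_ids), len(p.network_ids)) for p in patterns)
        assert sizes == [(5, 4), (8, 3)]


class TestMasking:
    def test_masked_region_has_zero_heaviness(self, clique_tensor):
        cluster = FrequentCoSplicingCluster(
            frozenset(clique_tensor.node_ids[:5]),
            frozenset(clique_tensor.network_ids[:2]),
            heaviness=0.9,
        )
        masked = mask_pattern(clique_tensor, cluster)
        assert pattern_heaviness(
            masked, clique_tensor.node_ids[:5], clique_tensor.network_ids[:2]
        ) == 0.0

    def test_entries_outside_cluster_unchanged(self):
        t = random_tensor(8, 3, seed=6)
        cluster = FrequentCoSplicingCluster(
            frozenset(t.node_ids[:3]), frozenset(t.network_ids[:1]), heaviness=0.5
        )
        masked = mask_pattern(t, cluster)
        assert np.array_equal(masked.weights[1:], t.weights[1:])
        assert np.array_equal(masked.weights[0, 3:, 3:], t.weights[0, 3:, 3:])

    def test_masking_is_idempotent(self, clique_tensor):
        cluster = FrequentCoSplicingCluster(
            frozenset(clique_tensor.node_ids[:5]),
            frozenset(clique_tensor.network_ids[:2]),
            heaviness=0.9,
        )
        once = mask_pattern(clique_tensor, cluster)
        twice = mask_pattern(once, cluster)
        assert np.array_equal(once.weights, twice.weights)

    def test_unknown_ids_rejected(self, clique_tensor):
        cluster = FrequentCoSplicingCluster(
            frozenset(["nope"]), frozenset(clique_tensor.network_ids[:1]), heaviness=0.5
        )
        with pytest.raises(KeyError):
            mask_pattern(clique_tensor, cluster)


class TestMineAll:
    def two_clique_tensor(self):
        t = planted_clique_tensor(
            n=20, m=4, clique=(0, 1, 2, 3, 4), networks=(0, 1, 2),
            weight=0.9, background=0.05,
        )
        second = np.array([10, 11, 12, 13, 14])
        block = np.full((5, 5), 0.7)
        np.fill_diagonal(block, 0.0)
        for k in (1, 2, 3):
            t.weights[np.ix_([k], second, second)] = block
        return t

    def test_two_disjoint_cliques_heavier_first(self):
        t = self.two_clique_tensor()
        cfg = MiningConfig(min_exons=5, min_networks=3, seed=0)
        clusters = mine_all(t, cfg)
        assert len(clusters) == 2
        assert clusters[0].heaviness > clusters[1].heaviness
        assert clusters[0].exon_ids == frozenset(t.node_ids[i] for i in range(5))
        assert clusters[1].exon_ids == frozenset(t.node_ids[i] for i in range(10, 15))

    def test_background_only_tensor_yields_nothing(self):
        t = random_tensor(15, 3, seed=2, low=0.0, high=0.2)
        assert mine_all(t, MiningConfig(seed=0)) == []

    def test_max_patterns_cap(self):
        t = self.two_clique_tensor()
        cfg = MiningConfig(min_exons=5, min_networks=3, seed=0, max_patterns=1)
        assert len(mine_all(t, cfg)) == 1

    def test_no_duplicate_cluster_keys(self):
        t = self.two_clique_tensor()
        clusters = mine_all(t, MiningConfig(min_exons=5, min_networks=3, seed=0))
        keys = [c.key() for c in clusters]
        assert len(keys) == len(set(keys))


class TestMineFixedSize:
    def test_recovers_planted_block_exactly(self, clique_tensor):
        cfg = MiningConfig(seed=0, min_exons=5, min_networks=2)
        c = mine_fixed_size(clique_tensor, cfg, 5, 2)
        assert c.exon_ids == frozenset(clique_tensor.node_ids[:5])
        assert c.heaviness == pytest.approx(0.9)

    def test_matches_exhaustive_oracle_on_tiny_instance(self):
        t = random_tensor(6, 3, seed=13)
        best = 0.0
        for ex in itertools.combinations(range(6), 3):
            for ne in itertools.combinations(range(3), 2):
                h = pattern_heaviness(
                    t, [t.node_ids[i] for i in ex], [t.network_ids[k] for k in ne]
                )
                best = max(best, h)
        c = mine_fixed_size(t, MiningConfig(seed=0, min_exons=3, min_networks=2), 3, 2)
        assert c.heaviness == pytest.approx(best)
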