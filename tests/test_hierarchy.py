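from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import full_embedding
from hierord import hierarchy
from hierord.errors import AnchorError, UnknownLabelError
from hierord.graph_io import AnchorSet
from hierord.hierarchy import (
    DistanceModel,
    discretize,
    minimize_levels,
    objective,
    pseudo_distance,
    similarity,
)
from hierord.synthetic import generate_planted_hierarchy


def brute_objective(h, mu):
    """Independent double-loop evaluation of the pairwise error sum."""
    n = len(h)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += (abs(h[i] - h[j]) - mu[i, j]) ** 2
    return total


def toy_model(mu, K=9):
    mu = np.asarray(mu, dtype=float)
    return DistanceModel(K=K, S=K / 2.0 - mu, mu=mu)


def planted_distance_model(seed, n=5, k=2, K=9):
    ph = generate_planted_hierarchy(n=n, K=2, p0=0.8, beta=0.8, seed=seed)
    se = full_embedding(ph.graph, k=k)
    return ph.graph, pseudo_distance(similarity(se.Z, K))


class TestSimilarity:
    def test_identical_rows(self):
        Z = np.tile([1.0, 0.0], (2, 1))
        dm = similarity(Z, K=9)
        np.testing.assert_allclose(dm.S, 9 / 11)

    def test_antipodal_rows(self):
        Z = np.array([[1.0, 0.0], [-1.0, 0.0]])
        dm = similarity(Z, K=9)
        assert dm.S[0, 1] == pytest.approx(-9 / 29, abs=1e-12)

    def test_orthogonal_rows(self):
        Z = np.eye(2)
        for K in (1, 4, 9):
            assert similarity(Z, K=K).S[0, 1] == pytest.approx(0.0, abs=1e-15)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 12))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_symmetry_for_unit_rows(self, seed, K):
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(6, 3))
        Z /= np.linalg.norm(Z, axis=1)[:, None]
        dm = similarity(Z, K=K)
        eps = dm.epsilon
        assert np.max(np.abs(dm.S - dm.S.T)) < 1e-12
        assert np.all(dm.S >= -1 / (3 + eps) - 1e-12)
        assert np.all(dm.S <= 1 / (1 + eps) + 1e-12)


class TestPseudoDistance:
    def test_identical_rows_distance(self):
        Z = np.tile([0.0, 1.0], (2, 1))
        dm = pseudo_distance(similarity(Z, K=9))
        assert dm.mu[0, 1] == pytest.approx(4.5 - 9 / 11, abs=1e-12)

    def test_orthogonal_rows_distance_is_delta(self):
        dm = pseudo_distance(similarity(np.eye(2), K=9))
        assert dm.mu[0, 1] == pytest.approx(4.5, abs=1e-12)

    def test_affine_decreasing_in_similarity(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(8, 3))
        Z /= np.linalg.norm(Z, axis=1)[:, None]
        dm = pseudo_distance(similarity(Z, K=7))
        iu = np.triu_indices(8, 1)
        order_s = np.argsort(dm.S[iu])
        order_mu = np.argsort(-dm.mu[iu])
        np.testing.assert_array_equal(order_s, order_mu)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 12))
    @settings(max_examples=50, deadline=None)
    def test_mu_strictly_inside_level_interval(self, seed, K):
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(5, 4))
        Z /= np.linalg.norm(Z, axis=1)[:, None]
        dm = pseudo_distance(similarity(Z, K=K))
        eps = dm.epsilon
        lo = dm.delta - 1 / (1 + eps)
        hi = dm.delta + 1 / (3 + eps)
        assert np.all(dm.mu >= lo - 1e-12) and np.all(dm.mu <= hi + 1e-12)
        assert 0 < lo and hi < K


class TestObjective:
    def test_perfectly_spaced_levels_give_zero(self):
        mu = np.array([[0, 4.5, 9], [4.5, 0, 4.5], [9, 4.5, 0]], dtype=float)
        assert objective(np.array([0.0, 4.5, 9.0]), toy_model(mu)) == pytest.approx(0.0)

    def test_constant_levels_give_sum_of_squared_mu(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(3, 5, size=(4, 4))
        mu = (mu + mu.T) / 2
        iu = np.triu_indices(4, 1)
        assert objective(np.full(4, 2.0), toy_model(mu)) == pytest.approx(
            np.sum(mu[iu] ** 2)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(0, 9, size=(4, 4))
        mu = (mu + mu.T) / 2
        h = rng.uniform(0, 9, size=4)
        assert objective(h, toy_model(mu)) == pytest.approx(
            brute_objective(h, mu), abs=1e-12
        )


class TestMinimize:
    def test_fully_anchored_two_nodes(self):
        mu = np.array([[0.0, 4.5], [4.5, 0.0]])
        res = minimize_levels(
            toy_model(mu), AnchorSet({"a": 0.0, "b": 9.0}), ("a", "b"), restarts=3, seed=0
        )
        np.testing.assert_array_equal(res.h, [0.0, 9.0])
        np.testing.assert_array_equal(res.levels, [0, 9])

    def test_middle_node_converges_to_midpoint(self):
        mu = np.array([[0, 4.5, 9], [4.5, 0, 4.5], [9, 4.5, 0]], dtype=float)
        res = minimize_levels(
            toy_model(mu),
            AnchorSet({"a": 0.0, "c": 9.0}),
            ("a", "b", "c"),
            restarts=5,
            seed=1,
        )
        assert res.h[1] == pytest.approx(4.5, abs=1e-3)
        assert res.objective < 1e-5

    def test_reproducible(self):
        g, dm = planted_distance_model(seed=2)
        anchors = AnchorSet({g.labels[0]: 0.0, g.labels[1]: 9.0})
        r1 = minimize_levels(dm, anchors, g.labels, restarts=8, seed=5)
        r2 = minimize_levels(dm, anchors, g.labels, restarts=8, seed=5)
        np.testing.assert_array_equal(r1.h, r2.h)
        assert r1.objective == r2.objective

    def test_anchors_held_fixed(self):
        g, dm = planted_distance_model(seed=4, n=6)
        anchors = AnchorSet({g.labels[2]: 3.0, g.labels[5]: 7.0})
        res = minimize_levels(dm, anchors, g.labels, restarts=6, seed=2)
        assert res.h[2] == 3.0 and res.h[5] == 7.0
        assert res.levels[2] == 3 and res.levels[5] == 7
        assert np.all((res.h >= 0) & (res.h <= 9))

    def test_reported_objective_matches_reevaluation(self):
        g, dm = planted_distance_model(seed=6)
        anchors = AnchorSet({g.labels[0]: 0.0})
        res = minimize_levels(dm, anchors, g.labels, restarts=10, seed=3)
        assert res.objective == pytest.approx(objective(res.h, dm), abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_best_restart_beats_integer_grid(self, seed):
        """The continuous optimum must be at least as good as exhaustive
        search over all anchored integer level assignments {0..9}^free."""
        g, dm = planted_distance_model(seed=seed)
        anchors = AnchorSet({g.labels[0]: 0.0, g.labels[1]: 9.0})
        res = minimize_levels(dm, anchors, g.labels, restarts=20, seed=40 + seed)
        best_grid = min(
            objective(np.array([0.0, 9.0, *combo]), dm)
            for combo in product(range(10), repeat=3)
        )
        assert res.best_objective <= best_grid + 1e-9

    def test_beats_random_feasible_points(self):
        g, dm = planted_distance_model(seed=8, n=8)
        anchors = AnchorSet({g.labels[0]: 0.0, g.labels[1]: 9.0})
        res = minimize_levels(dm, anchors, g.labels, restarts=10, seed=0)
        rng = np.random.default_rng(123)
        for _ in range(1000):
            h = rng.uniform(0, 9, size=8)
            h[0], h[1] = 0.0, 9.0
            assert res.objective <= objective(h, dm)

    def test_label_permutation_equivariance_of_restart_average(self):
        """Averaged levels agree (at tolerance) when the nodes are presented
        in a different order; restart initializations differ per ordering,
        so the check is on the restart average, not bitwise."""
        ph = generate_planted_hierarchy(n=15, K=4, p0=0.7, beta=1.0, seed=3)
        g = ph.graph
        se = full_embedding(g, k=3)
        dm = pseudo_distance(similarity(se.Z, 4))
        anchors = AnchorSet({g.labels[0]: 0.0, g.labels[1]: 4.0})
        r1 = minimize_levels(dm, anchors, g.labels, restarts=60, seed=9)
        perm = np.random.default_rng(0).permutation(15)
        dm_p = DistanceModel(K=4, S=dm.S[np.ix_(perm, perm)], mu=dm.mu[np.ix_(perm, perm)])
        labels_p = tuple(g.labels[i] for i in perm)
        r2 = minimize_levels(dm_p, anchors, labels_p, restarts=60, seed=9)
        inv = np.empty(15, dtype=int)
        inv[perm] = np.arange(15)
        assert np.corrcoef(r1.h, r2.h[inv])[0, 1] > 0.98
        assert np.max(np.abs(r1.h - r2.h[inv])) < 0.5

    def test_empty_anchor_set_rejected(self):
        _, dm = planted_distance_model(seed=1)
        with pytest.raises(AnchorError):
            minimize_levels(dm, AnchorSet({}), tuple("abcde"), restarts=1, seed=0)

    def test_unknown_anchor_label_rejected(self):
        g, dm = planted_distance_model(seed=1)
        with pytest.raises(UnknownLabelError):
            minimize_levels(dm, AnchorSet({"nope": 0.0}), g.labels, restarts=1, seed=0)

    def test_out_of_range_anchor_rejected(self):
        g, dm = planted_distance_model(seed=1)
        with pytest.raises(AnchorError):
            minimize_levels(dm, AnchorSet({g.labels[0]: 12.0}), g.labels, restarts=1, seed=0)


class TestDiscretize:
    @pytest.mark.parametrize(
        "value,expected",
        [(4.5, 5), (-0.2, 0), (9.3, 9), (3.0, 3), (0.49999, 0), (8.5, 9)],
    )
    def test_half_up_rounding_with_clipping(self, value, expected):
        assert discretize(np.array([value]), K=9)[0] == expected

    def test_integer_vector_unchanged(self):
        v = np.array([0.0, 3.0, 9.0])
        np.testing.assert_array_equal(discretize(v, K=9), [0, 3, 9])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.array([np.nan]), K=9)
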