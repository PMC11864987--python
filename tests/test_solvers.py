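import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from sctransport.solvers import (
    Coupling,
    Marginals,
    ProblemSpec,
    entropy,
    fused_gw,
    gromov_wasserstein,
    sinkhorn,
    sinkhorn_divergence,
    sinkhorn_low_rank,
    sinkhorn_unbalanced,
    transport_cost,
)

from conftest import gw_objective_dense, lp_transport_cost


def uniform(n, m=None):
    return Marginals.uniform(n, m if m is not None else n)


class TestSinkhorn:
    def test_small_eps_recovers_permutation(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        c = sinkhorn(C, uniform(2), 0.01)
        np.testing.assert_allclose(np.diag(c.plan), 0.5, atol=1e-8)
        assert c.plan[0, 1] < 1e-8 and c.plan[1, 0] < 1e-8

    def test_lp_oracle_small_instances(self, rng):
        for n in (3, 4, 5, 6):
            C = rng.random((n, n))
            C = C / C.mean()
            c = sinkhorn(C, uniform(n), 1e-3)
            cost = transport_cost(C, c)
            exact = lp_transport_cost(C, c.row_sums(), c.col_sums())
            assert cost <= exact * 1.01

    def test_large_eps_independence_limit(self, rng):
        C = rng.random((3, 4))
        c = sinkhorn(C, uniform(3, 4), 1e6 * C.mean())
        np.testing.assert_allclose(c.plan, np.full((3, 4), 1 / 12), atol=1e-6)

    def test_constant_cost_gives_product_plan(self):
        a = np.array([0.2, 0.3, 0.5])
        b = np.array([0.6, 0.4])
        c = sinkhorn(np.full((3, 2), 3.7), Marginals(a, b), 0.5)
        np.testing.assert_allclose(c.plan, np.outer(a, b), atol=1e-9)

    def test_entropy_monotone_in_eps(self, rng):
        C = rng.random((5, 5))
        entropies = [
            entropy(sinkhorn(C, uniform(5), e).plan)
            for e in (0.01, 0.05, 0.2, 1.0)
        ]
        assert all(h1 <= h2 + 1e-9 for h1, h2 in zip(entropies, entropies[1:]))

    def test_errors(self):
        with pytest.raises(ValueError, match="positive"):
            sinkhorn(np.ones((2, 2)), uniform(2), -1.0)
        with pytest.raises(ValueError, match="finite"):
            sinkhorn(np.array([[np.inf, 1.0], [1.0, 0.0]]), uniform(2), 0.1)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_marginal_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 7, size=2)
        C = rng.random((n, m))
        a = rng.random(n) + 0.1
        a /= a.sum()
        b = rng.random(m) + 0.1
        b /= b.sum()
        c = sinkhorn(C, Marginals(a, b), 0.1)
        assert c.converged
        assert c.marginal_error <= 1e-6


class TestUnbalanced:
    def test_tau_one_reduces_to_balanced(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        cb = sinkhorn(C, uniform(2), 0.01)
        cu = sinkhorn_unbalanced(C, uniform(2), 0.01, 1.0, 1.0)
        np.testing.assert_allclose(cu.plan, cb.plan, atol=1e-6)

    def test_row_deviation_grows_as_tau_a_decreases(self, rng):
        # fixed asymmetric instance: relaxing the left constraint frees the
        # plan to follow the cost geometry, monotonically in tau_a
        C = rng.random((4, 4)) * 2
        a = np.array([0.4, 0.3, 0.2, 0.1])
        b = np.full(4, 0.25)
        m = Marginals(a, b)
        devs = []
        for tau_a in (0.99, 0.9, 0.6, 0.3):
            c = sinkhorn_unbalanced(C, m, 0.1, tau_a=tau_a, tau_b=1.0)
            devs.append(np.abs(c.plan.sum(axis=1) - a).sum())
        assert all(d1 <= d2 + 1e-9 for d1, d2 in zip(devs, devs[1:]))

    def test_unequal_mass_triggers_renormalization_warning(self):
        C = np.ones((2, 2))
        m = Marginals(np.array([1.0, 1.0]), np.array([0.5, 0.5]))
        with pytest.warns(UserWarning, match="renormalizing"):
            sinkhorn(C, m, 0.1)

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError, match="tau"):
            sinkhorn_unbalanced(np.ones((2, 2)), uniform(2), 0.1, tau_a=1.5)


class TestLowRank:
    def test_full_rank_matches_sinkhorn_cost(self, rng):
        C = rng.random((4, 4))
        C = C / C.mean()
        full = sinkhorn(C, uniform(4), 1e-3)
        lr = sinkhorn_low_rank(C, uniform(4), eps=1e-4, rank=4, seed=0)
        assert transport_cost(C, lr) <= transport_cost(C, full) * 1.05

    def test_rank_one_is_product_plan(self, rng):
        C = rng.random((5, 3))
        lr = sinkhorn_low_rank(C, uniform(5, 3), rank=1, seed=0)
        np.testing.assert_allclose(lr.dense(), np.full((5, 3), 1 / 15), atol=1e-9)

    def test_rank_sweep_cost_non_increasing(self, rng):
        C = rng.random((5, 5))
        C = C / C.mean()
        m = uniform(5)
        costs = [
            transport_cost(C, sinkhorn_low_rank(C, m, rank=r, seed=0, n_init=6))
            for r in range(1, 6)
        ]
        assert all(c2 <= c1 + 1e-6 for c1, c2 in zip(costs, costs[1:]))

    def test_factor_marginals_and_determinism(self, rng):
        C = rng.random((6, 4))
        m = uniform(6, 4)
        c1 = sinkhorn_low_rank(C, m, rank=2, seed=5)
        c2 = sinkhorn_low_rank(C, m, rank=2, seed=5)
        q, r, g = c1.factors
        np.testing.assert_allclose(q.sum(axis=1), m.a, atol=1e-8)
        np.testing.assert_allclose(r.sum(axis=1), m.b, atol=1e-8)
        for x, y in zip(c1.factors, c2.factors):
            np.testing.assert_array_equal(x, y)

    def test_rank_validation(self):
        with pytest.raises(ValueError, match=">= 1"):
            sinkhorn_low_rank(np.ones((3, 3)), uniform(3), rank=0)
        with pytest.raises(ValueError, match="exceeds"):
            sinkhorn_low_rank(np.ones((3, 3)), uniform(3), rank=4)


def asymmetric_points(rng, n=4):
    """A planar configuration without nontrivial distance symmetries."""
    pts = rng.random((n, 2)) * 4
    pts[:, 0] += np.arange(n) ** 1.3  # break symmetry deterministically
    return pts


class TestGromovWasserstein:
    def test_self_matching_beats_product_plan(self, rng):
        from scipy.spatial.distance import cdist

        pts = asymmetric_points(rng, 4)
        Cx = cdist(pts, pts, "sqeuclidean")
        c = gromov_wasserstein(Cx, Cx, uniform(4), 5e-3)
        # brute force over all 4! permutation plans
        import itertools

        perm_objs = []
        for p in itertools.permutations(range(4)):
            P = np.zeros((4, 4))
            P[np.arange(4), p] = 0.25
            perm_objs.append(gw_objective_dense(Cx, Cx, P))
        product = gw_objective_dense(Cx, Cx, np.full((4, 4), 1 / 16))
        assert c.objective <= min(perm_objs) + 1e-6
        assert c.objective <= 1e-3 * product
        # row-argmax is a permutation
        assert sorted(np.argmax(c.plan, axis=1)) == [0, 1, 2, 3]

    def test_recovers_planted_permutation(self, rng):
        from scipy.spatial.distance import cdist

        pts = asymmetric_points(rng, 5)
        Cx = cdist(pts, pts, "sqeuclidean")
        perm = np.array([2, 0, 4, 1, 3])
        Cy = Cx[np.ix_(perm, perm)]
        c = gromov_wasserstein(Cx, Cy, uniform(5), 5e-3)
        inverse = np.empty(5, dtype=int)
        inverse[perm] = np.arange(5)
        np.testing.assert_array_equal(np.argmax(c.plan, axis=1), inverse)

    def test_single_point(self):
        c = gromov_wasserstein(np.zeros((1, 1)), np.zeros((1, 1)), uniform(1), 0.1)
        np.testing.assert_allclose(c.plan, [[1.0]])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            gromov_wasserstein(np.ones((2, 3)), np.ones((3, 3)), uniform(2, 3), 0.1)

    def test_objective_matches_dense_reference(self, rng):
        from scipy.spatial.distance import cdist

        x = rng.normal(size=(4, 2))
        y = rng.normal(size=(3, 2))
        Cx = cdist(x, x)
        Cy = cdist(y, y)
        c = gromov_wasserstein(Cx, Cy, uniform(4, 3), 0.05)
        assert c.objective == pytest.approx(
            gw_objective_dense(Cx, Cy, c.plan), abs=1e-10
        )


class TestFusedGW:
    def setup_instance(self, rng):
        from scipy.spatial.distance import cdist

        pts = asymmetric_points(rng, 5)
        Cx = cdist(pts, pts, "sqeuclidean")
        perm = np.array([3, 1, 4, 0, 2])
        Cy = Cx[np.ix_(perm, perm)]
        C = np.ones((5, 5))
        C[np.arange(5), perm] = 0.0  # zero cost on true pairs
        return C, Cx, Cy, perm

    def test_alpha_zero_equals_sinkhorn(self, rng):
        C, Cx, Cy, _ = self.setup_instance(rng)
        f = fused_gw(C, Cx, Cy, uniform(5), 0.05, alpha=0.0)
        s = sinkhorn(C, uniform(5), 0.05)
        np.testing.assert_allclose(f.plan, s.plan, atol=1e-6)

    def test_alpha_one_equals_gw_objective(self, rng):
        C, Cx, Cy, _ = self.setup_instance(rng)
        f = fused_gw(C, Cx, Cy, uniform(5), 5e-3, alpha=1.0)
        g = gromov_wasserstein(Cx, Cy, uniform(5), 5e-3)
        assert f.extras["gw_objective"] == pytest.approx(g.objective, abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.75])
    def test_planted_correspondence_recovery(self, rng, alpha):
        C, Cx, Cy, perm = self.setup_instance(rng)
        f = fused_gw(C, Cx, Cy, uniform(5), 5e-3, alpha=alpha)
        np.testing.assert_array_equal(np.argmax(f.plan, axis=1), perm)

    def test_alpha_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            fused_gw(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)),
                     uniform(2), 0.1, alpha=1.5)


class TestSinkhornDivergence:
    def test_identical_histograms_zero(self):
        B = 1.0 - np.eye(4)
        mu = np.array([0.4, 0.3, 0.2, 0.1])
        assert sinkhorn_divergence(mu, mu, B, 0.01) == pytest.approx(0.0, abs=1e-9)

    def test_point_masses_binary_cost(self):
        B = 1.0 - np.eye(2)
        s = sinkhorn_divergence(np.array([1.0, 0.0]), np.array([0.0, 1.0]), B, 1e-3)
        assert s == pytest.approx(1.0, abs=1e-3)

    def test_symmetry_and_nonnegativity(self, rng):
        B = 1.0 - np.eye(5)
        mu = rng.random(5)
        mu /= mu.sum()
        nu = rng.random(5)
        nu /= nu.sum()
        s1 = sinkhorn_divergence(mu, nu, B, 0.05)
        s2 = sinkhorn_divergence(nu, mu, B, 0.05)
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert s1 >= -1e-9

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sinkhorn_divergence(np.array([-0.1, 1.1]), np.array([0.5, 0.5]),
                                1.0 - np.eye(2), 0.1)
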