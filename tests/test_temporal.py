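import numpy as np
import pandas as pd
import pytest

from sctransport.container import AnnotatedMatrix
from sctransport.geometry import CostSpec
from sctransport.solvers import Coupling, ProblemSpec
from sctransport.temporal import (
    GrowthConfig,
    cell_transition,
    chain_couplings,
    correlate_with_distribution,
    fate_probabilities,
    growth_marginals,
    pull,
    push,
    scaled_growth_and_apoptosis,
    solve_temporal,
)

from conftest import annotated


def make_coupling(P, prefix=("x", "y")):
    P = np.asarray(P, dtype=float)
    return Coupling(
        plan=P,
        row_ids=[f"{prefix[0]}{i}" for i in range(P.shape[0])],
        col_ids=[f"{prefix[1]}{j}" for j in range(P.shape[1])],
        spec=ProblemSpec(),
        objective=0.0,
        converged=True,
        n_iter=0,
        marginal_error=0.0,
    )


class TestGrowthMarginals:
    def test_birth_death_arithmetic(self):
        am = annotated(np.zeros((2, 1)))
        # g = exp(beta - delta) = (2, 1)
        cfg = GrowthConfig(mode="birth_death", delta_t=1.0,
                           beta=np.log([2.0, 1.0]), delta=np.zeros(2))
        np.testing.assert_allclose(growth_marginals(am, cfg), [2 / 3, 1 / 3])

    def test_birth_death_delta_t_zero_is_uniform(self):
        am = annotated(np.zeros((3, 1)))
        cfg = GrowthConfig(mode="birth_death", delta_t=0.0,
                           beta=np.array([0.5, 2.0, -1.0]), delta=np.zeros(3))
        np.testing.assert_allclose(growth_marginals(am, cfg), 1 / 3)

    def test_score_diff_equal_scores_uniform(self):
        am = annotated(np.zeros((4, 1)))
        s = np.array([0.3, 0.1, -0.2, 0.8])
        cfg = GrowthConfig(mode="score_diff", scale_c=2.0,
                           proliferation_scores=s, apoptosis_scores=s)
        np.testing.assert_allclose(growth_marginals(am, cfg), 0.25)

    def test_marginals_sum_to_one_for_random_rates(self, rng):
        am = annotated(np.zeros((10, 1)))
        for dt in (0.3, 1.0, 2.5):
            cfg = GrowthConfig(mode="birth_death", delta_t=dt,
                               beta=rng.normal(size=10), delta=rng.normal(size=10))
            assert growth_marginals(am, cfg).sum() == pytest.approx(1.0)

    def test_nonpositive_scale_rejected(self):
        am = annotated(np.zeros((2, 1)))
        cfg = GrowthConfig(mode="score_diff", scale_c=0.0,
                           proliferation_scores=np.zeros(2),
                           apoptosis_scores=np.zeros(2))
        with pytest.raises(ValueError, match="positive scale_c"):
            growth_marginals(am, cfg)


class TestSolveTemporal:
    def test_identical_point_sets_near_identity(self, rng):
        x = rng.normal(size=(8, 3)) * 4
        src = annotated(x, prefix="a")
        tgt = annotated(x, prefix="b")
        cost = CostSpec(kind="sq_euclidean", scaling="mean")
        c = solve_temporal(src, tgt, cost, ProblemSpec(epsilon=1e-3))
        np.testing.assert_array_equal(np.argmax(c.plan, axis=1), np.arange(8))

    def test_growth_doubles_row_share(self, rng):
        x = rng.normal(size=(4, 2))
        src = annotated(x, prefix="a")
        tgt = annotated(rng.normal(size=(4, 2)), prefix="b")
        cost = CostSpec(kind="sq_euclidean", scaling="mean")
        g = np.array([2.0, 1.0, 1.0, 1.0])
        cfg = GrowthConfig(mode="birth_death", delta_t=1.0,
                           beta=np.log(g), delta=np.zeros(4))
        c = solve_temporal(src, tgt, cost, ProblemSpec(epsilon=0.5), cfg)
        shares = c.plan.sum(axis=1)
        assert shares[0] == pytest.approx(2 * shares[1], rel=1e-4)

    def test_nonconvergence_reported(self, rng):
        x = rng.normal(size=(5, 2))
        src = annotated(x, prefix="a")
        tgt = annotated(rng.normal(size=(5, 2)), prefix="b")
        cost = CostSpec(kind="sq_euclidean", scaling="mean")
        c = solve_temporal(src, tgt, cost, ProblemSpec(epsilon=1e-3, max_iter=1))
        assert not c.converged


class TestChaining:
    def test_single_coupling_unchanged(self, rng):
        c = make_coupling(rng.random((3, 3)))
        chained = chain_couplings([c])
        np.testing.assert_array_equal(chained.plan, c.plan)

    def test_three_link_chain_matches_dense_product(self, rng):
        P1, P2, P3 = rng.random((3, 4)), rng.random((4, 2)), rng.random((2, 5))
        c1 = make_coupling(P1, ("a", "b"))
        c2 = make_coupling(P2, ("b", "c"))
        c3 = make_coupling(P3, ("c", "d"))
        chained = chain_couplings([c1, c2, c3])
        np.testing.assert_allclose(chained.plan, P1 @ P2 @ P3, atol=1e-12)
        assert chained.row_ids == c1.row_ids
        assert chained.col_ids == c3.col_ids

    def test_id_mismatch_names_junction(self, rng):
        c1 = make_coupling(rng.random((2, 2)), ("a", "b"))
        c2 = make_coupling(rng.random((2, 2)), ("c", "d"))
        with pytest.raises(ValueError, match="junction 1"):
            chain_couplings([c1, c2])


class TestPushPull:
    def test_matvec_oracle(self, rng):
        P = rng.random((5, 7))
        c = make_coupling(P)
        p = rng.random(5)
        q = rng.random(7)
        np.testing.assert_allclose(push(c, p), P.T @ p, atol=1e-12)
        np.testing.assert_allclose(pull(c, q), P @ q, atol=1e-12)

    def test_mass_identity(self, rng):
        P = rng.random((4, 6))
        c = make_coupling(P)
        p = np.full(4, 0.25)
        assert push(c, p).sum() == pytest.approx(p @ P.sum(axis=1))

    def test_push_pull_of_uniform_recovers_marginals(self, rng):
        from sctransport.solvers import Marginals, sinkhorn

        C = rng.random((4, 5))
        a = rng.random(4) + 0.5
        a /= a.sum()
        b = rng.random(5) + 0.5
        b /= b.sum()
        c = sinkhorn(C, Marginals(a, b), 0.1)
        np.testing.assert_allclose(push(c, np.ones(4)), b, atol=1e-6)
        np.testing.assert_allclose(pull(c, np.ones(5)), a, atol=1e-6)

    def test_zero_weights_rejected(self, rng):
        c = make_coupling(rng.random((3, 3)))
        with pytest.raises(ValueError, match="all-zero"):
            push(c, np.zeros(3))


class TestCellTransition:
    def test_block_diagonal_gives_identity_table(self):
        P = np.kron(np.eye(2), np.full((2, 2), 0.125))
        c = make_coupling(P)
        table = cell_transition(c, ["A", "A", "B", "B"], ["A", "A", "B", "B"],
                                normalization="row")
        np.testing.assert_allclose(table.values, np.eye(2), atol=1e-12)

    def test_product_plan_rows_equal_target_mass(self):
        a = np.full(4, 0.25)
        b = np.array([0.1, 0.2, 0.3, 0.4])
        c = make_coupling(np.outer(a, b))
        tgt_labels = ["u", "u", "v", "v"]
        table = cell_transition(c, ["s"] * 4, tgt_labels, normalization="row")
        np.testing.assert_allclose(table.values, [[0.3, 0.7]], atol=1e-12)

    def test_unnormalized_total_is_plan_mass(self, rng):
        P = rng.random((6, 6))
        c = make_coupling(P)
        labels = ["a", "a", "b", "b", "c", "c"]
        table = cell_transition(c, labels, labels, normalization="none")
        assert table.values.sum() == pytest.approx(P.sum())

    def test_label_length_mismatch(self, rng):
        c = make_coupling(rng.random((3, 3)))
        with pytest.raises(ValueError, match="label vector lengths"):
            cell_transition(c, ["a", "b"], ["a", "b", "c"])


class TestCorrelations:
    def test_exact_positive_and_negative(self, rng):
        w = rng.random(10)
        values = np.column_stack([w, -w, rng.random(10)])
        am = annotated(values)
        out = correlate_with_distribution(w, am, method="pearson")
        assert out.loc["g0", "correlation"] == pytest.approx(1.0)
        assert out.loc["g1", "correlation"] == pytest.approx(-1.0)

    def test_spearman_invariant_to_monotone_transform(self, rng):
        w = rng.random(12)
        feat = rng.random(12)
        am1 = annotated(feat[:, None])
        am2 = annotated(np.exp(3 * feat)[:, None])
        r1 = correlate_with_distribution(w, am1, method="spearman")
        r2 = correlate_with_distribution(w, am2, method="spearman")
        assert r1.loc["g0", "correlation"] == pytest.approx(
            r2.loc["g0", "correlation"], abs=1e-12
        )

    def test_zero_variance_feature_is_nan_and_unranked(self, rng):
        w = rng.random(8)
        am = annotated(np.column_stack([np.ones(8), w]))
        out = correlate_with_distribution(w, am)
        assert np.isnan(out.loc["g0", "correlation"])
        assert np.isnan(out.loc["g0", "rank"])

    def test_too_few_observations_after_mask(self, rng):
        am = annotated(rng.random((5, 2)))
        mask = np.array([True, True, False, False, False])
        with pytest.raises(ValueError, match="at least 3"):
            correlate_with_distribution(rng.random(5), am, mask=mask)


class TestScaledGrowth:
    def test_uniform_marginal_no_apoptosis(self):
        g, rate = scaled_growth_and_apoptosis(np.full(10, 0.1), 10, 1.0)
        np.testing.assert_allclose(g, 1.0)
        assert rate == 0.0

    def test_hand_built_case(self):
        # one starving cell with zero mass contributes 1/N
        n = 5
        a = np.array([0.0, 2 / n, 1 / n, 1 / n, 1 / n])
        a = a / a.sum()  # = (0, 0.4, 0.2, 0.2, 0.2)
        g, rate = scaled_growth_and_apoptosis(np.array([0.0, 2 / n, 1 / n, 1 / n, 1 / n]), n, 1.0)
        assert rate == pytest.approx(1 / n)

    def test_rate_bounded(self, rng):
        a = rng.random(20)
        a /= a.sum()
        _, rate = scaled_growth_and_apoptosis(a, 20, rng.random() * 2 + 0.1)
        assert 0.0 <= rate <= 1.0

    def test_nonpositive_scaling_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            scaled_growth_and_apoptosis(np.full(3, 1 / 3), 3, 0.0)


class TestFateProbabilities:
    def test_single_chain_reaches_terminal(self):
        c = make_coupling(np.eye(3) / 3, ("t0", "t1"))
        W = [np.eye(3), np.eye(3)]
        labels = [["x"] * 3, ["T", "T", "T"]]
        out = fate_probabilities([c], W, labels, {"T": {"T"}})
        np.testing.assert_allclose(out.values, 1.0)

    def test_symmetric_terminals_split_evenly(self):
        # one source cell splits evenly onto two targets of different fates
        P = np.array([[0.5, 0.5]])
        c = make_coupling(P, ("t0", "t1"))
        W = [np.eye(1), np.eye(2)]
        labels = [["s"], ["A", "B"]]
        out = fate_probabilities([c], W, labels, {"A": {"A"}, "B": {"B"}})
        np.testing.assert_allclose(out.iloc[0].values, [0.5, 0.5])

    def test_matches_fundamental_matrix_oracle(self, rng):
        n0, n1 = 6, 5
        P = rng.random((n0, n1))
        c = make_coupling(P, ("t0", "t1"))
        W0 = rng.random((n0, n0))
        W0 /= W0.sum(axis=1, keepdims=True)
        W1 = rng.random((n1, n1))
        W1 /= W1.sum(axis=1, keepdims=True)
        labels = [["s"] * n0, ["A", "A", "B", "B", "B"]]
        out = fate_probabilities([c], [W0, W1], labels, {"A": {"A"}, "B": {"B"}})
        # oracle: assemble the chain independently and invert the
        # fundamental matrix
        K = np.zeros((n0 + n1, n0 + n1))
        K[:n0, :n0] = 0.1 * W0
        K[:n0, n0:] = 0.9 * P / P.sum(axis=1, keepdims=True)
        K[n0:, n0:] = W1
        K /= K.sum(axis=1, keepdims=True)
        absorbing = np.zeros(n0 + n1, dtype=bool)
        absorbing[n0:] = True
        T = K[np.ix_(~absorbing, ~absorbing)]
        R_all = K[np.ix_(~absorbing, absorbing)]
        N = np.linalg.inv(np.eye(n0) - T)
        B = N @ R_all
        expected_A = B[:, :2].sum(axis=1)
        expected_B = B[:, 2:].sum(axis=1)
        np.testing.assert_allclose(out.values[:n0, 0], expected_A, atol=1e-9)
        np.testing.assert_allclose(out.values[:n0, 1], expected_B, atol=1e-9)

    def test_zero_outgoing_mass_rejected(self):
        P = np.array([[1.0, 0.0], [0.0, 0.0]])
        c = make_coupling(P, ("t0", "t1"))
        with pytest.raises(ValueError, match="zero outgoing"):
            fate_probabilities([c], [np.eye(2), np.eye(2)],
                               [["s", "s"], ["T", "T"]], {"T": {"T"}})
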