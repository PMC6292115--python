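"""Unit and property tests for single-sample pathway scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutpath import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ScoringConfig,
    ValidationError,
    gsva_enrichment_score,
    kernel_cdf,
    score_collection,
    ssgsea_score_collection,
    symmetric_rank_statistic,
)


class TestKernelCdf:
    def test_two_sample_gene_hand_value(self):
        # gene (0, 1): h = sqrt(0.5)/4, Phi(-4*sqrt(2)) ~ 0 -> z ~ (0.75, 0.25)
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [0.0, 3.0], "s2": [1.0, 1.0]}, index=["a", "b"])
        )
        z = kernel_cdf(expr)
        np.testing.assert_allclose(z.loc["a"], [0.25, 0.75], atol=1e-8)

    def test_shift_invariance_is_exact(self, small_expression):
        z1 = kernel_cdf(small_expression)
        shifted = small_expression.data.copy()
        shifted.loc["g3"] += 123.5
        z2 = kernel_cdf(ExpressionMatrix(shifted))
        pd.testing.assert_frame_equal(z1, z2)

    def test_zero_variance_gene_is_named(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [5.0, 1.0], "s2": [5.0, 2.0]}, index=["flat", "ok"])
        )
        with pytest.raises(ValidationError, match="flat"):
            kernel_cdf(expr)

    def test_values_in_open_unit_interval_and_monotone(self, small_expression):
        z = kernel_cdf(small_expression)
        assert ((z.to_numpy() > 0) & (z.to_numpy() < 1)).all()
        # ordering within each gene matches ordering of expression
        for g in small_expression.gene_ids:
            x = small_expression.data.loc[g].to_numpy()
            assert (np.argsort(x) == np.argsort(z.loc[g].to_numpy())).all()


class TestSymmetricRankStatistic:
    def test_p4_weights_match_hand_values(self):
        # positions (1,2,3,4) -> |2 - pos| = (1, 0, 1, 2)
        z = pd.DataFrame({"s": [0.9, 0.7, 0.5, 0.3]}, index=list("abcd"))
        order, weights = symmetric_rank_statistic(z)
        np.testing.assert_array_equal(weights, [1.0, 0.0, 1.0, 2.0])
        np.testing.assert_array_equal(order[:, 0], [0, 1, 2, 3])

    def test_positions_equidistant_from_center_get_equal_weight(self):
        # p=6, centre at p/2 = 3: positions 3±k share the weight k
        z = pd.DataFrame({"s": np.linspace(1, 0, 6)}, index=list("abcdef"))
        _, w = symmetric_rank_statistic(z)
        assert w[2] == 0.0  # position 3
        assert w[1] == w[3] == 1.0  # positions 2 and 4
        assert w[0] == w[4] == 2.0  # positions 1 and 5

    def test_permuting_gene_order_permutes_positions(self, rng):
        z = pd.DataFrame(rng.random((7, 3)), index=list("abcdefg"))
        order, _ = symmetric_rank_statistic(z)
        perm = rng.permutation(7)
        order2, _ = symmetric_rank_statistic(z.iloc[perm])
        # gene at walk position l must be the same gene under both labelings
        for j in range(3):
            assert [z.index[perm][i] for i in order2[:, j]] == [
                z.index[i] for i in order[:, j]
            ]


class TestEnrichmentScore:
    def test_three_gene_walk_up(self):
        # p=3, position weights (0.5, 0.5, 1.5), set at position 1:
        # walk = (1, 0.5, 0) -> ES = 1
        weights = np.array([0.5, 0.5, 1.5])
        inset = np.array([True, False, False])
        assert gsva_enrichment_score(inset, weights) == pytest.approx(1.0)

    def test_three_gene_walk_down(self):
        # set at position 3: walk = (-0.5, -1, 0) -> ES = -1
        weights = np.array([0.5, 0.5, 1.5])
        inset = np.array([False, False, True])
        assert gsva_enrichment_score(inset, weights) == pytest.approx(-1.0)

    def test_max_mode_picks_largest_magnitude(self):
        weights = np.array([0.5, 0.5, 1.5])
        inset = np.array([False, False, True])
        assert gsva_enrichment_score(inset, weights, es_mode="max") == pytest.approx(-1.0)

    def test_full_set_rejected(self):
        with pytest.raises(ValidationError, match="all genes"):
            gsva_enrichment_score(np.array([True, True]), np.array([0.0, 1.0]))

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            gsva_enrichment_score(np.array([False, False]), np.array([0.0, 1.0]))


class TestScoreCollection:
    def test_worked_example_scores_exact(self, worked_example):
        scores = score_collection(
            worked_example.expression,
            worked_example.collection,
            ScoringConfig(min_set_size=1),
        )
        pd.testing.assert_frame_equal(
            scores.data, worked_example.expected_scores, check_exact=True
        )

    def test_shape_contract(self, small_expression, small_collection):
        scores = score_collection(
            small_expression, small_collection, ScoringConfig(min_set_size=2)
        )
        assert scores.data.shape == (2, 8)
        assert scores.sample_ids == small_expression.sample_ids

    def test_planted_upshift_yields_row_max_in_that_sample(self, rng):
        genes = [f"g{i}" for i in range(20)]
        data = pd.DataFrame(
            rng.normal(0, 1, (20, 10)), index=genes,
            columns=[f"s{j}" for j in range(10)],
        )
        members = genes[:6]
        data.loc[members, "s0"] += 3.0
        coll = GeneSetCollection([GeneSet("UP", "d", frozenset(members))])
        scores = score_collection(ExpressionMatrix(data), coll)
        row = scores.data.loc["UP"]
        assert row["s0"] == row.max() and row["s0"] > 0

    def test_size_filter_drops_sets_and_errors_when_empty(self, small_expression):
        tiny = GeneSetCollection([GeneSet("T", "d", frozenset({"g0", "g1"}))])
        with pytest.raises(ValidationError, match="retained"):
            score_collection(small_expression, tiny, ScoringConfig(min_set_size=5))

    def test_zero_variance_genes_dropped_not_fatal(self, small_collection):
        data = pd.DataFrame(
            np.random.default_rng(0).normal(size=(12, 8)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(8)],
        )
        data.loc["g11"] = 7.0  # constant; not a member of either set
        scores = score_collection(
            ExpressionMatrix(data), small_collection, ScoringConfig(min_set_size=2)
        )
        assert scores.data.shape[0] == 2


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_scores_bounded_and_invariant_to_shift_scale(seed):
    """GSVA scores lie in [-1, 1]; per-gene affine maps with positive slope
    leave them unchanged (kernel bandwidth and ranks are location/scale free)."""
    rng = np.random.default_rng(seed)
    p, n = 15, 6
    data = pd.DataFrame(
        rng.normal(size=(p, n)),
        index=[f"g{i}" for i in range(p)],
        columns=[f"s{j}" for j in range(n)],
    )
    coll = GeneSetCollection(
        [GeneSet("S", "d", frozenset(f"g{i}" for i in rng.choice(p, 5, replace=False)))]
    )
    cfg = ScoringConfig(min_set_size=1)
    s1 = score_collection(ExpressionMatrix(data), coll, cfg).data
    assert (s1.to_numpy() >= -1).all() and (s1.to_numpy() <= 1).all()

    scaled = data.mul(rng.uniform(0.5, 10, size=p), axis=0).add(
        rng.normal(0, 50, size=p), axis=0
    )
    s2 = score_collection(ExpressionMatrix(scaled), coll, cfg).data
    assert np.max(np.abs(s1.to_numpy() - s2.to_numpy())) <= 1e-10


def test_permuting_samples_permutes_score_columns(small_expression, small_collection):
    cfg = ScoringConfig(min_set_size=2)
    base = score_collection(small_expression, small_collection, cfg).data
    perm = ["s3", "s0", "s7", "s1", "s2", "s6", "s4", "s5"]
    permuted = score_collection(
        ExpressionMatrix(small_expression.data[perm]), small_collection, cfg
    ).data
    pd.testing.assert_frame_equal(base[perm], permuted)


def test_complement_set_scores_have_opposite_sign_on_worked_instance():
    # 3-gene instance: {A} at the top and its "complement-like" singleton {C}
    # at the bottom score +1 and -1 in the first sample.
    weights = np.array([0.5, 0.5, 1.5])
    up = gsva_enrichment_score(np.array([True, False, False]), weights)
    down = gsva_enrichment_score(np.array([False, False, True]), weights)
    assert up == -down == 1.0


# ---------------------------------------------------------------------------
# ssGSEA backend
# ---------------------------------------------------------------------------


def _ssgsea_oracle(x, members, alpha):
    """Straightforward loop implementation of the running-sum score."""
    p, n = x.shape
    out = np.zeros(n)
    for j in range(n):
        ranks = pd.Series(x[:, j]).rank().to_numpy()
        order = np.argsort(-x[:, j], kind="stable")
        pin = pout = es = 0.0
        denom = sum(ranks[i] ** alpha for i in order if members[i])
        n_out = p - members.sum()
        for i in order:
            if members[i]:
                pin += ranks[i] ** alpha / denom
            else:
                pout += 1.0 / n_out
            es += pin - pout
        out[j] = es
    return out


class TestSsgsea:
    def test_matches_loop_oracle_on_4x2_instance(self):
        x = np.array([[4.0, 1.0], [3.0, 2.0], [2.0, 3.0], [1.0, 4.0]])
        members = np.array([True, True, False, False])
        expr = ExpressionMatrix(
            pd.DataFrame(x, index=list("abcd"), columns=["s1", "s2"])
        )
        coll = GeneSetCollection([GeneSet("S", "d", frozenset({"a", "b"}))])
        cfg = ScoringConfig(backend="ssgsea", min_set_size=1, ssgsea_alpha=0.25)
        got = ssgsea_score_collection(expr, coll, cfg).data.loc["S"].to_numpy()
        raw = _ssgsea_oracle(x, members, 0.25)
        expected = raw / (raw.max() - raw.min())
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_singleton_at_top_everywhere_is_global_max(self, rng):
        x = rng.normal(size=(10, 4))
        x[0] = x.max() + np.arange(1, 5)  # gene 0 tops every sample
        expr = ExpressionMatrix(
            pd.DataFrame(x, index=[f"g{i}" for i in range(10)],
                         columns=[f"s{j}" for j in range(4)])
        )
        coll = GeneSetCollection(
            [GeneSet("TOP", "d", frozenset({"g0"})),
             GeneSet("OTHER", "d", frozenset({"g5", "g6"}))]
        )
        cfg = ScoringConfig(backend="ssgsea", min_set_size=1)
        scores = ssgsea_score_collection(expr, coll, cfg).data
        assert (scores.loc["TOP"] > 0).all()
        assert scores.loc["TOP"].min() >= scores.loc["OTHER"].max()

    def test_alpha_limit_reduces_to_uniform_in_set_steps(self):
        # alpha -> 0 makes rank^alpha -> 1: compare with an explicitly
        # uniform-increment oracle.
        x = np.array([[4.0, 1.0], [3.0, 2.0], [2.0, 3.0], [1.0, 4.0]])
        members = np.array([True, False, True, False])
        raw_small_alpha = _ssgsea_oracle(x, members, 1e-9)
        raw_uniform = _ssgsea_oracle(x, members, 0.0)
        np.testing.assert_allclose(raw_small_alpha, raw_uniform, atol=1e-6)
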