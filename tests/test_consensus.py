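import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from riscmir import consensus as cns
from riscmir.io_formats import OrthologMap, PredictionTable, ScoreDirection
from tests.conftest import make_rank_matrix


def ptable(pairs, direction=ScoreDirection.HIGHER_IS_BETTER, name="src"):
    """pairs: list of (gene, score) for a single miRNA 'm1'."""
    return PredictionTable(
        name,
        direction,
        pd.DataFrame(
            {
                "mirna_id": "m1",
                "gene_id": [g for g, _ in pairs],
                "score": [s for _, s in pairs],
            }
        ),
    )


def exact_null_pvalues(matrix: cns.RankMatrix) -> np.ndarray:
    """Independent exact oracle for the per-gene permutation p-value.

    Shuffling a source's rank column makes each gene's entry uniform over
    that column's rank multiset, independently across sources; the exact
    P(null rp <= rp(g)) is an average over the product of the column
    multisets. Feasible for small fully observed matrices only.
    """
    assert matrix.observed_mask.all(), "oracle assumes a fully observed matrix"
    cols = [matrix.ranks[:, j] for j in range(len(matrix.sources))]
    rp_obs = cns.rank_product(matrix)
    total = math.prod(len(c) for c in cols)
    p = np.zeros(len(matrix.genes))
    for combo in itertools.product(*cols):
        null_rp = math.prod(combo) ** (1.0 / len(combo))
        p += null_rp <= rp_obs * (1 + 1e-9)
    return p / total


class TestProjectOrthologs:
    def test_unmapped_genes_dropped(self):
        t = ptable([("a", 0.9), ("b", 0.5), ("c", 0.1)])
        m = OrthologMap(pd.DataFrame({"source_gene": ["a", "b"], "target_gene": ["x", "y"]}))
        out = cns.project_orthologs(t, m)
        assert sorted(out.records["gene_id"]) == ["x", "y"]

    def test_identity_map_preserves_table(self):
        t = ptable([("a", 0.9), ("b", 0.5)])
        m = OrthologMap(pd.DataFrame({"source_gene": ["a", "b"], "target_gene": ["a", "b"]}))
        out = cns.project_orthologs(t, m)
        pd.testing.assert_frame_equal(
            out.records.sort_values("gene_id").reset_index(drop=True),
            t.records.sort_values("gene_id").reset_index(drop=True),
        )

    def test_empty_map_gives_empty_table(self, caplog):
        t = ptable([("a", 0.9)])
        m = OrthologMap(pd.DataFrame({"source_gene": [], "target_gene": []}))
        with caplog.at_level("WARNING"):
            out = cns.project_orthologs(t, m)
        assert len(out) == 0


class TestRankByScore:
    def test_best_score_gets_rank_one(self):
        r = cns.rank_by_score(ptable([("a", 0.9), ("b", 0.7), ("c", 0.1)]), "m1")
        assert list(r[["a", "b", "c"]]) == [1.0, 2.0, 3.0]

    def test_ties_get_average_ranks(self):
        r = cns.rank_by_score(
            ptable([("a", 0.9), ("b", 0.7), ("c", 0.7), ("d", 0.1)]), "m1"
        )
        assert list(r[["a", "b", "c", "d"]]) == [1.0, 2.5, 2.5, 4.0]

    def test_lower_is_better_flips_direction(self):
        r = cns.rank_by_score(
            ptable([("a", 0.1), ("b", 0.9)], ScoreDirection.LOWER_IS_BETTER), "m1"
        )
        assert list(r[["a", "b"]]) == [1.0, 2.0]

    def test_absent_mirna_is_error(self):
        with pytest.raises(ValueError, match="m2"):
            cns.rank_by_score(ptable([("a", 0.9)]), "m2")


class TestAssembleRankMatrix:
    def _lists(self):
        s1 = pd.Series({"a": 3.0, "b": 1.0, "c": 2.0}, name="s1")
        s2 = pd.Series({"a": 5.0, "b": 2.0}, name="s2")  # c missing
        s3 = pd.Series({"b": 3.0, "c": 1.0}, name="s3")  # a missing
        return {"s1": s1, "s2": s2, "s3": s3}

    def test_full_genes_keep_their_ranks(self):
        m = cns.assemble_rank_matrix(self._lists())
        i = m.genes.index("b")
        assert list(m.ranks[i]) == [1.0, 2.0, 3.0]
        assert m.observed_mask[i].all()

    def test_single_missing_rank_imputed_with_observed_mean(self):
        lists = {
            "s1": pd.Series({"a": 3.0, "b": 1.0}),
            "s2": pd.Series({"b": 2.0}),
            "s3": pd.Series({"a": 5.0, "b": 3.0}),
        }
        m = cns.assemble_rank_matrix(lists)
        i = m.genes.index("a")
        assert m.ranks[i, 1] == 4.0  # mean(3, 5)
        assert m.imputed_mask[i, 1] and not m.observed_mask[i, 1]
        assert cns.rank_product(m)[i] == pytest.approx((3 * 4 * 5) ** (1 / 3))

    def test_gene_missing_two_sources_discarded(self):
        lists = {
            "s1": pd.Series({"a": 1.0, "b": 2.0}),
            "s2": pd.Series({"a": 1.0, "b": 2.0}),
            "s3": pd.Series({"a": 1.0}),
            "s4": pd.Series({"a": 1.0}),
        }
        m = cns.assemble_rank_matrix(lists)
        assert "b" not in m.genes and m.n_discarded == 1

    def test_fewer_than_two_sources_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            cns.assemble_rank_matrix({"s1": pd.Series({"a": 1.0})})

    @pytest.mark.parametrize(
        "rule,expected",
        [
            (cns.ImputeRule.MEAN, 4.0),
            (cns.ImputeRule.MEDIAN, 4.0),
            (cns.ImputeRule.WORST_PLUS_ONE, 6.0),  # worst observed s2 rank 5, +1
        ],
    )
    def test_imputation_rules(self, rule, expected):
        lists = {
            "s1": pd.Series({"a": 3.0, "b": 1.0}),
            "s2": pd.Series({"b": 5.0}),
            "s3": pd.Series({"a": 5.0, "b": 3.0}),
        }
        m = cns.assemble_rank_matrix(lists, impute=rule)
        assert m.ranks[m.genes.index("a"), 1] == expected


class TestRankProduct:
    def test_best_possible_is_one(self):
        m = make_rank_matrix([[1, 1, 1, 1], [2, 2, 2, 2]])
        assert cns.rank_product(m)[0] == 1.0

    def test_geometric_mean(self):
        m = make_rank_matrix([[2, 8], [1, 1]])
        assert cns.rank_product(m)[0] == pytest.approx(4.0)

    def test_log_domain_agrees_with_direct_arithmetic(self):
        m = make_rank_matrix([[3, 4, 5]])
        assert cns.rank_product(m)[0] == pytest.approx(60 ** (1 / 3), rel=1e-12)
        assert cns.rank_product(m)[0] == pytest.approx(3.91486764117, rel=1e-9)

    def test_invariant_to_source_column_order(self):
        ranks = np.array([[1.0, 3, 2], [2, 1, 3], [3, 2, 1]])
        m1 = make_rank_matrix(ranks)
        m2 = make_rank_matrix(ranks[:, ::-1])
        assert np.allclose(cns.rank_product(m1), cns.rank_product(m2))

    @given(
        ranks=hst.lists(
            hst.integers(min_value=1, max_value=50), min_size=2, max_size=5
        ),
        which=hst.integers(min_value=0, max_value=4),
        improvement=hst.integers(min_value=1, max_value=10),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_improving_one_rank_never_increases_rp(self, ranks, which, improvement):
        which %= len(ranks)
        improved = list(ranks)
        improved[which] = max(1, improved[which] - improvement)
        rp = cns.rank_product(make_rank_matrix([ranks]))[0]
        rp2 = cns.rank_product(make_rank_matrix([improved]))[0]
        assert rp2 <= rp + 1e-12


class TestPermutationPvalues:
    def test_top_gene_matches_exact_enumeration(self):
        # gene with ranks (1,1) among 3 genes and 2 sources: exact p = 1/9
        m = make_rank_matrix([[1, 1], [2, 2], [3, 3]])
        exact = exact_null_pvalues(m)
        assert exact[0] == pytest.approx(1 / 9)
        n_perm = 1000
        p, _ = cns.permutation_pvalues(m, n_perm=n_perm, seed=42)
        count = round(p[0] * (n_perm + 1) - 1)
        lo, hi = st.binom.ppf([0.005, 0.995], n_perm, exact[0])
        assert lo <= count <= hi

    @pytest.mark.parametrize(
        "ranks",
        [
            [[1, 2], [2, 3], [3, 1]],
            [[1, 3, 2], [2, 1, 3], [3, 2, 1], [4, 4, 4]],
            [[2, 1], [1, 2], [3, 4], [4, 3]],
        ],
    )
    def test_monte_carlo_within_ci_of_enumeration(self, ranks):
        m = make_rank_matrix(ranks)
        exact = exact_null_pvalues(m)
        n_perm = 1000
        p, _ = cns.permutation_pvalues(m, n_perm=n_perm, seed=7)
        for g in range(len(ranks)):
            count = round(p[g] * (n_perm + 1) - 1)
            lo, hi = st.binom.ppf([0.005, 0.995], n_perm, exact[g])
            assert lo <= count <= hi, f"gene {g}: {p[g]} vs exact {exact[g]}"

    def test_worst_gene_has_p_one(self):
        m = make_rank_matrix([[1, 1], [2, 2], [3, 3]])
        p, _ = cns.permutation_pvalues(m, n_perm=500, seed=0)
        assert p[2] == 1.0

    def test_same_seed_reproduces_p_vector(self):
        m = make_rank_matrix([[1, 4], [2, 2], [3, 3], [4, 1]])
        p1, q1 = cns.permutation_pvalues(m, n_perm=300, seed=5)
        p2, q2 = cns.permutation_pvalues(m, n_perm=300, seed=5)
        assert np.array_equal(p1, p2) and np.array_equal(q1, q2)

    def test_pvalues_never_zero(self):
        m = make_rank_matrix([[1, 1], [50, 50]])
        p, _ = cns.permutation_pvalues(m, n_perm=200, seed=1)
        assert (p >= 1 / 201).all()

    def test_imputed_entries_reimputed_under_null(self):
        # one gene missing source s1: the null must re-impute per permutation,
        # so its p stays well calibrated (uniform-ish), not degenerate
        observed = np.ones((4, 3), bool)
        observed[0, 0] = False
        ranks = np.array([[2.5, 2.0, 3.0], [1, 1, 1], [2, 3, 2], [3, 4, 4]])
        m = make_rank_matrix(ranks, observed=observed)
        p, _ = cns.permutation_pvalues(m, n_perm=400, seed=9)
        assert 0 < p[0] <= 1.0


class TestFilterTargets:
    def _results(self, values, statistic="pfp"):
        out = []
        for i, v in enumerate(values):
            r = cns.RankProductResult(f"g{i}", float(i + 1), 2, v, v)
            out.append(r)
        return out

    def test_paper_literal_rule_keeps_high_p_genes(self):
        rule = cns.RetentionRule(cns.Comparator.GREATER_THAN, 0.5)
        kept = cns.filter_targets(self._results([0.9, 0.4]), rule)
        assert kept == ["g0"]

    def test_at_most_rule_keeps_small_p_genes(self):
        rule = cns.RetentionRule(cns.Comparator.AT_MOST, 0.05)
        kept = cns.filter_targets(self._results([0.9, 0.04]), rule)
        assert kept == ["g1"]

    def test_zero_threshold_keeps_everything(self):
        rule = cns.RetentionRule(cns.Comparator.GREATER_THAN, 0.0)
        kept = cns.filter_targets(self._results([0.9, 0.4, 0.01]), rule)
        assert kept == ["g0", "g1", "g2"]  # sorted by ascending rp

    @pytest.mark.parametrize(
        "text,comparator,threshold",
        [
            ("gt:0.5", cns.Comparator.GREATER_THAN, 0.5),
            ("le:0.05", cns.Comparator.AT_MOST, 0.05),
        ],
    )
    def test_rule_parsing(self, text, comparator, threshold):
        rule = cns.RetentionRule.parse(text)
        assert rule.comparator is comparator and rule.threshold == threshold

    def test_bad_rule_rejected(self):
        with pytest.raises(ValueError, match="unparseable"):
            cns.RetentionRule.parse("ge=0.5")


class TestUnionSets:
    def test_overlapping_lists(self):
        out = cns.union_sets({"A": ["a", "b"], "B": ["b", "c"]})
        assert out["union_size"] == 3
        assert out["overlaps"][("A", "B")] == 1

    def test_disjoint_lists(self):
        out = cns.union_sets({"A": ["a", "b"], "B": ["c", "d", "e"]})
        assert out["union_size"] == 5

    def test_idempotent_on_single_list(self):
        out = cns.union_sets({"A": ["a", "b"]})
        assert out["union"] == {"a", "b"}
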