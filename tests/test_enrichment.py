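import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nlnc import (
    bh_adjust,
    compare_index_by_group,
    enrichment_score,
    make_ranked_list,
    preranked_gsea,
    rank_by_group_difference,
    ssgsea_score,
)
from tests.conftest import random_expression


def walk_oracle(scores, hits, weight):
    """Independent step-by-step enrichment walk (pure Python)."""
    n = len(scores)
    n_hit = sum(hits)
    hit_w = [abs(s) ** weight if h else 0.0 for s, h in zip(scores, hits)]
    total = sum(hit_w)
    running, best, cur = [], 0.0, 0.0
    for i in range(n):
        if hits[i]:
            cur += hit_w[i] / total if total > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        running.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best, running


class TestEnrichmentScore:
    def test_worked_example(self):
        ranked = make_ranked_list({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})
        es, running = enrichment_score(ranked, {"g1", "g3"}, 1.0)
        assert es == pytest.approx(2 / 3)
        assert running == pytest.approx([2 / 3, 1 / 6, 1 / 2, 0.0])

    @pytest.mark.parametrize("gene, expected", [("g1", 1.0), ("g4", -1.0)])
    def test_single_hit_extremes_unweighted(self, gene, expected):
        ranked = make_ranked_list({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})
        es, _ = enrichment_score(ranked, {gene}, 0.0)
        assert es == pytest.approx(expected)

    @pytest.mark.parametrize("weight", [0.0, 0.5, 1.0, 2.0])
    def test_matches_brute_force_walk_on_random_instances(self, weight):
        rng = np.random.default_rng(17)
        for _ in range(150):
            n = int(rng.integers(4, 51))
            scores = rng.normal(size=n)
            ranked = make_ranked_list(pd.Series(scores, index=[f"g{i}" for i in range(n)]))
            n_hit = int(rng.integers(1, n))
            members = set(rng.choice(ranked.index, n_hit, replace=False))
            es, _ = enrichment_score(ranked, members, weight)
            hits = [g in members for g in ranked.index]
            expected, _ = walk_oracle(ranked.to_numpy(), hits, weight)
            if es != pytest.approx(expected, abs=1e-12):
                # positive peak and negative trough of equal magnitude: the
                # winner is sign-ambiguous at machine precision
                assert abs(es) == pytest.approx(abs(expected), abs=1e-12)

    def test_positive_scaling_invariance_and_negation_reversal(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        members = set(scores.index[:7])
        ranked = make_ranked_list(scores)
        es, _ = enrichment_score(ranked, members)
        es_scaled, _ = enrichment_score(make_ranked_list(scores * 4.2), members)
        assert es_scaled == pytest.approx(es)
        # negating all scores yields the walk of the reversed list
        ranked_neg = make_ranked_list(-scores)
        es_neg, _ = enrichment_score(ranked_neg, members)
        hits_rev = [g in members for g in ranked.index][::-1]
        expected, _ = walk_oracle(np.abs(ranked.to_numpy())[::-1], hits_rev, 1.0)
        assert es_neg == pytest.approx(expected)

    def test_degenerate_sets_rejected(self):
        ranked = make_ranked_list({"a": 2.0, "b": 1.0})
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"zzz"})
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"a", "b"})


class TestPrerankedGsea:
    def test_null_pvalues_uniform(self):
        # random sets in random rankings: nominal p ~ Uniform(0,1)
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(200)]
        ps = []
        for rep in range(200):
            ranked = make_ranked_list(pd.Series(rng.normal(size=200), index=genes))
            members = list(rng.choice(genes, 20, replace=False))
            res = preranked_gsea(ranked, {"S": members}, n_perm=200, seed=rep)
            ps.append(res["p_nominal"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_extreme_es_hits_add_one_floor(self):
        # a set occupying the very top of a steep ranking beats all permutations
        scores = {f"g{i}": float(100 - i) for i in range(40)}
        ranked = make_ranked_list(scores)
        res = preranked_gsea(ranked, {"TOP": [f"g{i}" for i in range(8)]},
                             n_perm=200, seed=0)
        assert res["p_nominal"].iloc[0] == pytest.approx(1 / 201)

    def test_single_set_adjusted_equals_nominal_and_seed_reproducible(self):
        rng = np.random.default_rng(11)
        ranked = make_ranked_list(pd.Series(rng.normal(size=80),
                                            index=[f"g{i}" for i in range(80)]))
        members = list(ranked.index[10:25])
        a = preranked_gsea(ranked, {"S": members}, n_perm=300, seed=5)
        b = preranked_gsea(ranked, {"S": members}, n_perm=300, seed=5)
        assert a["p_adjusted"].iloc[0] == a["p_nominal"].iloc[0]
        pd.testing.assert_frame_equal(a, b)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_identity_cases(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_never_below_input_and_monotone_when_sorted(self, pvals):
        out = bh_adjust(pvals)
        assert np.all(out >= np.asarray(pvals) - 1e-12)
        assert np.all(out <= 1.0)
        srt = bh_adjust(sorted(pvals))
        assert np.all(np.diff(srt) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSsgsea:
    def test_identical_samples_identical_scores(self, tiny_matrix):
        m = tiny_matrix
        m.values["S2"] = m.values["S1"]
        s = ssgsea_score(m, {"M1"}, normalize=False)
        assert s["S1"] == pytest.approx(s["S2"])

    def test_rank_and_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        expr = random_expression(rng, 10, 2, 4)
        gene_set = set(expr.gene_ids[:4])
        base = ssgsea_score(expr, gene_set, normalize=False)
        shifted = expr.values.copy()
        shifted["S0"] += 7.5  # constant shift of one sample
        from nlnc import ExpressionMatrix
        s2 = ssgsea_score(ExpressionMatrix(shifted, expr.biotype), gene_set, normalize=False)
        assert s2["S0"] == pytest.approx(base["S0"])
        cubed = ExpressionMatrix(expr.values ** 3, expr.biotype)  # strictly monotone (values>0 not needed for odd power)
        s3 = ssgsea_score(cubed, gene_set, normalize=False)
        pd.testing.assert_series_equal(s3, base)

    def test_six_gene_fixture_matches_ecdf_oracle(self):
        from nlnc import ExpressionMatrix
        values = pd.DataFrame({"S1": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]},
                              index=[f"g{i}" for i in range(6)])
        bt = pd.Series("mRNA", index=values.index)
        gene_set = {"g0", "g2", "g4"}
        got = ssgsea_score(ExpressionMatrix(values, bt), gene_set, alpha=0.0,
                           normalize=False)["S1"]
        # plain ECDF difference walk over the 6 positions
        hits = [g in gene_set for g in values.index]  # already in rank order
        cum_in = np.cumsum(hits) / 3
        cum_out = np.cumsum([not h for h in hits]) / 3
        assert got == pytest.approx(float(np.sum(cum_in - cum_out)))


class TestGroupDifferenceRanking:
    def test_shifted_gene_ranks_first_and_label_swap_negates(self):
        rng = np.random.default_rng(21)
        expr = random_expression(rng, 30, 0, 40)
        vals = expr.values.copy()
        labels = pd.Series(["a"] * 20 + ["b"] * 20, index=expr.sample_ids)
        vals.loc["M0", labels == "a"] += 5.0
        from nlnc import ExpressionMatrix
        expr = ExpressionMatrix(vals, expr.biotype)
        ranked = rank_by_group_difference(expr, labels)
        assert ranked.index[0] == "M0"
        swapped = rank_by_group_difference(expr, labels.map({"a": "b", "b": "a"}))
        assert list(swapped.index) == list(ranked.index[::-1])
        assert swapped.to_numpy() == pytest.approx(-ranked.to_numpy()[::-1])

    def test_null_statistics_small(self):
        rng = np.random.default_rng(5)
        expr = random_expression(rng, 200, 0, 300)
        labels = pd.Series(["a", "b"] * 150, index=expr.sample_ids)
        ranked = rank_by_group_difference(expr, labels)
        assert (ranked.abs() < 0.5).mean() > 0.3  # |t| concentrates near 0


class TestCompareIndexByGroup:
    def test_identical_groups_give_p_one(self):
        scores = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=scores.index)
        _, p = compare_index_by_group(scores, labels)
        assert p == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        scores = pd.Series([1.0, 2, 3, 10, 11, 12], index=list("abcdef"))
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=scores.index)
        _, p = compare_index_by_group(scores, labels)
        assert p == pytest.approx(0.1)  # 2 of the C(6,3)=20 orderings

    def test_three_group_kruskal_null_uniform(self):
        rng = np.random.default_rng(13)
        ps = []
        for rep in range(100):
            scores = pd.Series(rng.normal(size=200),
                               index=[f"s{i}" for i in range(200)])
            labels = pd.Series(rng.choice(["a", "b", "c"], size=200), index=scores.index)
            _, p = compare_index_by_group(scores, labels)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_group_rejected(self):
        scores = pd.Series([1.0, 2, 3], index=list("abc"))
        labels = pd.Series(["x", "x", "y"], index=scores.index)
        with pytest.raises(ValueError):
            compare_index_by_group(scores, labels)
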