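import math

import numpy as np
import pandas as pd
import pytest

from gcaxis.enrichment import (
    estimate_scores,
    gsea_es,
    gsea_test,
    ora_test,
    snr_ranking,
    ssgsea_score,
)
from gcaxis.io import ExpressionMatrix, GeneSetCollection, Unit


def hypergeom_tail_oracle(N, K, n, k):
    """Upper-tail hypergeometric by direct enumeration of the pmf."""
    total = 0.0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
    return total


def es_oracle(ranked, scores, members, p):
    """Running-sum enumeration, step by step."""
    members = set(members)
    n_hit = sum(g in members for g in ranked)
    denom = sum(abs(s) ** p for g, s in zip(ranked, scores) if g in members)
    run, best = 0.0, 0.0
    for g, s in zip(ranked, scores):
        if g in members:
            run += (abs(s) ** p) / denom if denom > 0 else 1.0 / n_hit
        else:
            run -= 1.0 / (len(ranked) - n_hit)
        if abs(run) > abs(best):
            best = run
    return best


class TestORA:
    def collection(self, **sets):
        return GeneSetCollection({k: ("", v) for k, v in sets.items()})

    def test_closed_form_full_overlap(self):
        bg = [f"G{i}" for i in range(20)]
        sets = self.collection(S=bg[:5])
        res = ora_test(bg[:5], bg, sets)
        assert res.loc["S", "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        bg = [f"G{i}" for i in range(20)]
        sets = self.collection(S=bg[:5])
        res = ora_test(bg[10:15], bg, sets)
        assert res.loc["S", "p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 31))
        bg = [f"G{i}" for i in range(N)]
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        members = list(rng.choice(bg, K, replace=False))
        de = list(rng.choice(bg, n, replace=False))
        res = ora_test(de, bg, self.collection(S=members))
        k = len(set(members) & set(de))
        assert res.loc["S", "k"] == k
        assert res.loc["S", "p"] == pytest.approx(
            hypergeom_tail_oracle(N, K, n, k), abs=1e-12
        )

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            ora_test([], [], self.collection(S=["G1"]))


class TestGseaES:
    def test_top_singleton_unweighted_es_is_one(self):
        ranked = ["A", "B", "C", "D"]
        scores = [3.0, 2.0, 1.0, 0.5]
        assert gsea_es(ranked, scores, {"A"}, weight_p=0) == pytest.approx(1.0)
        assert gsea_es(ranked, scores, {"A"}, weight_p=0) == pytest.approx(
            es_oracle(ranked, scores, {"A"}, 0)
        )

    def test_bottom_singleton_unweighted_es_negative(self):
        ranked = ["A", "B", "C", "D"]
        scores = [3.0, 2.0, 1.0, 0.5]
        es = gsea_es(ranked, scores, {"D"}, weight_p=0)
        assert es < 0
        assert es == pytest.approx(es_oracle(ranked, scores, {"D"}, 0))

    def test_reversed_ranking_negates_singleton_es(self):
        ranked = ["A", "B", "C", "D"]
        scores = [3.0, 2.0, 1.0, 0.5]
        fwd = gsea_es(ranked, scores, {"A"}, weight_p=0)
        rev = gsea_es(ranked[::-1], scores[::-1], {"A"}, weight_p=0)
        assert fwd == pytest.approx(-rev)

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_es_matches_enumeration_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        N = 30
        ranked = [f"G{i}" for i in range(N)]
        scores = np.sort(rng.normal(0, 2, N))[::-1]
        members = set(rng.choice(ranked, 8, replace=False))
        es = gsea_es(ranked, scores, members, weight_p=1.0)
        assert es == pytest.approx(es_oracle(ranked, scores, members, 1.0), rel=1e-12)
        assert -1.0 <= es <= 1.0

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ValueError):
            gsea_es(["A", "B"], [1, 2], {"A", "B"})
        with pytest.raises(ValueError):
            gsea_es(["A", "B"], [1, 2], set())


def two_group_matrix(n_genes=200, n_per_group=8, planted=20, shift=2.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(5.0, 1.0, (n_genes, 2 * n_per_group))
    x[:planted, :n_per_group] += shift
    genes = [f"G{i:03d}" for i in range(n_genes)]
    cols = [f"A{j}" for j in range(n_per_group)] + [f"B{j}" for j in range(n_per_group)]
    m = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=cols), Unit.LOG2TPM1)
    return m, genes[:planted], cols[:n_per_group], cols[n_per_group:]


class TestGseaTest:
    def test_planted_upregulated_set_significant(self):
        m, planted, ga, gb = two_group_matrix()
        sets = GeneSetCollection(
            {"PLANTED": ("", planted), "RANDOM": ("", [f"G{i:03d}" for i in range(100, 120)])}
        )
        res = gsea_test(m, ga, gb, sets, n_perm=1000, seed=3)
        assert res.loc["PLANTED", "es"] > 0
        assert res.loc["PLANTED", "nes"] > 0
        assert res.loc["PLANTED", "p_perm"] < 0.05
        assert res.loc["RANDOM", "p_perm"] > 0.05

    def test_seeded_run_reproducible_and_p_bounded(self):
        m, planted, ga, gb = two_group_matrix(seed=4)
        sets = GeneSetCollection({"S": ("", planted)})
        r1 = gsea_test(m, ga, gb, sets, n_perm=50, seed=9)
        r2 = gsea_test(m, ga, gb, sets, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(r1, r2)
        assert (r1["p_perm"] >= 1 / 51 - 1e-12).all()

    def test_small_groups_and_low_perm_rejected(self):
        m, planted, ga, gb = two_group_matrix()
        sets = GeneSetCollection({"S": ("", planted)})
        with pytest.raises(ValueError):
            gsea_test(m, ga[:2], gb, sets)
        with pytest.raises(ValueError):
            gsea_test(m, ga, gb, sets, n_perm=5)

    def test_snr_ranking_orders_planted_genes_first(self):
        m, planted, ga, gb = two_group_matrix()
        ranking = snr_ranking(m, ga, gb)
        assert set(ranking.index[: len(planted)]) == set(planted)


class TestSsgseaAndEstimate:
    def matrix(self, seed=0, n_genes=60, n_samples=5):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.exponential(50.0, (n_genes, n_samples)),
            index=[f"G{i:02d}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
        return ExpressionMatrix(df, Unit.TPM)

    def test_identical_columns_identical_scores(self):
        m = self.matrix()
        dup = m.data.copy()
        dup["S1"] = dup["S0"]
        scores = ssgsea_score(ExpressionMatrix(dup, Unit.TPM), [f"G{i:02d}" for i in range(10)])
        assert scores["S0"] == pytest.approx(scores["S1"])

    def test_raising_set_genes_increases_score(self):
        m = self.matrix(seed=1)
        members = [f"G{i:02d}" for i in range(10)]
        base = ssgsea_score(m, members)
        boosted = m.data.copy()
        boosted.loc[members, "S2"] *= 100.0
        up = ssgsea_score(ExpressionMatrix(boosted, Unit.TPM), members)
        assert up["S2"] > base["S2"]
        others = [s for s in m.sample_ids if s != "S2"]
        np.testing.assert_allclose(up[others], base[others])

    def test_empty_or_total_set_rejected(self):
        m = self.matrix()
        with pytest.raises(ValueError):
            ssgsea_score(m, [])
        with pytest.raises(ValueError):
            ssgsea_score(m, m.gene_ids)

    def test_estimate_is_sum_and_orders_enriched_samples(self):
        m = self.matrix(seed=2)
        stromal = [f"G{i:02d}" for i in range(8)]
        immune = [f"G{i:02d}" for i in range(20, 30)]
        boosted = m.data.copy()
        boosted.loc[immune, "S3"] *= 50.0
        boosted.loc[immune, "S4"] /= 50.0
        m2 = ExpressionMatrix(boosted, Unit.TPM)
        sets = GeneSetCollection({"STROMAL": ("", stromal), "IMMUNE": ("", immune)})
        est = estimate_scores(m2, sets, "STROMAL", "IMMUNE")
        t = est.table
        assert (t["estimate_score"] == t["stromal_score"] + t["immune_score"]).all()
        assert t.loc["S3", "immune_score"] > t.loc["S4", "immune_score"]

    def test_missing_signature_rejected(self):
        m = self.matrix()
        sets = GeneSetCollection({"STROMAL": ("", ["G00"])})
        with pytest.raises(KeyError):
            estimate_scores(m, sets, "STROMAL", "IMMUNE")
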