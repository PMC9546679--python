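import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcaxis.genomics import (
    cnv_proportion_test,
    contingency_test,
    correlated_genes,
    kruskal_wallis,
    mutation_frequency_by_subtype,
    mutual_exclusivity,
)
from gcaxis.io import CNVTable, ExpressionMatrix, MutationTable, Unit


def fisher_two_sided_oracle(table):
    """Enumerate all 2x2 tables with the observed margins; two-sided p sums
    the probabilities of tables no more likely than the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def kruskal_oracle(groups):
    """Textbook H with tie correction."""
    allv = np.concatenate(groups)
    ranks = stats.rankdata(allv)
    N = len(allv)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(allv, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / tie


def mut_table(records):
    df = pd.DataFrame(records, columns=["sample_id", "gene"])
    df["variant_class"] = "SNV"
    return MutationTable(df)


def calls_frame(mapping):
    return pd.DataFrame({"subtype": pd.Series(mapping)})


class TestContingency:
    def test_homogeneous_table_statistic_zero(self):
        r = contingency_test([[10, 10], [10, 10]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)
        assert r.method == "chi-square"

    def test_sparse_2x2_uses_fisher_and_matches_oracle(self):
        table = [[8, 2], [1, 9]]
        r = contingency_test(table)
        assert r.method == "fisher"
        assert r.p == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)

    def test_expected_below_five_triggers_fisher(self):
        assert contingency_test([[2, 1], [1, 2]]).method == "fisher"

    def test_row_column_permutation_invariance(self):
        t = np.array([[20, 30, 10], [15, 25, 35]])
        base = contingency_test(t)
        permuted = contingency_test(t[::-1, ::-1])
        assert base.statistic == pytest.approx(permuted.statistic)
        assert base.p == pytest.approx(permuted.p)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_test([[0, 0], [5, 5]])


class TestMutationFrequency:
    def test_uniformly_mutated_gene_no_signal(self):
        samples = [f"S{i}" for i in range(40)]
        calls = calls_frame({s: ["Mixed", "Quiescent"][i % 2] for i, s in enumerate(samples)})
        muts = mut_table([(s, "TP53") for s in samples])
        out = mutation_frequency_by_subtype(muts, calls, ["TP53"])
        assert out["p"].to_numpy() == pytest.approx(1.0)

    def test_planted_frequency_difference_detected(self):
        rng = np.random.default_rng(17)
        mixed = [f"M{i}" for i in range(100)]
        quiet = [f"Q{i}" for i in range(100)]
        calls = calls_frame({**{s: "Mixed" for s in mixed}, **{s: "Quiescent" for s in quiet}})
        recs = [(s, "TP53") for s in mixed if rng.random() < 0.4]
        recs += [(s, "TP53") for s in quiet if rng.random() < 0.05]
        out = mutation_frequency_by_subtype(mut_table(recs), calls, ["TP53"])
        assert out["p"].iloc[0] < 0.01

    def test_unprofiled_gene_gives_zero_rows(self):
        calls = calls_frame({"S1": "Mixed", "S2": "Quiescent"})
        muts = mut_table([("S1", "TP53")])
        out = mutation_frequency_by_subtype(muts, calls, ["NOVEL"])
        assert (out[["n1_mut", "n2_mut"]] == 0).all().all()

    def test_sample_without_call_excluded(self):
        calls = calls_frame({"S1": "Mixed", "S2": "Quiescent"})
        muts = mut_table([("S1", "TP53"), ("ORPHAN", "TP53")])
        out = mutation_frequency_by_subtype(muts, calls, ["TP53"])
        assert out[["n1", "n2"]].to_numpy().sum() == 2


class TestCnvProportions:
    def cnv(self, states_by_sample, gene="TP53"):
        df = pd.DataFrame(
            [{"sample_id": s, "gene": gene, "state": st} for s, st in states_by_sample.items()]
        )
        return CNVTable(df)

    def test_identical_proportions_not_significant(self):
        states = {}
        for grp, prefix in (("Mixed", "M"), ("Quiescent", "Q")):
            for i in range(20):
                states[f"{prefix}{i}"] = "Loss" if i < 5 else "Neutral"
        calls = calls_frame({s: ("Mixed" if s.startswith("M") else "Quiescent") for s in states})
        out = cnv_proportion_test(self.cnv(states), calls, "TP53", "Loss")
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_planted_loss_excess_flagged(self):
        rng = np.random.default_rng(23)
        states = {}
        for i in range(80):
            states[f"M{i}"] = "Loss" if rng.random() < 0.5 else "Neutral"
        for i in range(80):
            states[f"Q{i}"] = "Loss" if rng.random() < 0.08 else "Neutral"
        calls = calls_frame({s: ("Mixed" if s.startswith("M") else "Quiescent") for s in states})
        out = cnv_proportion_test(self.cnv(states), calls, "TP53", "Loss")
        assert out["p"].iloc[0] < 0.05

    def test_invalid_state_rejected(self):
        calls = calls_frame({"S1": "Mixed"})
        with pytest.raises(ValueError):
            cnv_proportion_test(self.cnv({"S1": "Loss"}), calls, "TP53", "Neutral")


class TestMutualExclusivity:
    def test_disjoint_mutations_give_small_odds_ratio(self):
        recs = [(f"A{i}", "TP53") for i in range(20)]
        recs += [(f"B{i}", "CTNNB1") for i in range(20)]
        universe = [r[0] for r in recs] + [f"N{i}" for i in range(60)]
        odds, p, counts = mutual_exclusivity(mut_table(recs), "TP53", "CTNNB1", universe)
        assert odds < 1
        assert p < 0.05
        table = counts.to_numpy()
        assert p == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)
        assert table[0, 0] == 0 and table[1, 1] == 60

    def test_independent_mutations_p_not_extreme(self):
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(200):
            samples = [f"S{i}" for i in range(120)]
            recs = [(s, "A") for s in samples if rng.random() < 0.3]
            recs += [(s, "B") for s in samples if rng.random() < 0.3]
            try:
                _, p, _ = mutual_exclusivity(mut_table(recs), "A", "B", samples)
            except ValueError:
                continue
            ps.append(p)
        assert 0.2 <= float(np.median(ps)) <= 0.8

    def test_never_mutated_gene_rejected(self):
        muts = mut_table([("S1", "TP53")])
        with pytest.raises(ValueError, match="CTNNB1"):
            mutual_exclusivity(muts, "TP53", "CTNNB1", ["S1", "S2"])


class TestCorrelatedGenes:
    def matrix(self, seed=0, n_genes=60, n_samples=40):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (n_genes, n_samples))
        x[1] = x[0]  # duplicated copy of the target
        df = pd.DataFrame(
            x, index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
        return ExpressionMatrix(df + 10, Unit.LOG2TPM1)

    def test_duplicated_target_has_rho_one(self):
        _, _, table = correlated_genes(self.matrix(), "G0")
        assert table.loc["G1", "rho"] == pytest.approx(1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        m = self.matrix(seed=1)
        _, _, base = correlated_genes(m, "G0")
        transformed = m.data.copy()
        transformed.loc["G5"] = np.exp(transformed.loc["G5"] / 3.0)
        _, _, after = correlated_genes(
            ExpressionMatrix(transformed, Unit.LOG2TPM1), "G0"
        )
        assert base.loc["G5", "rho"] == pytest.approx(after.loc["G5", "rho"])

    def test_null_matrix_false_positive_rate_loose(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.normal(0, 1, (500, 60)),
            index=[f"G{i}" for i in range(500)],
            columns=[f"S{j}" for j in range(60)],
        )
        pos, neg, table = correlated_genes(
            ExpressionMatrix(df + 10, Unit.LOG2TPM1), "G0", fdr_cut=0.05
        )
        # BH controls the FDR: under a global null expect few discoveries
        assert len(pos) + len(neg) <= 25

    def test_constant_target_rejected(self):
        m = self.matrix()
        data = m.data.copy()
        data.loc["G0"] = 1.0
        with pytest.raises(ValueError):
            correlated_genes(ExpressionMatrix(data, Unit.LOG2TPM1), "G0")


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([1, 2, 3, 1, 2, 3], ["A"] * 3 + ["B"] * 3)
        assert h == pytest.approx(0.0)

    def test_matches_textbook_formula(self):
        groups = [np.array([1.2, 3.4, 5.1]), np.array([2.2, 4.4]), np.array([0.5, 6.6, 7.7])]
        values = np.concatenate(groups)
        labels = ["A"] * 3 + ["B"] * 2 + ["C"] * 3
        h, _ = kruskal_wallis(values, labels)
        assert h == pytest.approx(kruskal_oracle(groups), rel=1e-10)

    def test_two_groups_agree_with_rank_sum_large_sample(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        _, p_kw = kruskal_wallis(np.concatenate([x, y]), ["X"] * 30 + ["Y"] * 25)
        mwu = stats.mannwhitneyu(x, y, use_continuity=False, alternative="two-sided",
                                 method="asymptotic")
        assert p_kw == pytest.approx(mwu.pvalue, abs=1e-6)

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([2, 2, 2, 2], ["A", "A", "B", "B"])
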