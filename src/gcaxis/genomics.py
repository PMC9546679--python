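"""Mutation/CNV contrasts between subtypes and generic group-difference tests.

Counts come from the mutation and CNV tables; all contingency tests share
one entry point (Pearson chi-square without continuity correction, Fisher's
exact two-sided fallback for sparse 2x2 tables), all multiplicity
corrections share :func:`gcaxis.diffexpr.bh_adjust`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import CNVTable, ExpressionMatrix, MutationTable

logger = logging.getLogger("gcaxis")

__all__ = [
    "ContingencyResult",
    "contingency_test",
    "mutation_frequency_by_subtype",
    "cnv_proportion_test",
    "mutual_exclusivity",
    "correlated_genes",
    "kruskal_wallis",
]


@dataclass
class ContingencyResult:
    statistic: float
    p: float
    method: str  # "chi-square" or "fisher"


def contingency_test(table) -> ContingencyResult:
    """r x c independence test.

    Pearson chi-square without Yates correction; a 2x2 table with any
    expected count < 5 falls back to Fisher's exact two-sided test (the
    statistic is then the sample odds ratio).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must hold non-negative integer counts")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero-margin row or column")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if t.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return ContingencyResult(statistic=float(odds), p=float(p), method="fisher")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return ContingencyResult(statistic=float(chi2), p=float(p), method="chi-square")


def _proportion_test(table) -> tuple[float, float, str]:
    """2x2 proportion contrast; a zero-margin column (both groups all-positive
    or all-negative) carries no contrast information and yields p = 1."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0, "degenerate"
    res = contingency_test(t)
    return res.statistic, res.p, res.method


def mutation_frequency_by_subtype(
    muts: MutationTable,
    calls: pd.DataFrame,
    genes: list[str],
) -> pd.DataFrame:
    """Per-gene mutated/wild counts per subtype with pairwise tests.

    ``calls`` is the subtype-call table indexed by sample. Mutation records
    for samples without a subtype call are excluded (with a warning). A gene
    absent from the table contributes zero mutated counts, not an error.
    p-values are BH-adjusted across genes within each subtype pair.
    """
    called = set(calls.index)
    uncalled = set(muts.data["sample_id"]) - called
    if uncalled:
        logger.warning(
            "%d mutated sample(s) lack a subtype call and are excluded", len(uncalled)
        )
    subtype_of = calls["subtype"].astype(str)
    subtypes = sorted(subtype_of.unique())
    n_by_subtype = subtype_of.value_counts()
    rows = []
    for gene in genes:
        mutated = muts.mutated_samples(gene) & called
        mut_by_st = subtype_of[subtype_of.index.isin(mutated)].value_counts()
        for a, b in combinations(subtypes, 2):
            ma = int(mut_by_st.get(a, 0))
            mb = int(mut_by_st.get(b, 0))
            na = int(n_by_subtype[a])
            nb = int(n_by_subtype[b])
            table = [[ma, na - ma], [mb, nb - mb]]
            stat, p, method = _proportion_test(table)
            rows.append(
                {
                    "gene": gene,
                    "group1": a,
                    "group2": b,
                    "n1_mut": ma,
                    "n1": na,
                    "n2_mut": mb,
                    "n2": nb,
                    "statistic": stat,
                    "p": p,
                    "method": method,
                }
            )
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    for (_, _), idx in df.groupby(["group1", "group2"]).groups.items():
        ok = df.loc[idx, "p"].notna()
        if ok.any():
            df.loc[idx[ok], "fdr"] = bh_adjust(df.loc[idx[ok], "p"].to_numpy())
    return df


def cnv_proportion_test(
    cnv: CNVTable,
    calls: pd.DataFrame,
    gene: str,
    state: str,
) -> pd.DataFrame:
    """Pairwise tests of a gene's Gain/Loss proportion between subtypes."""
    if state not in ("Gain", "Loss"):
        raise ValueError(f"state must be Gain or Loss, got {state!r}")
    recs = cnv.data[cnv.data["gene"] == gene]
    if recs.empty:
        raise KeyError(f"gene {gene!r} absent from CNV table")
    recs = recs[recs["sample_id"].isin(calls.index)]
    subtype_of = calls["subtype"].astype(str)
    merged = recs.assign(subtype=recs["sample_id"].map(subtype_of))
    subtypes = sorted(subtype_of.unique())
    counts = {}
    for s in subtypes:
        sub = merged[merged["subtype"] == s]
        if sub.empty:
            raise ValueError(f"subtype {s!r} has no CNV-profiled samples for {gene}")
        counts[s] = (int((sub["state"] == state).sum()), len(sub))
    rows = []
    for a, b in combinations(subtypes, 2):
        ka, na = counts[a]
        kb, nb = counts[b]
        table = [[ka, na - ka], [kb, nb - kb]]
        stat, p, method = _proportion_test(table)
        rows.append(
            {
                "gene": gene,
                "state": state,
                "group1": a,
                "group2": b,
                "prop1": ka / na,
                "prop2": kb / nb,
                "statistic": stat,
                "p": p,
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def mutual_exclusivity(
    muts: MutationTable,
    gene_a: str,
    gene_b: str,
    samples: list[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Fisher test of co-mutation of two genes over the profiled samples.

    ``samples`` is the profiled-sample universe; by default every sample
    appearing in the mutation table. Returns (odds ratio with Haldane 0.5
    correction when a cell is zero, two-sided Fisher p, the 2x2 count table).
    An odds ratio < 1 with small p indicates mutual exclusivity.
    """
    universe = list(samples) if samples is not None else muts.samples
    if not universe:
        raise ValueError("no profiled samples")
    in_a = muts.mutated_samples(gene_a) & set(universe)
    in_b = muts.mutated_samples(gene_b) & set(universe)
    if not in_a:
        raise ValueError(f"gene {gene_a!r} never mutated among profiled samples")
    if not in_b:
        raise ValueError(f"gene {gene_b!r} never mutated among profiled samples")
    both = len(in_a & in_b)
    a_only = len(in_a) - both
    b_only = len(in_b) - both
    neither = len(universe) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]], dtype=float)
    _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    counts = pd.DataFrame(
        table.astype(int),
        index=[f"{gene_a}+", f"{gene_a}-"],
        columns=[f"{gene_b}+", f"{gene_b}-"],
    )
    return float(odds), float(p), counts


def correlated_genes(
    m: ExpressionMatrix,
    target_gene: str,
    method: str = "spearman",
    fdr_cut: float = 0.05,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Genome-wide correlation screen against one gene's expression.

    Spearman (default; rank-invariant under monotone transforms) or Pearson
    correlation of every other gene with the target, p from the t
    approximation, BH across genes; significant genes split by correlation
    sign. Returns (positive genes, negative genes, full rho table).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if target_gene not in m.data.index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    if m.n_samples < 10:
        raise ValueError("need >= 10 samples for the correlate screen")
    X = m.data.to_numpy(dtype=float)
    genes = np.array(m.gene_ids)
    ti = int(np.where(genes == target_gene)[0][0])
    y = X[ti]
    if np.std(y) == 0:
        raise ValueError(f"target gene {target_gene!r} has constant expression")
    if method == "spearman":
        Xr = np.apply_along_axis(stats.rankdata, 1, X)
        y_r = stats.rankdata(y)
    else:
        Xr, y_r = X, y
    Xc = Xr - Xr.mean(axis=1, keepdims=True)
    yc = y_r - y_r.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (Xc * yc).sum(axis=1) / denom, np.nan)
    n = m.n_samples
    rho_cl = np.clip(rho, -0.9999999999, 0.9999999999)
    tstat = rho_cl * np.sqrt((n - 2) / (1.0 - rho_cl**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    keep = (genes != target_gene) & np.isfinite(rho)
    table = pd.DataFrame({"rho": rho[keep], "p": p[keep]}, index=genes[keep])
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    sig = table["fdr"] < fdr_cut
    positive = table.index[sig & (table["rho"] > 0)].tolist()
    negative = table.index[sig & (table["rho"] < 0)].tolist()
    return positive, negative, table


def kruskal_wallis(values, group_labels) -> tuple[float, float]:
    """Kruskal-Wallis rank test (tie-corrected) across >= 2 groups."""
    v = np.asarray(values, dtype=float)
    g = pd.Series(group_labels).astype(str).to_numpy()
    if v.shape[0] != g.shape[0]:
        raise ValueError("values and group labels differ in length")
    groups = [v[g == lab] for lab in np.unique(g)]
    if len(groups) < 2 or any(len(x) == 0 for x in groups):
        raise ValueError("need >= 2 non-empty groups")
    if np.unique(v).size == 1:
        raise ValueError("all values identical; ranks carry no information")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
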