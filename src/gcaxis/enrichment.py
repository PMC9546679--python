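"""Gene-set enrichment: hypergeometric ORA, two-group GSEA, ssGSEA scores.

Three rank statistics over user-supplied GMT collections:

* ORA — upper-tail hypergeometric over-representation of a DEG list in each
  set, BH-adjusted across sets.
* GSEA — weighted Kolmogorov-Smirnov running-sum enrichment of a set in a
  signal-to-noise-ranked gene list, with a phenotype-permutation null.
* ssGSEA — per-sample rank-weighted enrichment (weighted ECDF difference),
  used for ESTIMATE-style stromal/immune microenvironment scores whose sum
  is the combined infiltration score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .diffexpr import bh_adjust
from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "ora_test",
    "gsea_es",
    "snr_ranking",
    "gsea_test",
    "ssgsea_score",
    "EstimateScores",
    "estimate_scores",
]


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora_test(
    de_genes: list[str], background: list[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric ORA of a gene list against each set, BH across sets.

    p = P(X >= k) with X ~ Hypergeom(N=len(background), K=|set cap bg|,
    n=len(de_genes)). The DE list must be a subset of the background; set
    members outside the background are ignored.
    """
    bg = list(dict.fromkeys(background))
    if not bg:
        raise ValueError("empty background")
    bg_set = set(bg)
    de = list(dict.fromkeys(de_genes))
    stray = [g for g in de if g not in bg_set]
    if stray:
        raise ValueError(f"DE genes not in background: {stray[:5]}...")
    N, n = len(bg), len(de)
    rows = []
    for name in sets.names():
        members = set(sets.members(name)) & bg_set
        K = len(members)
        k = len(members & set(de))
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("set")
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def gsea_es(
    ranked_genes: list[str],
    scores,
    gene_set: set[str] | list[str],
    weight_p: float = 1.0,
) -> float:
    """Enrichment score: signed extreme of the weighted KS running sum.

    ``ranked_genes`` is ordered best-to-worst with ``scores`` aligned; hits
    advance the sum by |score|^weight_p (normalized over hits), misses
    retreat it by 1/(N - |S|).
    """
    genes = list(ranked_genes)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != len(genes):
        raise ValueError("scores misaligned with ranked genes")
    inset = np.fromiter((g in set(gene_set) for g in genes), dtype=bool, count=len(genes))
    n_hit = int(inset.sum())
    N = len(genes)
    if n_hit == 0 or n_hit == N:
        raise ValueError("gene set covers none or all of the ranked list")
    w = np.abs(s) ** weight_p
    hit_w = np.where(inset, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores zero: fall back to unweighted steps
        hit_w = inset.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~inset) / (N - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def snr_ranking(
    m: ExpressionMatrix, group_a: list[str], group_b: list[str]
) -> pd.Series:
    """Signal-to-noise ranking metric (A vs B), descending.

    s = (meanA - meanB) / (sdA + sdB) with each sd floored at 0.2*|mean|
    (0.2 when the mean is zero), the conventional GSEA adjustment.
    """
    a = m.subset_samples(list(group_a)).data.to_numpy(dtype=float)
    b = m.subset_samples(list(group_b)).data.to_numpy(dtype=float)

    def adj_sd(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        floor = np.where(mu == 0, 0.2, 0.2 * np.abs(mu))
        return np.maximum(sd, floor)

    snr = (a.mean(axis=1) - b.mean(axis=1)) / (adj_sd(a) + adj_sd(b))
    return pd.Series(snr, index=m.gene_ids).sort_values(ascending=False)


def gsea_test(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Two-phenotype GSEA with a label-permutation null.

    p_perm = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1); NES divides each ES
    by the mean |ES_perm| of the same sign; BH FDR across sets. Significance
    convention: p < 0.05 and FDR < 0.25.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each phenotype group needs >= 3 samples")
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    sub = m.subset_samples(list(group_a) + list(group_b))
    na = len(group_a)
    rng = np.random.default_rng(seed)
    all_samples = np.array(sub.sample_ids)

    def es_for(split_a: np.ndarray) -> dict[str, float]:
        ga = all_samples[split_a].tolist()
        gb = all_samples[~split_a].tolist()
        ranking = snr_ranking(sub, ga, gb)
        genes = ranking.index.tolist()
        scores = ranking.to_numpy()
        gene_pool = set(genes)
        out = {}
        for name in sets.names():
            hit = set(sets.members(name)) & gene_pool
            if not hit or len(hit) == len(genes):
                out[name] = np.nan
            else:
                out[name] = gsea_es(genes, scores, hit, weight_p=weight_p)
        return out

    base_mask = np.zeros(len(all_samples), dtype=bool)
    base_mask[:na] = True
    observed = es_for(base_mask)

    perm_es: dict[str, list[float]] = {name: [] for name in sets.names()}
    for _ in range(n_perm):
        mask = np.zeros(len(all_samples), dtype=bool)
        mask[rng.choice(len(all_samples), size=na, replace=False)] = True
        for name, v in es_for(mask).items():
            perm_es[name].append(v)

    rows = []
    for name in sets.names():
        es = observed[name]
        perms = np.asarray(perm_es[name], dtype=float)
        perms = perms[np.isfinite(perms)]
        if not np.isfinite(es) or perms.size == 0:
            rows.append({"set": name, "es": np.nan, "nes": np.nan, "p_perm": np.nan})
            continue
        p = (1.0 + np.sum(np.abs(perms) >= abs(es))) / (perms.size + 1.0)
        same_sign = perms[np.sign(perms) == np.sign(es)] if es != 0 else perms
        nes = es / np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        rows.append({"set": name, "es": es, "nes": nes, "p_perm": p})
    df = pd.DataFrame(rows).set_index("set")
    ok = df["p_perm"].notna()
    df["fdr"] = np.nan
    if ok.any():
        df.loc[ok, "fdr"] = bh_adjust(df.loc[ok, "p_perm"].to_numpy())
    df["significant"] = (df["p_perm"] < 0.05) & (df["fdr"] < 0.25)
    return df


# ---------------------------------------------------------------------------
# ssGSEA / ESTIMATE-style scores
# ---------------------------------------------------------------------------

def ssgsea_score(
    m: ExpressionMatrix, gene_set: set[str] | list[str], alpha: float = 0.25
) -> pd.Series:
    """Per-sample single-sample GSEA score of one gene set.

    Genes are ranked by expression within each sample (average ranks for
    ties, highest expression = rank N); walking the list from the top, the
    score accumulates the difference between the rank^alpha-weighted ECDF of
    in-set genes and the unweighted ECDF of out-of-set genes.
    """
    members = set(gene_set)
    if not members:
        raise ValueError("empty gene set")
    genes = m.gene_ids
    inset = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    if not inset.any():
        raise ValueError("gene set does not intersect the matrix genes")
    if inset.all():
        raise ValueError("gene set covers every gene in the matrix")
    X = m.data.to_numpy(dtype=float)
    N = len(genes)
    scores = np.empty(m.n_samples)
    for j in range(m.n_samples):
        ranks = rankdata(X[:, j])  # 1..N ascending, ties averaged
        order = np.argsort(-ranks, kind="stable")  # descending expression
        in_ord = inset[order]
        r_ord = ranks[order]
        w = np.where(in_ord, r_ord**alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_ord) / (N - inset.sum())
        scores[j] = float(np.sum(p_in - p_out))
    return pd.Series(scores, index=m.sample_ids)


@dataclass
class EstimateScores:
    """Stromal / immune ssGSEA scores and their sum per sample."""

    table: pd.DataFrame  # columns: stromal_score, immune_score, estimate_score

    def __post_init__(self) -> None:
        resid = self.table["estimate_score"] - (
            self.table["stromal_score"] + self.table["immune_score"]
        )
        if (resid != 0).any():
            raise ValueError("estimate_score must equal stromal + immune exactly")


def estimate_scores(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    stromal_set: str,
    immune_set: str,
    alpha: float = 0.25,
) -> EstimateScores:
    """ESTIMATE-style microenvironment scores from two signature sets."""
    for name in (stromal_set, immune_set):
        if name not in sets:
            raise KeyError(f"signature set {name!r} missing from collection")
    stromal = ssgsea_score(m, sets.members(stromal_set), alpha=alpha)
    immune = ssgsea_score(m, sets.members(immune_set), alpha=alpha)
    table = pd.DataFrame(
        {
            "stromal_score": stromal,
            "immune_score": immune,
            "estimate_score": stromal + immune,
        }
    )
    return EstimateScores(table)
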