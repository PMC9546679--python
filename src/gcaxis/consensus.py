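"""Resampling consensus clustering of signature genes and CDF-based k selection.

Items are GENES; the resampling evidence is SAMPLES. For each of ``n_reps``
draws, ceil(p_item * n_samples) samples are subsampled without replacement,
genes are clustered on 1 - Pearson correlation (computed over the drawn
samples) with a PAM (k-medoids) inner clusterer, and the consensus matrix
entry (i, j) is the fraction of draws in which genes i and j co-clustered.
Because items are genes and only samples are subsampled, every gene pair is
co-evaluated in every draw, so the consensus denominator is exactly n_reps.

k is selected from the area under the consensus CDF: the area grows with k,
and the chosen k is the largest one whose relative area gain over k-1 still
exceeds an elbow threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "ConsensusResult",
    "KSelection",
    "SignatureModules",
    "consensus_cluster",
    "consensus_cdf_area",
    "select_k",
    "label_modules",
]


@dataclass
class ConsensusResult:
    """Consensus matrix and assignments for one value of k."""

    k: int
    consensus: pd.DataFrame  # items x items, values in [0, 1]
    assignments: dict[str, int]  # gene -> cluster id (1..k)
    cdf_area: float
    n_reps: int
    p_item: float
    seed: int
    co_cluster_counts: np.ndarray = field(repr=False, default=None)


@dataclass
class KSelection:
    """Chosen k plus the full CDF-area curve for reporting."""

    k: int
    areas: dict[int, float]
    relative_increase: dict[int, float]
    threshold: float


@dataclass
class SignatureModules:
    """Co-expressed glycolysis / cholesterol gene modules."""

    glycolysis_module: list[str]
    cholesterol_module: list[str]

    def __post_init__(self) -> None:
        if not self.glycolysis_module or not self.cholesterol_module:
            raise ValueError("signature modules must be non-empty")
        if set(self.glycolysis_module) & set(self.cholesterol_module):
            raise ValueError("signature modules must be disjoint")


# ---------------------------------------------------------------------------
# PAM (k-medoids) on a precomputed distance matrix
# ---------------------------------------------------------------------------

def _pam(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic PAM: greedy BUILD then SWAP until no improvement.

    Returns integer labels 0..k-1. Ties break toward the lower index, so the
    result depends only on `dist`.
    """
    n = dist.shape[0]
    # BUILD: first medoid minimizes total distance; then greedy gain.
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        m = int(np.argmax(gains))
        medoids.append(m)
        nearest = np.minimum(nearest, dist[m])
    medoids_arr = np.array(sorted(medoids))
    cost = dist[medoids_arr].min(axis=0).sum()
    for _ in range(max_iter):
        best = (cost, None)
        for mi, m in enumerate(medoids_arr):
            for h in range(n):
                if h in medoids_arr:
                    continue
                cand = medoids_arr.copy()
                cand[mi] = h
                c = dist[cand].min(axis=0).sum()
                if c < best[0] - 1e-12:
                    best = (c, cand)
        if best[1] is None:
            break
        cost, medoids_arr = best[0], np.sort(best[1])
    return dist[medoids_arr].argmin(axis=0)


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; NaN (zero-variance rows within a
    subsample) treated as zero correlation."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------

def consensus_cluster(
    sig: ExpressionMatrix,
    k_range: range | list[int] = range(2, 11),
    n_reps: int = 100,
    p_item: float = 0.8,
    seed: int = 0,
) -> list[ConsensusResult]:
    """Monti-style consensus clustering of genes over subsampled samples.

    Genes are row-standardized (z across samples) before clustering. The
    inner clusterer is PAM on 1 - Pearson distance. Final cluster
    assignments cut an average-linkage dendrogram of 1 - consensus into k
    groups.
    """
    ks = sorted(set(int(k) for k in k_range))
    genes = sig.gene_ids
    n_items, n_samples = sig.data.shape
    if len(set(genes)) != n_items:
        raise ValueError("duplicate gene ids; collapse symbols first")
    values = sig.data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValueError(f"constant (zero-variance) gene row(s): {bad}")
    if min(ks) < 2 or max(ks) > n_items - 1:
        raise ValueError(f"k_range {ks} outside [2, n_items-1] = [2, {n_items - 1}]")
    if n_items < 2 * max(ks):
        raise ValueError(f"need >= {2 * max(ks)} genes for max k {max(ks)}, have {n_items}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]

    n_draw = math.ceil(p_item * n_samples)
    root = np.random.SeedSequence(seed)
    # One sample subsampling plan shared across k, as in reference tools.
    rep_rngs = [np.random.default_rng(s) for s in root.spawn(n_reps)]
    draws = [rng.choice(n_samples, size=n_draw, replace=False) for rng in rep_rngs]
    dists = [_pearson_distance(z[:, cols]) for cols in draws]

    results: list[ConsensusResult] = []
    for k in ks:
        co = np.zeros((n_items, n_items), dtype=float)
        for dist in dists:
            labels = _pam(dist, k)
            same = labels[:, None] == labels[None, :]
            co += same
        consensus = co / n_reps
        np.fill_diagonal(consensus, 1.0)
        cons_df = pd.DataFrame(consensus, index=genes, columns=genes)
        # condensed distance on 1 - consensus for the final cut
        condensed = squareform(1.0 - consensus, checks=False)
        tree = linkage(condensed, method="average")
        labels = fcluster(tree, t=k, criterion="maxclust")
        results.append(
            ConsensusResult(
                k=k,
                consensus=cons_df,
                assignments={g: int(l) for g, l in zip(genes, labels)},
                cdf_area=consensus_cdf_area(consensus),
                n_reps=n_reps,
                p_item=p_item,
                seed=seed,
                co_cluster_counts=co,
            )
        )
    return results


def consensus_cdf_area(consensus: np.ndarray | pd.DataFrame) -> float:
    """Area under the empirical CDF of the upper-triangular consensus entries."""
    c = consensus.to_numpy() if isinstance(consensus, pd.DataFrame) else consensus
    iu = np.triu_indices(c.shape[0], k=1)
    vals = np.sort(c[iu])
    n = vals.size
    if n == 0:
        return 0.0
    xs = np.unique(vals)
    cdf = np.searchsorted(vals, xs, side="right") / n
    area = 0.0
    for i in range(1, xs.size):
        area += (xs[i] - xs[i - 1]) * cdf[i - 1]
    return float(area)


def select_k(results: list[ConsensusResult], threshold: float = 0.05) -> KSelection:
    """Elbow selection on the CDF-area curve.

    The relative increase r(k) = (A(k) - A(k-1)) / A(k-1) flattens once k
    exceeds the number of genuine modules. Among candidate k with
    r(k) >= threshold, the chosen k is the one where the curve flattens
    most sharply afterwards (largest r(k) / r(k+1), with r at the top of
    the range compared against the threshold). If no k clears the floor the
    smallest k is returned.
    """
    if len(results) < 2:
        raise ValueError("select_k needs results for at least 2 values of k")
    by_k = {r.k: r for r in results}
    ks = sorted(by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"k values must be contiguous, got {ks}")
    areas = {k: by_k[k].cdf_area for k in ks}
    rel: dict[int, float] = {}
    for prev, k in zip(ks, ks[1:]):
        denom = areas[prev] if areas[prev] > 0 else np.finfo(float).tiny
        rel[k] = (areas[k] - areas[prev]) / denom
    candidates = [k for k, r in rel.items() if r >= threshold]
    if not candidates:
        chosen = ks[0]
    else:
        floor = max(threshold, np.finfo(float).tiny)

        def knee(k: int) -> float:
            nxt = rel.get(k + 1, threshold)
            return rel[k] / max(nxt, floor * 1e-3)

        chosen = max(candidates, key=lambda k: (knee(k), -k))
    return KSelection(k=chosen, areas=areas, relative_increase=rel, threshold=threshold)


def label_modules(
    assignments: dict[str, int],
    sets: GeneSetCollection,
    glycolysis_set: str,
    cholesterol_set: str,
) -> SignatureModules:
    """Map consensus clusters to the two metabolic source sets.

    Each source set claims the cluster containing the plurality of its genes;
    the module is that cluster's members intersected with the source set. An
    exact plurality tie, or both sets claiming one cluster, is an error (no
    axis separation).
    """
    clusters: dict[int, list[str]] = {}
    for g, c in assignments.items():
        clusters.setdefault(c, []).append(g)

    def majority_cluster(set_name: str) -> int:
        members = set(sets.members(set_name))
        counts = {c: len(members & set(gs)) for c, gs in clusters.items()}
        best = max(counts.values())
        if best == 0:
            raise ValueError(f"no gene of set {set_name!r} appears in the assignments")
        winners = [c for c, n in counts.items() if n == best]
        if len(winners) > 1:
            raise ValueError(
                f"plurality tie for set {set_name!r} between clusters {sorted(winners)}"
            )
        return winners[0]

    g_cluster = majority_cluster(glycolysis_set)
    c_cluster = majority_cluster(cholesterol_set)
    if g_cluster == c_cluster:
        raise ValueError(
            "glycolysis and cholesterol sets map to the same cluster; no axis separation"
        )
    gly = [g for g in clusters[g_cluster] if g in set(sets.members(glycolysis_set))]
    cho = [g for g in clusters[c_cluster] if g in set(sets.members(cholesterol_set))]
    return SignatureModules(glycolysis_module=gly, cholesterol_module=cho)
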