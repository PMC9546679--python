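"""Two-group differential expression with an empirical-Bayes moderated t.

Per gene on log2(TPM+1) values: log2FC = meanA - meanB; the pooled residual
variance s2_g (df d_g = nA + nB - 2) is shrunk toward a prior s0^2 carrying
d0 prior degrees of freedom,

    s~2_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g),

and t = log2FC / (s~_g * sqrt(1/nA + 1/nB)) is referred to a t distribution
with d0 + d_g df. The prior (d0, s0^2) is estimated by method of moments on
z_g = log s2_g: for a scaled-F-distributed sample variance,
E[z] = log s0^2 + psi(d_g/2) - log(d_g/2) - psi(d0/2) + log(d0/2) and
Var[z] = psi'(d_g/2) + psi'(d0/2), so d0 solves
psi'(d0/2) = Var(z) - psi'(d_g/2) (d0 = inf when the right side is <= 0,
i.e. no excess variance beyond sampling noise). With prior_df = 0 the
statistic reduces to the ordinary pooled two-sample t.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, Unit, log2_tpm1

__all__ = [
    "moderated_t_table",
    "estimate_variance_prior",
    "bh_adjust",
    "select_degs",
    "de_analysis",
]


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve polygamma(1, x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments (d0, s0^2) from per-gene sample variances.

    Returns d0 = np.inf when the observed log-variance spread is no larger
    than expected from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need >= 2 positive variances to estimate the prior")
    z = np.log(s2)
    evar = z.var(ddof=1) - polygamma(1, d / 2.0)
    emean = z.mean() - digamma(d / 2.0) + np.log(d / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_t_table(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t DE statistics for group A vs group B (log2FC = A - B).

    ``prior_df=None`` estimates (d0, s0^2) by moments; ``prior_df=0`` gives
    the ordinary pooled two-sample t. Returns a DataFrame indexed by gene
    with columns log2fc, t, p, s2, s2_post, df_total.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if m.unit is not Unit.LOG2TPM1:
        m = log2_tpm1(m)
    a = m.subset_samples(list(group_a)).data.to_numpy(dtype=float)
    b = m.subset_samples(list(group_b)).data.to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    d = na + nb - 2
    lfc = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / d

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, d)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "p": p,
            "s2": s2,
            "s2_post": s2_post,
            "df_total": df_total,
        },
        index=m.gene_ids,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(
    results: pd.DataFrame, lfc_cut: float = 1.0, fdr_cut: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split significant genes into up/down lists: |log2FC| > lfc_cut, FDR < fdr_cut."""
    if "fdr" not in results.columns:
        raise ValueError("run bh_adjust first: results lack an 'fdr' column")
    sig = results["fdr"] < fdr_cut
    up = results.index[sig & (results["log2fc"] > lfc_cut)].tolist()
    down = results.index[sig & (results["log2fc"] < -lfc_cut)].tolist()
    return up, down


def de_analysis(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    prior_df: float | None = None,
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Full DE table with FDR and up/down/ns direction calls."""
    res = moderated_t_table(m, group_a, group_b, prior_df=prior_df)
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    direction = np.full(len(res), "ns", dtype=object)
    sig = res["fdr"] < fdr_cut
    direction[(sig & (res["log2fc"] > lfc_cut)).to_numpy()] = "up"
    direction[(sig & (res["log2fc"] < -lfc_cut)).to_numpy()] = "down"
    res["direction"] = direction
    return res
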