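"""Median-Z quadrant subtyping on the glycolysis / cholesterol axes.

Each tumor sample gets two scores: the median log2(TPM+1) expression of the
glycolysis module genes and of the cholesterol module genes, each
standardized (z) across the tumor cohort. The sign pair assigns one of four
subtypes:

    GLYCOLYSIS <= 0, CHOLESTEROL <= 0  -> Quiescent
    GLYCOLYSIS  > 0, CHOLESTEROL <= 0  -> Glycolysis
    GLYCOLYSIS <= 0, CHOLESTEROL  > 0  -> Cholesterol
    GLYCOLYSIS  > 0, CHOLESTEROL  > 0  -> Mixed

Ties at exactly zero go to the <= side so the four quadrants partition the
plane (the origin is Quiescent).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consensus import SignatureModules
from .io import ExpressionMatrix, Unit, log2_tpm1

__all__ = ["SUBTYPES", "compute_axis_scores", "assign_subtype", "subtype_counts"]

SUBTYPES = ("Quiescent", "Glycolysis", "Cholesterol", "Mixed")


def compute_axis_scores(
    m: ExpressionMatrix,
    modules: SignatureModules,
    tumor_samples: list[str] | None = None,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-sample glycolysis/cholesterol z-scores.

    Raw score = median expression over the module's genes; each axis vector
    is z-scored (ddof=1) over the tumor cohort. Normal samples must be
    excluded via ``tumor_samples`` before standardization. Set
    ``log_scale=False`` to take medians on raw TPM instead of log2(TPM+1).

    Returns a DataFrame indexed by sample with columns
    ``glycolysis_z`` and ``cholesterol_z`` (mean 0, sd 1 each).
    """
    if m.unit is Unit.FPKM:
        raise ValueError("convert FPKM to TPM before scoring")
    work = log2_tpm1(m) if (log_scale and m.unit is Unit.TPM) else m
    if tumor_samples is None:
        tumor_samples = work.sample_ids
    if len(tumor_samples) < 3:
        raise ValueError("need >= 3 tumor samples to standardize axis scores")
    data = work.subset_samples(list(tumor_samples)).data

    def axis(genes: list[str], name: str) -> pd.Series:
        missing = [g for g in genes if g not in data.index]
        if missing:
            raise KeyError(
                f"{name} module gene(s) absent from matrix: {missing}; "
                "run extract_signature_matrix first"
            )
        raw = data.loc[genes].median(axis=0)
        sd = raw.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"{name} raw scores have zero variance; cannot z-score")
        return (raw - raw.mean()) / sd

    return pd.DataFrame(
        {
            "glycolysis_z": axis(modules.glycolysis_module, "glycolysis"),
            "cholesterol_z": axis(modules.cholesterol_module, "cholesterol"),
        }
    )


def assign_subtype(scores: pd.DataFrame) -> pd.DataFrame:
    """Quadrant labels from the sign pair of the two z-scores.

    Returns the scores with an added ``subtype`` column; every sample gets
    exactly one of Quiescent / Glycolysis / Cholesterol / Mixed.
    """
    g = scores["glycolysis_z"].to_numpy(dtype=float)
    c = scores["cholesterol_z"].to_numpy(dtype=float)
    if np.isnan(g).any() or np.isnan(c).any():
        bad = scores.index[np.isnan(g) | np.isnan(c)].tolist()
        raise ValueError(f"NaN axis score(s) for samples {bad}")
    label = np.where(
        g > 0,
        np.where(c > 0, "Mixed", "Glycolysis"),
        np.where(c > 0, "Cholesterol", "Quiescent"),
    )
    out = scores.copy()
    out["subtype"] = pd.Categorical(label, categories=list(SUBTYPES))
    return out


def subtype_counts(calls: pd.DataFrame) -> pd.Series:
    """Sample count per subtype (all four listed, zeros included)."""
    return calls["subtype"].value_counts().reindex(list(SUBTYPES), fill_value=0)
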