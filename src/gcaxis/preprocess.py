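"""Cohort preprocessing: symbol collapse, sample/gene filtering, signature extraction.

The filtering rules mirror a standard TCGA-style workflow: duplicate gene
symbols are collapsed to their per-sample median, samples without complete
follow-up are dropped, and signature genes must reach TPM >= 1 in at least
half of the cohort to be retained.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, ClinicalTable, Unit

logger = logging.getLogger("gcaxis")

__all__ = [
    "collapse_duplicate_symbols",
    "filter_low_expression",
    "filter_samples_with_followup",
    "extract_signature_matrix",
]


def collapse_duplicate_symbols(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse duplicated gene symbols to their per-sample median row.

    The median of an even number of rows is the mean of the two middle
    values. Gene order follows first occurrence.
    """
    idx = m.data.index
    if not idx.duplicated().any():
        return m
    order = idx.drop_duplicates()
    collapsed = m.data.groupby(level=0, sort=False).median()
    collapsed = collapsed.loc[order]
    return ExpressionMatrix(collapsed, m.unit)


def filter_low_expression(
    m: ExpressionMatrix,
    min_value: float = 1.0,
    min_fraction: float = 0.5,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes expressed below ``min_value`` in more than half the samples.

    A gene is kept iff the fraction of samples with expression >= min_value
    is >= min_fraction (a gene exactly at the boundary fraction is kept).
    Returns the filtered matrix and the list of dropped genes.
    """
    if m.unit is not Unit.TPM:
        raise ValueError(f"filter_low_expression expects TPM, got {m.unit.value}")
    if m.n_genes == 0 or m.n_samples == 0:
        raise ValueError("cannot filter an empty expression matrix")
    frac = (m.data >= min_value).mean(axis=1)
    keep = frac >= min_fraction
    dropped = m.data.index[~keep].tolist()
    if dropped:
        logger.info(
            "filter_low_expression: dropped %d/%d genes (TPM<%g in >%d%% of samples)",
            len(dropped), m.n_genes, min_value, round((1 - min_fraction) * 100),
        )
    return ExpressionMatrix(m.data.loc[keep].copy(), m.unit), dropped


def filter_samples_with_followup(
    c: ClinicalTable, m: ExpressionMatrix
) -> tuple[ClinicalTable, ExpressionMatrix]:
    """Keep only samples with survival time, event status and expression.

    Both outputs share the same sample set in the clinical table's order.
    """
    complete = c.data.dropna(subset=["os_time_days", "os_event"])
    keep = [s for s in complete.index if s in m.data.columns]
    if not keep:
        raise ValueError("no samples with complete follow-up and expression")
    n_dropped = len(c.data) - len(keep)
    if n_dropped:
        logger.info("filter_samples_with_followup: dropped %d samples", n_dropped)
    return ClinicalTable(complete.loc[keep].copy()), m.subset_samples(keep)


def extract_signature_matrix(
    m: ExpressionMatrix, sets: GeneSetCollection, names: list[str]
) -> ExpressionMatrix:
    """Restrict rows to the union of the named gene sets.

    Set members absent from the matrix are skipped with a warning (public
    signatures routinely contain symbols a given platform lacks). Overlapping
    sets contribute each gene once, in first-mention order.
    """
    missing_sets = [n for n in names if n not in sets]
    if missing_sets:
        raise KeyError(f"gene set(s) not in collection: {missing_sets}")
    wanted: list[str] = []
    seen: set[str] = set()
    for name in names:
        for g in sets.members(name):
            if g not in seen:
                seen.add(g)
                wanted.append(g)
    present = [g for g in wanted if g in m.data.index]
    absent = [g for g in wanted if g not in m.data.index]
    for g in absent:
        logger.warning("signature gene %s absent from expression matrix; skipped", g)
    if not present:
        raise ValueError(f"no genes of sets {names} present in the matrix")
    sub = m.data.loc[present]
    if isinstance(sub, pd.Series):  # pragma: no cover - single gene edge
        sub = sub.to_frame().T
    return ExpressionMatrix(sub.copy(), m.unit)
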