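"""Readers, writers and unit conversion for the pipeline's tabular formats.

All on-disk formats are plain TSV (UTF-8, tab-separated, no quoting) or GMT.
Expression matrices are genes (rows) x samples (columns); the first header
cell is ignored. Clinical, mutation and CNV tables follow the column
contracts documented on each reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("gcaxis")

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "MutationTable",
    "CNVTable",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "read_mutations",
    "read_cnv",
    "read_cohort_tables",
    "fpkm_to_tpm",
    "log2_tpm1",
]

CNV_STATES = ("Loss", "Neutral", "Gain")
VARIANT_CLASSES = ("SNV", "InDel")


class FormatError(ValueError):
    """A file or table violates its format contract."""


class Unit(str, Enum):
    """Expression unit tag."""

    FPKM = "FPKM"
    TPM = "TPM"
    LOG2TPM1 = "LOG2TPM1"  # log2(TPM + 1)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a unit tag.

    Sample ids must be unique. Gene ids may contain duplicates straight off
    disk; :func:`gcaxis.preprocess.collapse_duplicate_symbols` establishes
    uniqueness before any per-gene analysis.
    """

    data: pd.DataFrame
    unit: Unit

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise FormatError("expression values must be finite")
        if self.unit in (Unit.FPKM, Unit.TPM) and values.size and (values < 0).any():
            raise FormatError(f"negative values not allowed for unit {self.unit.value}")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(samples)].copy(), self.unit)


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, ordered member symbols)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if any((not m) or (not str(m).strip()) for m in members):
                raise FormatError(f"gene set {name!r} contains blank member symbols")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample follow-up: survival time (days), event flag, covariates.

    ``data`` is indexed by unique sample_id with columns ``os_time_days``,
    ``os_event`` and any number of categorical covariates. Missing values are
    allowed per field (NaN).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample_id in clinical table")
        for col in ("os_time_days", "os_event"):
            if col not in self.data.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        ev = self.data["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            bad = sorted(ev[~ev.isin([0, 1])].unique().tolist())
            raise FormatError(f"os_event values outside {{0,1}}: {bad}")
        t = self.data["os_time_days"].dropna()
        if (t <= 0).any():
            raise FormatError("os_time_days must be > 0 where present")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("os_time_days", "os_event")]


@dataclass
class MutationTable:
    """MAF-lite records: one row per (sample_id, gene, variant_class)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "gene", "variant_class"):
            if col not in self.data.columns:
                raise FormatError(f"mutation table missing column {col!r}")
        bad = set(self.data["variant_class"]) - set(VARIANT_CLASSES)
        if bad:
            raise FormatError(f"variant_class outside {VARIANT_CLASSES}: {sorted(bad)}")
        if (self.data["sample_id"].astype(str).str.strip() == "").any() or (
            self.data["gene"].astype(str).str.strip() == ""
        ).any():
            raise FormatError("empty sample_id or gene in mutation table")
        if self.data.duplicated().any():
            raise FormatError("fully duplicated mutation records")

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique().tolist())

    def mutated_samples(self, gene: str) -> set[str]:
        return set(self.data.loc[self.data["gene"] == gene, "sample_id"])


@dataclass
class CNVTable:
    """Gene-level copy-number states: one record per (sample, gene)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "gene", "state"):
            if col not in self.data.columns:
                raise FormatError(f"CNV table missing column {col!r}")
        bad = set(self.data["state"]) - set(CNV_STATES)
        if bad:
            raise FormatError(f"CNV state outside {CNV_STATES}: {sorted(bad)}")
        if self.data.duplicated(subset=["sample_id", "gene"]).any():
            raise FormatError("multiple CNV records for the same (sample, gene)")


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, unit: Unit | str) -> ExpressionMatrix:
    """Read a genes-x-samples TSV with a sample-id header row.

    The first header cell (usually "gene") is ignored. Duplicate gene symbols
    are preserved; duplicate sample headers are an error. Non-numeric cells
    raise :class:`FormatError` naming the offending row and column.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]  # first header cell ("gene") ignored
    dups = sorted({s for s in samples if samples.count(s) > 1})
    if dups:
        raise FormatError(f"{path}: duplicated sample header(s) {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, header=0)
    raw.columns = samples
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression file")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at gene "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    # exact per-cell float() conversion: pandas' fast parser is not
    # correctly rounded and would break full-precision round trips
    values = raw.astype(float)
    values.index = values.index.astype(str)
    values.index.name = "gene"
    return ExpressionMatrix(values, Unit(unit))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; round-trips through :func:`read_expression`."""
    df = m.data.copy()
    df.index.name = "gene"
    df.to_csv(Path(path), sep="\t")  # default shortest-repr floats: exact


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB member1 TAB member2 ...``

    Duplicate members within one line are deduplicated (first occurrence
    kept) with a warning; member order is otherwise preserved.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    logger.warning("GMT set %s: duplicate member %s dropped", name, g)
                    continue
                seen.add(g)
                members.append(g)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = (desc, members)
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Clinical / mutation / CNV TSVs
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV: sample_id, os_time_days, os_event, covariates...

    Unknown covariate columns are carried through as opaque categoricals.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: clinical table missing 'sample_id' column")
    df = df.set_index("sample_id")
    df["os_time_days"] = pd.to_numeric(df.get("os_time_days"), errors="coerce")
    df["os_event"] = pd.to_numeric(df.get("os_event"), errors="coerce")
    return ClinicalTable(df)


def read_mutations(path: str | Path) -> MutationTable:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    return MutationTable(df)


def read_cnv(path: str | Path) -> CNVTable:
    """Read gene-level CNV calls.

    Accepts either the 3-level alphabet {Loss, Neutral, Gain} or discrete
    integer calls in -2..2, which are collapsed {-2,-1}->Loss, {0}->Neutral,
    {1,2}->Gain. Anything else is an error.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if "state" in df.columns:
        as_num = pd.to_numeric(df["state"], errors="coerce")
        if as_num.notna().all():
            df = df.assign(state=as_num.map(_collapse_cnv_call))
    return CNVTable(df)


def _collapse_cnv_call(x: float) -> str:
    if x not in (-2, -1, 0, 1, 2):
        raise FormatError(f"integer CNV call {x} outside -2..2")
    return "Loss" if x < 0 else ("Gain" if x > 0 else "Neutral")


def read_cohort_tables(
    clinical_path: str | Path,
    mutation_path: str | Path,
    cnv_path: str | Path,
) -> tuple[ClinicalTable, MutationTable, CNVTable]:
    """Read the three per-sample annotation tables in one call."""
    return read_clinical(clinical_path), read_mutations(mutation_path), read_cnv(cnv_path)


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so abundances sum to 1e6.

    TPM_gs = FPKM_gs / sum_g FPKM_gs * 1e6. Per-sample scale invariant:
    multiplying one column by c > 0 leaves its output unchanged.
    """
    if m.unit is not Unit.FPKM:
        raise ValueError(f"fpkm_to_tpm requires FPKM input, got {m.unit.value}")
    colsums = m.data.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"all-zero FPKM sample column(s): {zero.index.tolist()}")
    tpm = m.data.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(tpm, Unit.TPM)


def log2_tpm1(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform; identity if already on the log scale."""
    if m.unit is Unit.LOG2TPM1:
        return m
    if m.unit is not Unit.TPM:
        raise ValueError(f"log2_tpm1 requires TPM input, got {m.unit.value}")
    return ExpressionMatrix(np.log2(m.data + 1.0), Unit.LOG2TPM1)
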