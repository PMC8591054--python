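"""Readers and writers for the formats the pipeline touches.

Expression matrices arrive as TSV or GCT with gene symbols in the first
column and sample ids in the header; clinical tables, immunophenoscore
tables and signature matrices as TSV; somatic mutations as MAF; gene sets
as GMT.  All loaders validate their invariants eagerly and raise
:class:`FormatError` subclasses with the offending location, so a malformed
cohort fails at load time rather than three stages later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "DimensionError",
    "ExpressionMatrix",
    "ClinicalTable",
    "MAFTable",
    "GeneSetCollection",
    "SignatureMatrix",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_maf",
    "read_gmt",
    "read_signature_matrix",
    "MAF_VARIANT_CLASSES",
]

#: MAF-standard Variant_Classification vocabulary.
MAF_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Silent",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)

_STAGE_LEVELS = {"Stage_I", "Stage_II", "Stage_III", "Stage_IV", "Stage_un"}
_T_LEVELS = {"T1", "T2", "T3", "T4", "TX", "T_un"}
_N_LEVELS = {"N0", "N1", "NX", "N_un"}
_M_LEVELS = {"M0", "M1", "MX", "M_un"}
_THERAPY_LEVELS = {"YES", "NO", "UN"}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class DimensionError(FormatError):
    """A matrix is too small or mis-shaped for the requested operation."""


@dataclass
class ExpressionMatrix:
    """Dense genes x samples matrix of log2-scale expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    n_dropped_rows: int = 0
    n_collapsed_rows: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DimensionError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids after loading")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if np.isnan(self.values).any():
            raise FormatError("expression matrix contains missing values")
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise DimensionError("expression matrix needs >= 2 genes and >= 2 samples")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), **kw)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        keep = [g for g in genes if g in idx]
        if len(keep) < 2:
            raise DimensionError("fewer than 2 requested genes present")
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(keep, list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates including overall survival."""

    table: pd.DataFrame
    n_excluded: int = 0

    REQUIRED = ("os_time", "os_event")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        if (t["os_time"] < 0).any():
            raise FormatError("negative os_time")
        if not t["os_event"].isin([0, 1]).all():
            raise FormatError("os_event must be 0/1")
        for col, levels in (
            ("stage", _STAGE_LEVELS),
            ("t_stage", _T_LEVELS),
            ("n_stage", _N_LEVELS),
            ("m_stage", _M_LEVELS),
            ("rt", _THERAPY_LEVELS),
            ("tmt", _THERAPY_LEVELS),
        ):
            if col in t.columns:
                bad = set(t[col].dropna().unique()) - levels
                if bad:
                    raise FormatError(f"column {col!r} has unknown levels {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def os_time(self) -> np.ndarray:
        return self.table["os_time"].to_numpy(dtype=float)

    @property
    def os_event(self) -> np.ndarray:
        return self.table["os_event"].to_numpy(dtype=int)

    @property
    def ips(self) -> np.ndarray | None:
        if "ips" in self.table.columns:
            return self.table["ips"].to_numpy(dtype=float)
        return None


@dataclass
class MAFTable:
    """Per-variant somatic mutation records (MAF v2.4-compatible)."""

    table: pd.DataFrame

    MANDATORY = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

    def __post_init__(self) -> None:
        missing = [c for c in self.MANDATORY if c not in self.table.columns]
        if missing:
            raise FormatError(f"MAF missing mandatory column(s): {', '.join(missing)}")
        if "Start_Position" in self.table.columns:
            pos = pd.to_numeric(self.table["Start_Position"], errors="coerce")
            if (pos.dropna() < 1).any():
                raise FormatError("MAF Start_Position must be >= 1 (1-based)")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.table["Tumor_Sample_Barcode"].unique())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> unique gene symbols."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class SignatureMatrix:
    """Reference basis: marker genes x immune cell types, linear scale."""

    marker_gene_ids: list[str]
    cell_type_names: list[str]
    basis: np.ndarray
    n_cell_types_expected: int = 22

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.shape != (len(self.marker_gene_ids), len(self.cell_type_names)):
            raise DimensionError("basis shape mismatch")
        if len(self.cell_type_names) != self.n_cell_types_expected:
            raise FormatError(
                f"expected {self.n_cell_types_expected} cell types, "
                f"got {len(self.cell_type_names)}"
            )
        if (self.basis < 0).any():
            raise FormatError("signature basis must be non-negative (linear scale)")
        if (self.basis.sum(axis=1) == 0).any():
            raise FormatError("signature basis has an all-zero marker row")


def _read_table_body(path: Path, skiprows: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: malformed header (no sample columns)")
    return df


def read_expression(path: str | Path, dialect: str = "tsv", log2_transform: bool = False) -> ExpressionMatrix:
    """Load a genes x samples expression table.

    Duplicate gene symbols are collapsed by the per-sample median; rows with
    any missing value are dropped (counted in ``n_dropped_rows``).  With
    ``log2_transform`` the values are mapped through log2(x+1) for cohorts
    delivered as raw counts or FPKM.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise FormatError(f"{path}: not a GCT file (missing #1.x version line)")
            fh.readline()  # dimension line, re-derived from the body
        df = _read_table_body(path, skiprows=2)
        # GCT carries a Description column after the id column
        if df.columns.size and df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
    elif dialect == "tsv":
        df = _read_table_body(path, skiprows=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise FormatError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
        df[col] = coerced

    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("read_expression: dropped %d row(s) with missing values", n_dropped)

    n_with_dups = len(df)
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).median()
    n_collapsed = n_with_dups - len(df)
    if n_collapsed:
        logger.info("read_expression: collapsed %d duplicate gene row(s) by median", n_collapsed)

    if df.shape[1] < 2:
        raise DimensionError(f"{path}: fewer than 2 samples")
    if log2_transform:
        df = np.log2(df + 1.0)
    return ExpressionMatrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
        n_dropped_rows=n_dropped,
        n_collapsed_rows=n_collapsed,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_symbol", float_format="%.10g")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Load a per-sample clinical TSV (sample_id index).

    Samples missing survival time or status are excluded, and the count is
    recorded on the returned table.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_before = len(df)
    missing = [c for c in ClinicalTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: clinical table missing column(s) {missing}")
    df = df.dropna(subset=list(ClinicalTable.REQUIRED))
    n_excluded = n_before - len(df)
    if n_excluded:
        logger.info("read_clinical: excluded %d sample(s) without survival data", n_excluded)
    df.index = df.index.astype(str)
    return ClinicalTable(df, n_excluded=n_excluded)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.table.to_csv(path, sep="\t", index_label="sample_id")


def read_maf(path: str | Path) -> MAFTable:
    """Load a MAF; lines starting with '#' are skipped, extra columns kept."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse as MAF ({exc})") from exc
    return MAFTable(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Load gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            seen: list[str] = []
            for g in genes:
                if g and g not in seen:
                    seen.append(g)
            sets[name] = seen
            descriptions[name] = desc
    if not sets:
        logger.warning("read_gmt: %s contains no gene sets", path)
    return GeneSetCollection(sets, descriptions)


def read_signature_matrix(path: str | Path, n_cell_types: int = 22) -> SignatureMatrix:
    """Load a marker-genes x cell-types reference basis (linear scale TSV)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
        n_cell_types_expected=n_cell_types,
    )
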