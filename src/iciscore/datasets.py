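"""Packaged reference fixtures.

Two small text assets ship with the package: a published-cohort clinical
summary (category/level/count) used as an integrity fixture, and a
22-cell-type synthetic signature basis for deconvolution tests.  Both are
plain TSV so they survive any source checkout.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import SignatureMatrix, read_signature_matrix

__all__ = [
    "CELL_TYPES",
    "CHECKPOINT_GENES",
    "ACTIVATION_GENES",
    "load_clinical_summary",
    "clinical_summary_cohort_size",
    "load_synthetic_signature",
]

#: The 22 immune cell types of the deconvolution basis (LM22 ordering).
CELL_TYPES = [
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
]

#: Immune checkpoint panel contrasted between ICI score groups.
CHECKPOINT_GENES = ["CD274", "CTLA4", "HAVCR2", "IDO1", "LAG3", "PDCD1"]

#: Immune activation panel contrasted between ICI score groups.
ACTIVATION_GENES = [
    "CD8A", "CXCL10", "CXCL9", "GZMA", "GZMB", "IFNG", "PRF1", "TBX2", "TNF",
]


def _data_path(name: str):
    return resources.files("iciscore.data").joinpath(name)


def load_clinical_summary() -> pd.DataFrame:
    """Category/level/count summary of the reference thyroid-cancer cohort."""
    with resources.as_file(_data_path("table1_clinical_summary.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def clinical_summary_cohort_size() -> int:
    """Cohort size implied by the clinical summary.

    Every category partitions the cohort, so per-category counts must sum to
    the same total; raises if the fixture is internally inconsistent.
    """
    df = load_clinical_summary()
    totals = df.groupby("category")["count"].sum()
    if totals.nunique() != 1:
        raise ValueError(f"inconsistent category totals: {totals.to_dict()}")
    return int(totals.iloc[0])


def load_synthetic_signature() -> SignatureMatrix:
    """The packaged 22-type synthetic deconvolution basis (linear scale)."""
    with resources.as_file(_data_path("synthetic_lm22.tsv")) as p:
        return read_signature_matrix(p)
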