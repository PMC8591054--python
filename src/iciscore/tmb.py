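"""Tumor mutation burden and driver-gene frequency contrasts from MAF.

TMB counts nonsilent variants per sample and divides by the captured exome
size in megabases (default 38 Mb).  Group contrasts run Fisher's exact test
per gene on mutated-sample counts; the waterfall export reproduces the
usual oncoplot matrix (most severe classification per gene/sample,
memo-sorted) as a TSV-ready frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MAFTable
from .survival import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "NONSILENT_CLASSES",
    "SEVERITY_ORDER",
    "TMBResult",
    "compute_tmb",
    "mutation_frequency_contrast",
    "waterfall_export",
]

#: Variant classes counted toward TMB (coding, protein-altering).
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Severity ranking for multi-hit cells in the waterfall matrix (most severe first).
SEVERITY_ORDER = [
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Nonstop_Mutation",
    "Translation_Start_Site",
    "Splice_Site",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Missense_Mutation",
    "Silent",
]
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


@dataclass
class TMBResult:
    table: pd.DataFrame          # nonsilent_count, tmb, absent_from_maf per sample
    exome_mb: float
    excluded_classes: list[str]

    @property
    def tmb(self) -> pd.Series:
        return self.table["tmb"]


def compute_tmb(maf: MAFTable, samples, exome_mb: float = 38.0,
                nonsilent_classes=NONSILENT_CLASSES) -> TMBResult:
    """Nonsilent mutation count per megabase for every requested sample.

    Samples absent from the MAF get count 0 and are flagged.  Variant
    classes outside the MAF-standard vocabulary are excluded with a warning
    and listed on the result.
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be > 0")
    samples = list(samples)
    df = maf.table
    known = set(nonsilent_classes) | {"Silent", "3'UTR", "5'UTR", "3'Flank", "5'Flank",
                                      "Intron", "IGR", "RNA", "Targeted_Region"}
    unknown = sorted(set(df["Variant_Classification"].unique()) - known) if len(df) else []
    if unknown:
        logger.warning("compute_tmb: excluding unknown classification(s) %s", unknown)
        df = df[~df["Variant_Classification"].isin(unknown)]
    nonsilent = df[df["Variant_Classification"].isin(nonsilent_classes)]
    counts = nonsilent.groupby("Tumor_Sample_Barcode").size()
    out = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    out["nonsilent_count"] = counts.reindex(samples).fillna(0).astype(int)
    out["tmb"] = out["nonsilent_count"] / exome_mb
    present = set(df["Tumor_Sample_Barcode"].unique()) if len(df) else set()
    out["absent_from_maf"] = [s not in present for s in samples]
    return TMBResult(out, exome_mb, unknown)


def _mutated_matrix(maf: MAFTable) -> pd.DataFrame:
    """Gene x sample boolean: sample counted once per gene (any variant)."""
    df = maf.table
    if df.empty:
        return pd.DataFrame()
    return pd.crosstab(df["Hugo_Symbol"], df["Tumor_Sample_Barcode"]).astype(bool)


def mutation_frequency_contrast(maf: MAFTable, group_assignment: pd.Series,
                                top_n: int = 30) -> pd.DataFrame:
    """Per-gene mutation frequency in two groups with Fisher exact contrast.

    ``group_assignment`` maps sample id -> group label (exactly two labels).
    The top ``top_n`` genes by pooled frequency are kept (frequency then
    alphabetical tie-break); BH adjustment runs across the kept genes.
    """
    groups = pd.Series(group_assignment)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("group_assignment must have exactly 2 groups")
    n_by_group = groups.value_counts()
    if (n_by_group < 1).any():
        raise ValueError("both groups must be non-empty")
    mut = _mutated_matrix(maf)
    if mut.empty:
        logger.warning("mutation_frequency_contrast: empty MAF")
        return pd.DataFrame(columns=["n_mut_0", "freq_0", "n_mut_1", "freq_1",
                                     "pooled_freq", "fisher_p", "adjusted_p"])
    mut = mut.reindex(columns=groups.index, fill_value=False)

    g0 = groups.index[groups == labels[0]]
    g1 = groups.index[groups == labels[1]]
    n0, n1 = len(g0), len(g1)
    rows = []
    for gene in mut.index:
        m0 = int(mut.loc[gene, g0].sum())
        m1 = int(mut.loc[gene, g1].sum())
        rows.append((gene, m0, m0 / n0, m1, m1 / n1, (m0 + m1) / (n0 + n1)))
    tab = (pd.DataFrame(rows, columns=["gene", "n_mut_0", "freq_0", "n_mut_1",
                                       "freq_1", "pooled_freq"])
           .sort_values(["pooled_freq", "gene"], ascending=[False, True])
           .set_index("gene")
           .head(top_n))
    pvals = [
        sps.fisher_exact(
            [[r.n_mut_0, n0 - r.n_mut_0], [r.n_mut_1, n1 - r.n_mut_1]]
        )[1]
        for r in tab.itertuples()
    ]
    tab["fisher_p"] = pvals
    tab["adjusted_p"] = bh_adjust(tab["fisher_p"].to_numpy())
    tab.attrs["group_labels"] = labels
    return tab


def waterfall_export(maf: MAFTable, group_assignment: pd.Series | None = None,
                     top_n: int = 30) -> pd.DataFrame:
    """Gene x sample matrix of the most severe variant classification.

    Genes are ordered by mutation frequency (descending); samples are
    memo-sorted: treated as binary mutation patterns over the ordered genes
    and sorted lexicographically so mutation blocks align.  Empty cells hold
    "".  Per-gene and per-sample totals ride along in ``attrs``.
    """
    df = maf.table
    if df.empty:
        return pd.DataFrame()
    if group_assignment is not None:
        keep = set(pd.Series(group_assignment).index)
        df = df[df["Tumor_Sample_Barcode"].isin(keep)]
    sev = df.assign(rank=df["Variant_Classification"].map(
        lambda c: _SEVERITY_RANK.get(c, len(SEVERITY_ORDER))))
    worst = (sev.sort_values("rank", kind="stable")
             .drop_duplicates(["Hugo_Symbol", "Tumor_Sample_Barcode"]))
    mat = worst.pivot(index="Hugo_Symbol", columns="Tumor_Sample_Barcode",
                      values="Variant_Classification").fillna("")

    freq = (mat != "").sum(axis=1)
    gene_order = freq.sort_values(ascending=False, kind="stable").index
    mat = mat.loc[gene_order]

    binary = (mat != "").to_numpy().astype(int)
    # memo-sort: most-frequent gene is the most significant bit
    keys = [tuple(-binary[:, j]) for j in range(binary.shape[1])]
    col_order = sorted(range(binary.shape[1]), key=lambda j: keys[j])
    mat = mat.iloc[:, col_order].head(top_n)
    mat.attrs["gene_totals"] = (mat != "").sum(axis=1).to_dict()
    mat.attrs["sample_totals"] = (mat != "").sum(axis=0).to_dict()
    return mat
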