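"""Prognostic value of the ICI score: survival, immune panels, GSEA, TMB.

Dichotomizes the score at its survival cutpoint, contrasts checkpoint and
activation panels, runs preranked GSEA between score groups, and integrates
the mutation data (TMB cutpoint, score-group contrast, correlation, driver
frequencies, waterfall).  Writes under results/survival_tmb/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import iciscore as ic
from iciscore.datasets import ACTIVATION_GENES, CHECKPOINT_GENES

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    expr = ic.read_expression(ROOT / "cohort" / "expression.tsv")
    clin = ic.read_clinical(ROOT / "cohort" / "clinical.tsv").table.loc[expr.sample_ids]
    scores = pd.read_csv(ROOT / "score_model" / "ici_scores.tsv", sep="\t", index_col=0)
    maf = ic.read_maf(ROOT / "cohort" / "mutations.maf")
    out = ROOT / "survival_tmb"
    out.mkdir(parents=True, exist_ok=True)

    s = scores["ici_score"].to_numpy()
    t, e = clin["os_time"].to_numpy(float), clin["os_event"].to_numpy(int)
    cut = ic.optimal_cutpoint(s, t, e)
    high = s > cut.threshold
    lr = ic.logrank_test(t, e, high.astype(int))
    km_hi, km_lo = ic.km_estimate(t[high], e[high]), ic.km_estimate(t[~high], e[~high])
    print(f"ICI score cutpoint {cut.threshold:.2f} "
          f"({cut.n_high} high / {cut.n_low} low); log-rank p = {lr.p_value:.3g}; "
          f"median OS high = {km_hi.median or 'not reached'}, "
          f"low = {km_lo.median or 'not reached'}")

    panel, skipped = ic.compare_gene_panels(expr, high, CHECKPOINT_GENES + ACTIVATION_GENES)
    panel.to_csv(out / "panel_tests.tsv", sep="\t")
    up = int((panel["direction"] == "up_in_high").sum())
    print(f"immune panels: {up}/{len(panel)} genes up in the high-score group")

    gene_sets = ic.GeneSetCollection({
        "IMMUNE_UP": [g for g in expr.gene_ids if g.startswith("SIGA")][:40],
        "IMMUNE_DN": [g for g in expr.gene_ids if g.startswith("SIGB")][:40],
        "RANDOM_SET": [g for g in expr.gene_ids if g.startswith("GENE")][:40],
    })
    deg = ic.differential_expression(expr, high.astype(int), lfc_threshold=0.0)
    gsea = ic.preranked_gsea(deg.table["log2_fold_change"], gene_sets,
                             n_perm=500, seed=6)
    gsea.table.to_csv(out / "gsea.tsv", sep="\t")
    top = gsea.table["nes"].abs().idxmax()
    print(f"GSEA: strongest set {top} (NES {gsea.table.loc[top, 'nes']:.2f}, "
          f"p {gsea.table.loc[top, 'nominal_p']:.3g})")

    tmb = ic.compute_tmb(maf, expr.sample_ids)
    tmb.table.to_csv(out / "tmb.tsv", sep="\t")
    tv = tmb.tmb.to_numpy()
    tmb_cut = ic.optimal_cutpoint(tv, t, e)
    _, p_wx = ic.wilcoxon_rank_sum(tv[high], tv[~high])
    rho, p_rho = ic.spearman(s, tv)
    print(f"TMB cutpoint {tmb_cut.threshold:.3f} mut/Mb; "
          f"TMB higher in high-score group (Wilcoxon p = {p_wx:.3g}); "
          f"score~TMB Spearman rho = {rho:.2f} (p = {p_rho:.3g})")

    group = pd.Series(np.where(high, "high", "low"), index=expr.sample_ids)
    drivers = ic.mutation_frequency_contrast(maf, group, top_n=30)
    drivers.to_csv(out / "driver_contrast.tsv", sep="\t")
    ic.waterfall_export(maf, group, top_n=30).to_csv(out / "waterfall.tsv", sep="\t")
    n_diff = int((drivers["adjusted_p"] < 0.05).sum())
    print(f"driver genes: {n_diff}/30 differ in frequency between score groups (BH < 0.05)")


if __name__ == "__main__":
    main()
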