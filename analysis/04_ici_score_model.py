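"""Build the ICI scoring model from the immunophenoscore stratification.

IPS survival cutpoint -> moderated-t differential expression -> consensus
clustering of samples on the DEGs -> gene types A/B (IPS-anchored) ->
Boruta reduction -> PC1 model and per-sample ICI scores.  Writes the frozen
model (JSON) and the score table under results/score_model/.
"""

from pathlib import Path

import pandas as pd

import iciscore as ic

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    expr = ic.read_expression(ROOT / "cohort" / "expression.tsv")
    clin = ic.read_clinical(ROOT / "cohort" / "clinical.tsv").table.loc[expr.sample_ids]
    out = ROOT / "score_model"
    out.mkdir(parents=True, exist_ok=True)

    ips = clin["ips"].to_numpy(float)
    cut = ic.optimal_cutpoint(ips, clin["os_time"], clin["os_event"])
    high = (ips > cut.threshold).astype(int)
    print(f"IPS cutpoint {cut.threshold:.2f}: {high.sum()} high / {(1 - high).sum()} low")

    deg = ic.differential_expression(expr, high)
    deg.table.to_csv(out / "deg.tsv", sep="\t", index_label="gene")
    degs = deg.significant_genes
    n_up = int((deg.table["direction"] == "up_in_high").sum())
    print(f"{len(degs)} DEGs (BH < 0.05, |log2FC| > 1): {n_up} up in IPS-high")

    deg_expr = expr.subset_genes(degs)
    cons = ic.consensus_cluster(deg_expr.values.T, (2, 3, 4, 5), n_resample=200, seed=4)
    assign = ic.assign_gene_types(deg_expr, cons.labels[cons.chosen_k], anchor=ips)
    assign.table.to_csv(out / "gene_types.tsv", sep="\t", index_label="gene")
    print(f"expression subtypes k = {cons.chosen_k}; gene types: "
          f"{len(assign.genes_A)} A / {len(assign.genes_B)} B "
          f"(reference cluster {assign.reference_cluster})")

    feats = deg_expr.to_frame().T
    gA = ic.boruta_select(feats[assign.genes_A], high, max_iter=30, seed=5)
    gB = ic.boruta_select(feats[assign.genes_B], high, max_iter=30, seed=5)
    gA = gA if len(gA) >= 2 else assign.genes_A
    gB = gB if len(gB) >= 2 else assign.genes_B
    print(f"Boruta kept {len(gA)} A and {len(gB)} B genes")

    model = ic.fit_ici_model(expr, gA, gB)
    model.to_json(out / "ici_model.json")
    scores = ic.score_samples(model, expr)
    scores.to_csv(out / "ici_scores.tsv", sep="\t", index_label="sample_id")
    print(f"PC1 explains {model.explained_var_A:.0%} (A) / "
          f"{model.explained_var_B:.0%} (B) of set variance; "
          f"score range [{scores['ici_score'].min():.2f}, {scores['ici_score'].max():.2f}]")


if __name__ == "__main__":
    main()
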