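"""End-to-end orchestration of the ICI analysis.

`run_pipeline` executes the full chain on one cohort — deconvolution,
immune subtypes, subtype survival, IPS cutpoint, differential expression,
expression subtypes, gene types A/B, Boruta reduction, the PC1-based ICI
score, score-group survival, checkpoint/activation panels, GSEA, and the
TMB stages — writing every stage's tables before the next stage begins and
finishing with a manifest of output hashes.  `validate_cohort` scores an
external immunotherapy cohort with a frozen model and tests response and
survival against the score groups.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import survival as surv
from .consensus import consensus_cluster
from .datasets import ACTIVATION_GENES, CHECKPOINT_GENES
from .deconv import deconvolve
from .enrichment import preranked_gsea
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, MAFTable, SignatureMatrix
from .signature import (ICIModel, assign_gene_types, boruta_select, compare_gene_panels,
                        differential_expression, fit_ici_model, score_samples)
from .tmb import compute_tmb, mutation_frequency_contrast, waterfall_export

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineResult", "ValidationReport", "run_pipeline", "validate_cohort"]


@dataclass
class PipelineParams:
    """Tunables of the full pipeline; every stochastic stage derives its
    seed from ``seed``."""

    k_range: tuple[int, ...] = (2, 3, 4, 5)
    n_resample: int = 200
    subsample_frac: float = 0.8
    deconv_method: str = "nnls"
    deconv_n_perm: int = 0
    deg_alpha: float = 0.05
    deg_lfc_threshold: float = 1.0
    boruta_max_iter: int = 30
    boruta_alpha: float = 0.05
    minprop: float = 0.1
    exome_mb: float = 38.0
    top_n_drivers: int = 30
    gsea_n_perm: int = 200
    gsea_min_size: int = 5
    seed: int = 0


@dataclass
class PipelineResult:
    """Artifacts of a pipeline run, keyed by stage."""

    fractions: pd.DataFrame
    subtype_labels: pd.Series
    subtype_k: int
    subtype_logrank: surv.LogrankResult
    fraction_contrasts: pd.DataFrame
    ips_cutpoint: surv.CutpointResult
    ips_high: pd.Series
    deg: pd.DataFrame
    n_deg: int
    expression_subtype_labels: pd.Series
    expression_subtype_k: int
    genes_A: list[str]
    genes_B: list[str]
    genes_A_reduced: list[str]
    genes_B_reduced: list[str]
    model: ICIModel
    scores: pd.DataFrame
    score_cutpoint: surv.CutpointResult
    score_high: pd.Series
    score_logrank: surv.LogrankResult
    panel_tests: pd.DataFrame
    gsea: pd.DataFrame | None
    tmb: pd.DataFrame | None
    tmb_cutpoint: surv.CutpointResult | None
    tmb_by_score_group: tuple[float, float] | None
    tmb_score_spearman: tuple[float, float] | None
    driver_contrast: pd.DataFrame | None
    manifest: dict


def _write(outdir: Path | None, name: str, df: pd.DataFrame, manifest: dict) -> None:
    if outdir is None:
        return
    path = outdir / name
    df.to_csv(path, sep="\t")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest["outputs"][name] = digest


def run_pipeline(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    signature: SignatureMatrix,
    maf: MAFTable | None = None,
    gene_sets: GeneSetCollection | None = None,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on one cohort.

    ``clinical`` must carry an ``ips`` column (the immunophenoscore drives
    the differential-expression split).  The MAF and gene sets are optional;
    their stages are skipped with a logged notice when absent.
    """
    p = params or PipelineParams()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "params": asdict(p), "stages": []}
    rng = np.random.SeedSequence(p.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(6)]

    ids = expression.sample_ids
    if list(clinical.table.index) != ids:
        clinical = ClinicalTable(clinical.table.loc[ids], clinical.n_excluded)
    times, events = clinical.os_time, clinical.os_event
    ips = clinical.ips
    if ips is None:
        raise ValueError("clinical table must carry an 'ips' column")

    # 1. deconvolution
    cf = deconvolve(expression, signature, method=p.deconv_method,
                    n_perm=p.deconv_n_perm, seed=seeds[0])
    fractions = cf.to_frame()
    _write(outdir, "fractions.tsv", pd.concat([fractions, cf.diagnostics], axis=1), manifest)
    manifest["stages"].append("deconvolution")

    # 2. ICI subtypes from fractions
    cons = consensus_cluster(fractions.to_numpy(), p.k_range, n_resample=p.n_resample,
                             subsample_frac=p.subsample_frac, seed=seeds[1])
    k = cons.chosen_k
    subtype = pd.Series(cons.labels[k], index=ids, name="ici_subtype")
    _write(outdir, "ici_subtypes.tsv", subtype.to_frame(), manifest)
    manifest["stages"].append("ici_subtypes")

    # 3. subtype survival + per-cell-type Kruskal-Wallis + PD1/PD-L1 contrasts
    subtype_lr = surv.logrank_test(times, events, subtype.to_numpy())
    rows = []
    for ct in fractions.columns:
        groups = [fractions.loc[subtype == c, ct].to_numpy() for c in sorted(subtype.unique())]
        stat, pv = surv.kruskal_wallis(*groups)
        rows.append((ct, stat, pv))
    gene_pos = {g: i for i, g in enumerate(expression.gene_ids)}
    for gname in ("PDCD1", "CD274"):
        if gname in gene_pos:
            vals = expression.values[gene_pos[gname]]
            groups = [vals[(subtype == c).to_numpy()] for c in sorted(subtype.unique())]
            stat, pv = surv.kruskal_wallis(*groups)
            rows.append((gname, stat, pv))
    contrasts = pd.DataFrame(rows, columns=["feature", "kruskal_stat", "p_value"]).set_index("feature")
    contrasts["adjusted_p"] = surv.bh_adjust(contrasts["p_value"].to_numpy())
    _write(outdir, "subtype_contrasts.tsv", contrasts, manifest)
    manifest["stages"].append("subtype_survival")

    # 4. IPS cutpoint
    ips_cut = surv.optimal_cutpoint(ips, times, events, minprop=p.minprop)
    ips_high = pd.Series(ips > ips_cut.threshold, index=ids, name="ips_high")
    _write(outdir, "ips_groups.tsv", ips_high.to_frame(), manifest)
    manifest["stages"].append("ips_cutpoint")

    # 5. differential expression between IPS groups
    deg = differential_expression(expression, ips_high.to_numpy().astype(int),
                                  alpha=p.deg_alpha, lfc_threshold=p.deg_lfc_threshold)
    deg_genes = deg.significant_genes
    _write(outdir, "deg.tsv", deg.table, manifest)
    manifest["stages"].append("differential_expression")
    if len(deg_genes) < 4:
        raise RuntimeError(f"pipeline: only {len(deg_genes)} DEGs; cannot build a signature")

    # 6. expression subtypes: consensus clustering of samples on DEG expression
    deg_expr = expression.subset_genes(deg_genes)
    cons2 = consensus_cluster(deg_expr.values.T, p.k_range, n_resample=p.n_resample,
                              subsample_frac=p.subsample_frac, seed=seeds[2])
    k2 = cons2.chosen_k
    expr_subtype = pd.Series(cons2.labels[k2], index=ids, name="expression_subtype")
    _write(outdir, "expression_subtypes.tsv", expr_subtype.to_frame(), manifest)
    manifest["stages"].append("expression_subtypes")

    # 7. gene types A/B, anchored on the immunophenoscore
    assign = assign_gene_types(deg_expr, expr_subtype.to_numpy(), anchor=ips)
    genes_A, genes_B = assign.genes_A, assign.genes_B
    _write(outdir, "gene_types.tsv", assign.table, manifest)
    manifest["stages"].append("gene_types")

    # 8. Boruta reduction, target = IPS group label
    target = ips_high.to_numpy().astype(int)
    feats = deg_expr.to_frame().T
    reduced = {}
    for label, genes in (("A", genes_A), ("B", genes_B)):
        if len(genes) >= 5:
            sel = boruta_select(feats[genes], target, max_iter=p.boruta_max_iter,
                                alpha=p.boruta_alpha, seed=seeds[3])
        else:
            sel = list(genes)
        if len(sel) < 2:
            logger.warning("pipeline: Boruta left <2 type-%s genes; keeping full list", label)
            sel = list(genes)
        reduced[label] = sel
    genes_A_red, genes_B_red = reduced["A"], reduced["B"]
    manifest["stages"].append("boruta")

    # 9. ICI model + scores
    model = fit_ici_model(expression, genes_A_red, genes_B_red)
    scores = score_samples(model, expression)
    if outdir is not None:
        model.to_json(outdir / "ici_model.json")
        manifest["outputs"]["ici_model.json"] = hashlib.sha256(
            (outdir / "ici_model.json").read_bytes()).hexdigest()
    _write(outdir, "ici_scores.tsv", scores, manifest)
    manifest["stages"].append("ici_model")

    # 10. score cutpoint + survival
    score_cut = surv.optimal_cutpoint(scores["ici_score"].to_numpy(), times, events,
                                      minprop=p.minprop)
    score_high = pd.Series(scores["ici_score"] > score_cut.threshold, index=ids,
                           name="ici_high")
    score_lr = surv.logrank_test(times, events, score_high.to_numpy().astype(int))
    _write(outdir, "score_groups.tsv", score_high.to_frame(), manifest)
    manifest["stages"].append("score_cutpoint")

    # 11. checkpoint / activation panels between score groups
    panel = CHECKPOINT_GENES + ACTIVATION_GENES
    panel_tests, skipped = compare_gene_panels(expression, score_high.to_numpy(), panel)
    if skipped:
        logger.info("pipeline: panel genes absent from cohort: %s", skipped)
    _write(outdir, "panel_tests.tsv", panel_tests, manifest)
    manifest["stages"].append("panel_tests")

    # 12. GSEA between score groups (ranking = log2FC high vs low ICI score)
    gsea_table = None
    if gene_sets is not None and len(gene_sets) > 0:
        deg_scores = differential_expression(expression, score_high.to_numpy().astype(int),
                                             alpha=p.deg_alpha, lfc_threshold=0.0)
        ranking = deg_scores.table["log2_fold_change"]
        gres = preranked_gsea(ranking, gene_sets, n_perm=p.gsea_n_perm,
                              min_size=p.gsea_min_size, seed=seeds[4])
        gsea_table = gres.table
        _write(outdir, "gsea.tsv", gsea_table, manifest)
        manifest["stages"].append("gsea")
    else:
        logger.info("pipeline: no gene sets supplied; GSEA skipped")

    # 13. TMB integration
    tmb_table = tmb_cut = tmb_by_group = tmb_rho = driver_tab = None
    if maf is not None and len(maf) > 0:
        tmb_res = compute_tmb(maf, ids, exome_mb=p.exome_mb)
        tmb_table = tmb_res.table
        tmb_vals = tmb_res.tmb.to_numpy()
        try:
            tmb_cut = surv.optimal_cutpoint(tmb_vals, times, events, minprop=p.minprop)
        except ValueError as exc:
            logger.warning("pipeline: TMB cutpoint not fit (%s)", exc)
        hi = score_high.to_numpy()
        tmb_by_group = surv.wilcoxon_rank_sum(tmb_vals[hi], tmb_vals[~hi])
        tmb_rho = surv.spearman(scores["ici_score"].to_numpy(), tmb_vals)
        group = pd.Series(np.where(hi, "high", "low"), index=ids)
        driver_tab = mutation_frequency_contrast(maf, group, top_n=p.top_n_drivers)
        _write(outdir, "tmb.tsv", tmb_table, manifest)
        _write(outdir, "driver_contrast.tsv", driver_tab, manifest)
        wf = waterfall_export(maf, group, top_n=p.top_n_drivers)
        _write(outdir, "waterfall.tsv", wf, manifest)
        manifest["stages"].append("tmb")
    else:
        logger.info("pipeline: no MAF supplied; mutation stages skipped")

    if outdir is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    return PipelineResult(
        fractions=fractions, subtype_labels=subtype, subtype_k=k,
        subtype_logrank=subtype_lr, fraction_contrasts=contrasts,
        ips_cutpoint=ips_cut, ips_high=ips_high, deg=deg.table, n_deg=len(deg_genes),
        expression_subtype_labels=expr_subtype, expression_subtype_k=k2,
        genes_A=genes_A, genes_B=genes_B,
        genes_A_reduced=genes_A_red, genes_B_reduced=genes_B_red,
        model=model, scores=scores, score_cutpoint=score_cut, score_high=score_high,
        score_logrank=score_lr, panel_tests=panel_tests, gsea=gsea_table,
        tmb=tmb_table, tmb_cutpoint=tmb_cut, tmb_by_score_group=tmb_by_group,
        tmb_score_spearman=tmb_rho, driver_contrast=driver_tab, manifest=manifest,
    )


@dataclass
class ValidationReport:
    """Immunotherapy-cohort validation of a frozen ICI model.

    Responder definition: CR/PR = responder, SD/PD = non-responder.
    """

    scores: pd.DataFrame
    cutpoint: surv.CutpointResult | None
    high_group: pd.Series
    score_by_response: tuple[float, float] | None     # Wilcoxon stat, p
    response_by_group_chi2: tuple[float, float] | None
    responder_rate_high: float | None
    responder_rate_low: float | None
    logrank: surv.LogrankResult | None
    cutpoint_source: str = "refit"


def validate_cohort(
    model: ICIModel,
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    response: pd.Series | None = None,
    minprop: float = 0.1,
    training_cutpoint: float | None = None,
) -> ValidationReport:
    """Score an external cohort and test response/survival by score group.

    The score cutpoint is re-fit on the external cohort by default (pass
    ``training_cutpoint`` to transfer the training threshold instead); the
    choice is recorded on the report.
    """
    scores = score_samples(model, expression)
    ids = expression.sample_ids
    clin = clinical.table.loc[ids]
    times = clin["os_time"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=int)
    s = scores["ici_score"].to_numpy()

    if training_cutpoint is not None:
        cut, source = None, "training"
        thr = training_cutpoint
    else:
        cut = surv.optimal_cutpoint(s, times, events, minprop=minprop)
        thr, source = cut.threshold, "refit"
    high = pd.Series(s > thr, index=ids, name="ici_high")

    lr = surv.logrank_test(times, events, high.to_numpy().astype(int))

    wx = chi2 = None
    rate_hi = rate_lo = None
    if response is not None:
        resp = pd.Series(response).loc[ids]
        responder = resp.isin(["CR", "PR"]).to_numpy()
        wx = surv.wilcoxon_rank_sum(s[responder], s[~responder])
        table = np.array([
            [(high & responder).sum(), (high & ~responder).sum()],
            [(~high & responder).sum(), (~high & ~responder).sum()],
        ])
        chi2 = surv.chi_square_table(table)
        rate_hi = float(responder[high.to_numpy()].mean()) if high.any() else np.nan
        rate_lo = float(responder[~high.to_numpy()].mean()) if (~high).any() else np.nan

    return ValidationReport(scores, cut, high, wx, chi2, rate_hi, rate_lo, lr, source)
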