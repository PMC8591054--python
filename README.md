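# iciscore

Immune-cell-infiltration (ICI) subtyping and scoring for bulk tumor
expression cohorts.

Tumors differ widely in how strongly immune cells infiltrate them, and that
infiltration predicts both prognosis and response to immune checkpoint
blockade. This package reimplements, as a tested and reusable pipeline, a
common bioinformatic strategy for quantifying that axis from bulk RNA
profiles, aimed at computational oncologists who want each step exercisable
and verifiable in isolation:

1. **Deconvolution** — estimate the fractions of 22 immune cell types per
   sample against an LM22-style signature basis (NNLS, or a ν-SVR
   re-implementation of the classic approach), with permutation-based fit
   diagnostics.
2. **ICI subtypes** — resampled PAM consensus clustering of the fractions,
   with CDF/PAC model selection for the number of subtypes.
3. **A/B gene signature** — split the cohort at the survival-optimal
   immunophenoscore (IPS) cutpoint, find differentially expressed genes
   with an empirical-Bayes moderated *t*-test (BH-adjusted *p* < 0.05,
   |log2FC| > 1), partition them into gene types A and B by their
   association with the expression subtypes, and prune each list with a
   Boruta-style all-relevant selector.
4. **ICI score** — per sample,

   `ICI_score = PC1(A) − PC1(B)`

   i.e. the first-principal-component projection on gene set A minus that
   on gene set B, with centering vectors and sign-fixed loadings frozen so
   external cohorts can be scored without refitting.
5. **Downstream** — Kaplan–Meier / log-rank survival by maximally selected
   score cutpoints, checkpoint and activation gene panels, preranked GSEA,
   tumor mutation burden (nonsilent variants per Mb from MAF) with driver
   frequency contrasts, and immunotherapy-response validation
   (CR/PR vs SD/PD) on cohorts scored with the frozen model.

Because the real cohorts such a study uses are access-controlled downloads,
the package ships a synthetic-cohort generator (`iciscore.simulate`) whose
latent immune phenotype drives cell fractions, signature-gene expression,
IPS, survival hazard, mutation burden and therapy response — so every stage
has a recoverable ground truth.

## Worked example

The `analysis/` directory holds the numbered study drivers; each reads the
previous step's files under `results/` and prints what it found:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_deconvolution.py
python analysis/03_ici_subtypes.py
python analysis/04_ici_score_model.py
python analysis/05_survival_tmb.py
python analysis/06_validation.py
```

Output of a full run:

```
cohort: 300 samples, 2000 genes, 3246 variants, 34 deaths -> results/cohort
deconvolved 300 samples: MAE vs truth = 0.0118, 100% of fits beat the shuffled-marker null (p < 0.05)
chosen k = 3 (PAC 0.000); ARI vs planted phenotypes = 1.000; subtype log-rank p = 7.37e-05; 15/22 cell types differ across subtypes (BH < 0.05)
IPS cutpoint 4.31: 228 high / 72 low
420 DEGs (BH < 0.05, |log2FC| > 1): 200 up in IPS-high
expression subtypes k = 3; gene types: 200 A / 220 B (reference cluster 1)
Boruta kept 55 A and 60 B genes
PC1 explains 81% (A) / 80% (B) of set variance; score range [-27.32, 32.15]
ICI score cutpoint -11.73 (208 high / 92 low); log-rank p = 1.32e-07; median OS high = not reached, low = not reached
immune panels: 15/15 genes up in the high-score group
GSEA: strongest set IMMUNE_UP (NES 1.95, p 0.004)
TMB cutpoint 0.237 mut/Mb; TMB higher in high-score group (Wilcoxon p = 1.07e-26); score~TMB Spearman rho = 0.75 (p = 1.48e-56)
driver genes: 7/30 differ in frequency between score groups (BH < 0.05)
validation (n=250): responder rate 53% high vs 7% low (chi-square p = 8.09e-13); OS log-rank p = 0.000456
```

Reading the numbers: consensus clustering of the deconvolved fractions
finds exactly the three planted immune phenotypes (ARI = 1.0); the ICI
score built from the A/B signature separates a high-score group with
significantly better overall survival, higher checkpoint/activation gene
expression and higher mutation burden; and on a fresh cohort scored with
the frozen model, high-score patients respond to therapy far more often
(53% vs 7%).

The same stages are scriptable through one CLI (`ici sim`, `ici deconv`,
`ici cluster`, `ici score fit/apply`, `ici cutpoint`, `ici tmb`,
`ici gsea`, `ici pipeline run/validate`), and `iciscore.run_pipeline`
executes the whole chain from a single call with a per-stage output
manifest.

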