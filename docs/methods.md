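# Methods

This note documents the models and procedures behind `iciscore`, their
assumptions, the defaults that matter, and what the synthetic benchmark
does and does not establish.

## The synthetic cohort generator

`simulate.SimulationConfig` / `simulate_cohort` produce a cohort in which a
single latent per-sample immune-activity score, organised into discrete
phenotypes, drives every observable. Defaults (300 samples, 3 phenotypes,
2,000 genes) define the benchmark conditions used throughout the tests.

* **Phenotypes and latent score.** Samples are assigned uniformly to
  `n_phenotypes` groups; phenotype means span +1 … −1 on the latent axis
  with within-phenotype SD 0.35, and the score is standardized cohort-wide.
  Three phenotypes model the familiar hot / intermediate / cold gradient.
* **Cell fractions.** Per phenotype, a Dirichlet concentration vector over
  the 22 reference cell types: baseline 1 everywhere plus 8 on a
  phenotype-specific block of five types (hot: CD8 T, activated CD4
  memory, Tfh, activated NK, M1; cold: resting CD4 memory, M0, M2,
  activated DC, resting mast — mirroring reported hot/cold infiltration
  patterns). Total concentration ≈ 62 gives clearly separated but noisy
  compositions.
* **Expression.** Marker genes mix the packaged signature basis linearly
  with the true fractions, then log2(1+x). Signal set A rises, set B falls,
  by 1 log2 unit per unit latent score around gene-specific baselines
  (U(4,8)); the first fifteen A genes carry the checkpoint/activation
  panel symbols (CD274, PDCD1, CD8A, …) so panel contrasts are meaningful.
  Remaining genes are baseline + noise. Gaussian noise SD 0.5 on the log2
  scale throughout.
* **Immunophenoscore.** `clip(5.5 + 1.5·z + N(0, 0.8), 0, 10)` — a noisy
  monotone readout of latent activity on the 0–10 scale on which published
  IPS thresholds live.
* **Survival.** Exponential proportional hazards,
  h(z) = (ln2 / 1800 days) · exp(β·z) with β = −0.8 by default (immune-hot
  protective). Censoring is uniform on (0, c_max) with c_max solved by
  bisection so the expected event rate matches 1 − censoring_rate
  (default censoring 0.9, close to the heavy censoring of real
  thyroid-cancer cohorts). The exponential choice makes the log-rank test
  correctly specified, so null calibration checks are meaningful.
* **Mutations.** Per-phenotype Poisson counts (16 → 6 from hot to cold;
  divided by a 38 Mb exome this spans the 0.15–0.45 mut/Mb range where
  published TMB thresholds sit) scattered over a 50-gene driver pool with
  Zipf-like weights; the five most frequent drivers are 3× enriched in the
  hot phenotype so group frequency contrasts carry signal. Variant classes
  are drawn with realistic proportions (60% missense, 15% silent, …).
* **Response.** P(responder) = logistic(−0.5 + 1.5·z); responders split
  CR/PR (30/70), non-responders SD/PD (40/60). The binary collapse CR/PR
  vs SD/PD follows immunotherapy-cohort convention.

All randomness flows from the config seed through one `numpy` Generator;
no global state is touched, and repeated calls are bitwise identical.

**What the generator does not emulate:** gene–gene correlation beyond the
single latent axis, batch effects, subclonal mutation structure,
non-proportional hazards, or cohort-level confounding. Passing tests
therefore demonstrate correctness of the machinery and recoverability of a
planted signal — not performance on real tumors, where the immune axis is
weaker and confounded.

## Deconvolution

Expression is de-logged (2^x) before fitting: signature deconvolution
assumes mixing is linear in transcript abundance. Two solvers share the
contract (non-negative coefficients normalized to sum 1, per-sample RMSE /
Pearson r / permutation p):

* **nnls** (default in tests): non-negative least squares on the raw linear
  scale. Exact on noiseless mixtures and invariant to per-sample positive
  rescaling.
* **nusvr**: ν-SVR (linear kernel) at ν ∈ {0.25, 0.5, 0.75} on jointly
  standardized data, keeping the lowest-RMSE fit and clipping negative
  coefficients — a re-implementation of the classic signature-based
  algorithm. The z-normalization is applied only here; under the NNLS
  non-negativity constraint an affine shift would break exact recovery.

The permutation null is shared across samples: each of `n_perm` draws
shuffles the marker vector of a random cohort sample and re-deconvolves;
permutation p = (1 + #null r ≥ observed r)/(n_perm + 1), hence never 0.

At least 50% of the signature's markers must be present. The packaged
22-type basis is synthetic (5 markers per type, own-type values 80–150 vs
off-type 1–10); real LM22 can be supplied as TSV.

## Consensus clustering

PAM (k-medoids) is implemented as BUILD + SWAP on Euclidean distances;
ties resolve to the smallest index, making results deterministic. Ward
hierarchical clustering is available as the alternative base learner.
Per k, `n_resample` subsamples of ⌈0.8·n⌉ samples are partitioned and
consensus(i,j) = co-cluster count / co-sampled count; final labels cut an
average-linkage tree of 1 − consensus. Columns are standardized by default
(switchable). k is chosen by PAC — the fraction of off-diagonal consensus
entries in (0.1, 0.9), argmin with ties to the smaller k — because visual
CDF inspection is not automatable; a delta-area rule and a manual override
are provided. The benchmark uses 200 resamples: on the default cohort the
consensus matrices are already essentially binary there, and the choice
keeps the full pipeline comfortably within a single-CPU budget (1,000
resamples reproduce the same selection).

## Differential expression

A moderated two-sample t-statistic: per-gene pooled variances are shrunk
toward a prior fitted by method of moments on the log residual variances
(digamma/trigamma moment equations, trigamma inverted by Newton
iteration); the statistic uses s̃²_g = (d₀s₀² + d_g s_g²)/(d₀ + d_g) with
d₀ + d_g degrees of freedom, capped at the pooled residual df across
genes. `prior_df=0` recovers the ordinary t-test; a Wilcoxon fallback
exists. Verified in the test suite against the reference empirical-Bayes
implementation in R to ~1e-8 on t and p. Calls require BH-adjusted
p < 0.05 and |log2FC| > 1; zero-variance genes get p = 1 and are logged.

## Gene types A and B

Per DEG, one-vs-rest point-biserial correlations against every sample
cluster indicator are computed. Because covariances against the k
indicators sum to zero, the maximal one-vs-rest correlation is
non-negative for every non-flat gene, so "positive association" alone
cannot split the DEGs. The split is therefore oriented by a reference
cluster: the cluster with the highest mean anchor covariate when one is
supplied (the pipeline passes the IPS, making A the genes aligned with the
immune-high subtype), otherwise the cluster best-matching the plurality of
genes. A gene is type A iff its correlation with the reference indicator
is positive. The reference cluster and per-gene statistics are reported so
users can audit the orientation.

## Boruta reduction

Each iteration appends a shuffled shadow copy of every active feature,
fits a 100-tree random forest (impurity importances — the standard choice
in Python implementations, and ~50× cheaper than permutation importances
at shadow-doubled width), and scores a hit for features beating the
strongest shadow. Hits accumulate into binomial tests (checked from
iteration 5 on) whose threshold is Bonferroni-adjusted across active
features; without that adjustment the every-iteration looks would not
control the null confirmation rate. Features still tentative at the end
are confirmed iff their median importance exceeds the median shadow
maximum. Target variable in the pipeline: the IPS-derived high/low label
(alternatives — cluster label, survival status — can be passed directly).

## The ICI score

Per gene set, genes are centered at their training means (no unit-variance
scaling — centering only, switch left to the caller by pre-scaling) and
the first right singular vector over samples is the loading. The PCA sign
ambiguity is resolved by requiring the score to correlate positively with
the set's per-sample mean expression, which makes refits bit-identical
and orients score_A with immune-high expression. ICI score = score_A −
score_B. Frozen models serialize to JSON (gene lists, centers, loadings,
training score mean/SD). Scoring an external cohort tolerates up to 20%
missing genes per set (imputed at the training mean, i.e. zero centered
contribution, with a warning); below 80% coverage scoring refuses.

## Survival machinery

Kaplan–Meier and the log-rank test are implemented directly because the
cutpoint search needs the standardized two-group statistic
(O−E)/√V, which wrapper libraries do not expose; both are cross-checked
against `lifelines` in the tests. The multi-group statistic uses the full
hypergeometric covariance with a pseudo-inverse on k−1 groups. The
"optimal cutpoint" is the maximally selected rank statistic: candidates
are observed score values (ties at the threshold go to the low group),
admissible when both sides hold ≥ minprop (default 0.1) of the cohort, and
the |z|-maximizing candidate wins with ties to the smallest threshold. No
selection-adjusted p-value is attached by default (matching common usage
of the method); the standardized statistic is reported so users can apply
a corrected reference distribution if desired. Rank tests (Wilcoxon with
exact enumeration for combined n ≤ 10 without ties, Kruskal–Wallis,
Spearman, Pearson chi-square without continuity correction, BH step-up)
wrap the standard scipy/statsmodels routines.

## TMB and waterfall

TMB = nonsilent variant count / exome size, default 38 Mb (configurable);
the nonsilent set is the standard protein-altering classes (missense,
nonsense, nonstop, frameshifts, in-frame indels, splice site, translation
start). Samples absent from the MAF count 0 and are flagged; unknown
classification strings are excluded with a report. Driver contrasts count
a sample once per gene, keep the top 30 by pooled frequency
(frequency-then-alphabetical tie-break) and test each with Fisher's exact
test, BH across the kept genes. The waterfall matrix keeps the most severe
classification per cell (severity order documented in `tmb.SEVERITY_ORDER`)
and memo-sorts samples lexicographically over the frequency-ordered genes.

## Enrichment

Preranked GSEA uses the weighted running-sum ES (hit increments ∝
|score|^weight, default weight 1; miss decrement 1/(N−Nh)), a gene-label
permutation null at the observed set size (phenotype permutation would
need per-sample recomputation the upstream ranking does not define), NES =
ES / mean |null ES| of matching sign, +1-corrected nominal p, and the
pooled positive/negative FDR. ORA is the upper-tail hypergeometric with BH
across tested sets; namespace-tagged set names (`BP:…`) get top-k flags
per ontology. No licensed gene-set collections are bundled; tests and the
analysis scripts build tiny synthetic GMT-style collections.

## Pipeline and validation

`run_pipeline` is a pure function of (inputs, params): stage seeds derive
from one master seed via `SeedSequence`, every stage writes its tables
before the next begins, and a manifest records parameters, stage order and
SHA-256 of every output, so reruns are hash-identical. Missing optional
inputs (MAF, gene sets) skip their stages with a logged notice. External
validation re-fits the score cutpoint on the external cohort by default
(a training-threshold transfer mode is available and recorded in the
report), then tests score-by-responder (Wilcoxon), responder-proportion by
group (chi-square) and OS by group (log-rank).

## Problem sizes and numerical choices

The shipped analysis and acceptance runs use n = 300 samples, 2,000 genes,
200 consensus resamples, 30 Boruta iterations, and 200–500 GSEA
permutations — sizes at which every planted structure is recovered
essentially perfectly and a full run completes in about half a minute on
one CPU. Degenerate inputs fail loudly: < 2 genes per scoring set, a
single cluster for gene typing, constant scores for cutpoints, empty
groups for rank tests. Fraction rows are validated to sum to 1 within
1e-6; consensus matrices are symmetrized with unit diagonal; permutation
p-values carry the +1 correction and can never be 0.

## Known limitations

* The A/B orientation depends on the anchor covariate; with no anchor the
  plurality rule can flip A and B on balanced designs (the score's sign
  flips with it, which the absolute-value invariants tolerate but users
  should audit).
* ν-SVR mode is far slower than NNLS and its coefficients are not exact on
  noiseless mixtures; it exists for methodological fidelity.
* The cutpoint search maximizes over thresholds without adjusting its own
  p-value for selection.
* Synthetic-benchmark performance overstates real-data performance by
  construction (see generator caveats above).
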