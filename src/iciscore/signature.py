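"""Construction of the immune-cell-infiltration (ICI) score.

The chain: split the cohort by immunophenoscore, find differentially
expressed genes with an empirical-Bayes moderated t-test, split the DEGs
into gene types A and B by their association with the expression subtypes,
prune each list with a Boruta-style all-relevant selector, and summarize
each pruned set by its first principal component.  The per-sample ICI score
is the PC1 projection on set A minus the PC1 projection on set B; the model
(gene lists, centering vectors, sign-fixed loadings) is frozen so external
cohorts can be scored without refitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .io import ExpressionMatrix
from .survival import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "DEGResult",
    "GeneTypeAssignment",
    "ICIModel",
    "differential_expression",
    "assign_gene_types",
    "boruta_select",
    "fit_ici_model",
    "score_samples",
    "compare_gene_panels",
]


# --- moderated t -------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on the log residual variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else (np.inf, 1.0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


@dataclass
class DEGResult:
    """Per-gene differential-expression table with EB-shrunken variances."""

    table: pd.DataFrame          # log2_fold_change, t, p_value, adjusted_p, direction
    prior_df: float              # fitted d0
    prior_var: float             # fitted s0^2
    lfc_threshold: float
    alpha: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["direction"] != "ns"])


def differential_expression(
    expr: ExpressionMatrix,
    group_labels,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    prior_df: float | None = None,
    method: str = "moderated_t",
) -> DEGResult:
    """Two-group DE with an empirical-Bayes moderated t-statistic.

    ``group_labels`` is a binary vector over samples (1 = high group); the
    fold change is high-group mean minus low-group mean in log2 units.  The
    per-gene variance is shrunk toward a prior fitted by method of moments
    on the observed residual variances; ``prior_df`` overrides the fitted
    d0 (0 recovers the ordinary t-test).  A gene is called when its BH
    adjusted p < ``alpha`` and |log2FC| > ``lfc_threshold``.
    """
    g = np.asarray(group_labels).astype(int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group_labels must be binary 0/1")
    n1, n0 = int(g.sum()), int((1 - g).sum())
    if min(n1, n0) < 2:
        raise ValueError("both groups need >= 2 samples")

    X = expr.values
    hi, lo = X[:, g == 1], X[:, g == 0]
    lfc = hi.mean(axis=1) - lo.mean(axis=1)

    if method == "wilcoxon":
        pvals = np.array([wilcoxon_rank_sum(hi[i], lo[i])[1] if hi[i].std() + lo[i].std() > 0 else 1.0
                          for i in range(X.shape[0])])
        tstat = np.full(X.shape[0], np.nan)
        d0, s0_sq = np.nan, np.nan
    elif method == "moderated_t":
        df_resid = n1 + n0 - 2
        s2 = ((n1 - 1) * hi.var(axis=1, ddof=1) + (n0 - 1) * lo.var(axis=1, ddof=1)) / df_resid
        if prior_df is None:
            d0, s0_sq = _fit_variance_prior(s2, df_resid)
        else:
            d0 = float(prior_df)
            _, s0_sq = _fit_variance_prior(s2, df_resid)
        if d0 == 0:
            s2_post = s2.copy()
        elif np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
        zero_var = s2_post <= 0
        if zero_var.any():
            logger.info("differential_expression: %d zero-variance gene(s), p set to 1",
                        int(zero_var.sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(zero_var, 0.0, lfc / np.where(zero_var, 1.0, se))
        if np.isinf(d0):
            pvals = 2.0 * sps.norm.sf(np.abs(tstat))
        else:
            # total df capped at the pooled residual df across all genes
            total_df = min(df_resid + d0, df_resid * X.shape[0])
            pvals = 2.0 * sps.t.sf(np.abs(tstat), total_df)
        pvals = np.where(zero_var, 1.0, pvals)
    else:
        raise ValueError(f"unknown method {method!r}")

    adj = bh_adjust(pvals)
    direction = np.full(X.shape[0], "ns", dtype=object)
    sig = (adj < alpha) & (np.abs(lfc) > lfc_threshold)
    direction[sig & (lfc > 0)] = "up_in_high"
    direction[sig & (lfc < 0)] = "up_in_low"
    table = pd.DataFrame(
        {"log2_fold_change": lfc, "t": tstat, "p_value": pvals,
         "adjusted_p": adj, "direction": direction},
        index=expr.gene_ids,
    )
    return DEGResult(table, float(d0), float(s0_sq), lfc_threshold, alpha)


# --- gene types A/B ----------------------------------------------------------

@dataclass
class GeneTypeAssignment:
    table: pd.DataFrame          # association, best_cluster, r_reference, gene_type
    reference_cluster: int

    @property
    def genes_A(self) -> list[str]:
        return list(self.table.index[self.table["gene_type"] == "A"])

    @property
    def genes_B(self) -> list[str]:
        return list(self.table.index[self.table["gene_type"] == "B"])


def assign_gene_types(expr_of_degs: ExpressionMatrix, gene_cluster_labels,
                      anchor=None) -> GeneTypeAssignment:
    """Split DEGs into gene types A and B by cluster association.

    Per gene, one-vs-rest point-biserial correlations against every sample
    cluster indicator are computed.  A reference cluster orients the split:
    the cluster with the highest mean ``anchor`` value (e.g. the
    immunophenoscore) when an anchor is supplied, otherwise the cluster
    that best matches the plurality of genes.  A gene is type A iff its
    correlation with the reference-cluster indicator is positive.
    """
    labels = np.asarray(gene_cluster_labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("gene-type assignment needs >= 2 sample clusters")
    X = expr_of_degs.values  # genes x samples
    n = X.shape[1]
    if labels.size != n:
        raise ValueError("cluster labels must match sample count")

    Xc = X - X.mean(axis=1, keepdims=True)
    xsd = X.std(axis=1)
    corr = np.zeros((X.shape[0], uniq.size))
    for j, c in enumerate(uniq):
        ind = (labels == c).astype(float)
        ind_c = ind - ind.mean()
        denom = xsd * ind.std() * n
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc @ ind_c) / np.where(denom == 0, 1.0, denom)
        corr[:, j] = np.where(denom == 0, 0.0, r)

    best_idx = corr.argmax(axis=1)
    association = corr[np.arange(X.shape[0]), best_idx]

    if anchor is not None:
        anchor = np.asarray(anchor, dtype=float)
        means = [anchor[labels == c].mean() for c in uniq]
        ref_idx = int(np.argmax(means))
    else:
        counts = np.bincount(best_idx, minlength=uniq.size)
        ref_idx = int(np.argmax(counts))
    r_ref = corr[:, ref_idx]
    gene_type = np.where(r_ref > 0, "A", "B")

    table = pd.DataFrame(
        {"association": association,
         "best_cluster": uniq[best_idx],
         "r_reference": r_ref,
         "gene_type": gene_type},
        index=expr_of_degs.gene_ids,
    )
    return GeneTypeAssignment(table, int(uniq[ref_idx]))


# --- Boruta ------------------------------------------------------------------

def boruta_select(
    features: pd.DataFrame,
    target,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 100,
) -> list[str]:
    """Boruta all-relevant feature selection with shadow features.

    Each iteration appends a shuffled copy of every still-active feature,
    fits a random-forest importance estimator, and scores a "hit" for
    features beating the strongest shadow.  Binomial tests at ``alpha``
    (Bonferroni-adjusted across active features) confirm (more hits than
    chance) or reject (fewer) features across iterations; features still
    tentative at ``max_iter`` are resolved by comparing their median
    importance to the median shadow maximum.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10")
    X = pd.DataFrame(features)
    if X.shape[1] < 5:
        raise ValueError("Boruta needs >= 5 features")
    y = np.asarray(target)
    uniq = np.unique(y)
    if uniq.size < 2:
        raise ValueError("target needs >= 2 levels")
    classification = uniq.size <= 10
    rng = np.random.default_rng(seed)

    names = list(X.columns)
    status = {f: "tentative" for f in names}        # tentative/confirmed/rejected
    hits = {f: 0 for f in names}
    trials = 0
    imp_history: dict[str, list[float]] = {f: [] for f in names}
    shadow_max_history: list[float] = []

    for it in range(max_iter):
        active = [f for f in names if status[f] != "rejected"]
        if all(status[f] == "confirmed" for f in active):
            break
        Xa = X[active].to_numpy(dtype=float)
        shadow = Xa.copy()
        for col in range(shadow.shape[1]):
            rng.shuffle(shadow[:, col])
        Xfull = np.hstack([Xa, shadow])
        est_cls = RandomForestClassifier if classification else RandomForestRegressor
        est = est_cls(n_estimators=n_estimators, random_state=int(rng.integers(2**31)),
                      max_features="sqrt", n_jobs=1)
        est.fit(Xfull, y)
        imp = est.feature_importances_
        real_imp = imp[: len(active)]
        shadow_max = float(imp[len(active):].max())
        shadow_max_history.append(shadow_max)
        trials += 1
        for f, v in zip(active, real_imp):
            imp_history[f].append(float(v))
            if v > shadow_max:
                hits[f] += 1
        if trials >= 5:
            # Bonferroni across active features: the binomial test is looked
            # at every iteration, so unadjusted alpha would not control the
            # null confirmation rate
            thr = alpha / max(len(active), 1)
            for f in active:
                if status[f] != "tentative":
                    continue
                res_hi = sps.binomtest(hits[f], trials, 0.5, alternative="greater")
                res_lo = sps.binomtest(hits[f], trials, 0.5, alternative="less")
                if res_hi.pvalue < thr:
                    status[f] = "confirmed"
                elif res_lo.pvalue < thr:
                    status[f] = "rejected"

    med_shadow = float(np.median(shadow_max_history)) if shadow_max_history else np.inf
    for f in names:
        if status[f] == "tentative" and imp_history[f]:
            if float(np.median(imp_history[f])) > med_shadow:
                status[f] = "confirmed"
    return [f for f in names if status[f] == "confirmed"]


# --- ICI model ---------------------------------------------------------------

@dataclass
class ICIModel:
    """Frozen PC1 scorer: gene lists, training means, sign-fixed loadings."""

    genes_A: list[str]
    genes_B: list[str]
    center_A: np.ndarray
    center_B: np.ndarray
    loading_A: np.ndarray
    loading_B: np.ndarray
    train_score_mean: float = 0.0
    train_score_sd: float = 1.0
    explained_var_A: float = float("nan")
    explained_var_B: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("loading_A", "loading_B"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
                raise ValueError(f"{name} must have unit L2 norm")
            setattr(self, name, v)
        self.center_A = np.asarray(self.center_A, dtype=float)
        self.center_B = np.asarray(self.center_B, dtype=float)
        overlap = set(self.genes_A) & set(self.genes_B)
        # identical sets are tolerated (the score is then identically 0);
        # a partial overlap is always a construction mistake
        if overlap and set(self.genes_A) != set(self.genes_B):
            raise ValueError("genes_A and genes_B overlap partially")

    def to_json(self, path=None) -> str:
        payload = {
            "genes_A": self.genes_A, "genes_B": self.genes_B,
            "center_A": self.center_A.tolist(), "center_B": self.center_B.tolist(),
            "loading_A": self.loading_A.tolist(), "loading_B": self.loading_B.tolist(),
            "train_score_mean": self.train_score_mean,
            "train_score_sd": self.train_score_sd,
            "explained_var_A": self.explained_var_A,
            "explained_var_B": self.explained_var_B,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ICIModel":
        if isinstance(source, dict):
            payload = source
        elif isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            payload["genes_A"], payload["genes_B"],
            np.array(payload["center_A"]), np.array(payload["center_B"]),
            np.array(payload["loading_A"]), np.array(payload["loading_B"]),
            payload.get("train_score_mean", 0.0), payload.get("train_score_sd", 1.0),
            payload.get("explained_var_A", float("nan")),
            payload.get("explained_var_B", float("nan")),
        )


def _fit_pc1(expr: ExpressionMatrix, genes: list[str], label: str):
    present = [g for g in genes if g in set(expr.gene_ids)]
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if len(present) < 2:
        raise ValueError(f"gene set {label} has < 2 genes in the cohort; missing: {missing}")
    sub = expr.subset_genes(present)
    X = sub.values.T                            # samples x genes
    center = X.mean(axis=0)
    Xc = X - center
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    score = Xc @ loading
    # sign fix: the score rises with the set's per-sample mean expression
    mean_profile = X.mean(axis=1)
    if np.std(score) > 0 and np.std(mean_profile) > 0:
        if np.corrcoef(score, mean_profile)[0, 1] < 0:
            loading = -loading
            score = -score
    explained = float(s[0] ** 2 / (s**2).sum()) if s.size else float("nan")
    return present, center, loading, score, explained


def fit_ici_model(expr: ExpressionMatrix, genes_A, genes_B) -> ICIModel:
    """Fit the two PC1 scorers on a training cohort (>= 3 samples)."""
    if len(expr.sample_ids) < 3:
        raise ValueError("fitting needs >= 3 samples")
    gA, cA, lA, sA, evA = _fit_pc1(expr, list(genes_A), "A")
    gB, cB, lB, sB, evB = _fit_pc1(expr, list(genes_B), "B")
    score = sA - sB
    return ICIModel(gA, gB, cA, cB, lA, lB,
                    float(score.mean()), float(score.std()) or 1.0, evA, evB)


def _project(model_genes: list[str], center: np.ndarray, loading: np.ndarray,
             expr: ExpressionMatrix, label: str) -> np.ndarray:
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    present_mask = np.array([g in pos for g in model_genes])
    coverage = present_mask.mean() if len(model_genes) else 0.0
    if coverage == 0:
        raise ValueError(f"no gene of set {label} present in the cohort")
    if coverage < 0.8:
        raise ValueError(
            f"cohort covers only {coverage:.0%} of gene set {label}; >= 80% required"
        )
    if coverage < 1.0:
        logger.warning("score_samples: %d gene(s) of set %s imputed at training mean",
                       int((~present_mask).sum()), label)
    n = len(expr.sample_ids)
    X = np.tile(center, (n, 1))                 # missing genes -> training mean
    for i, g in enumerate(model_genes):
        if present_mask[i]:
            X[:, i] = expr.values[pos[g]]
    return (X - center) @ loading


def score_samples(model: ICIModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Score a cohort with a frozen model: ici_score = score_A - score_B."""
    score_A = _project(model.genes_A, model.center_A, model.loading_A, expr, "A")
    score_B = _project(model.genes_B, model.center_B, model.loading_B, expr, "B")
    return pd.DataFrame(
        {"score_A": score_A, "score_B": score_B, "ici_score": score_A - score_B},
        index=expr.sample_ids,
    )


# --- checkpoint / activation panel contrasts ---------------------------------

def compare_gene_panels(expr: ExpressionMatrix, high_mask, panel) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene Wilcoxon rank-sum between high/low score groups over a panel.

    Returns the test table (BH-adjusted across the present panel genes) and
    the list of panel genes absent from the cohort.
    """
    high = np.asarray(high_mask).astype(bool)
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    present = [g for g in panel if g in pos]
    skipped = [g for g in panel if g not in pos]
    if not present:
        raise ValueError("no panel gene present in the cohort")
    rows = []
    for g in present:
        x = expr.values[pos[g], high]
        y = expr.values[pos[g], ~high]
        if np.std(np.concatenate([x, y])) == 0:
            stat, p = np.nan, 1.0
        else:
            stat, p = wilcoxon_rank_sum(x, y)
        rows.append((g, float(np.median(x) - np.median(y)), stat, p))
    table = pd.DataFrame(rows, columns=["gene", "median_diff", "statistic", "p_value"]).set_index("gene")
    table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
    table["direction"] = np.where(table["median_diff"] > 0, "up_in_high", "up_in_low")
    table.loc[table["adjusted_p"] >= 0.05, "direction"] = "ns"
    return table, skipped
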