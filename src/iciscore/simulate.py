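"""Synthetic tumor cohorts with a known immune ground truth.

A latent per-sample immune activity score, organised into discrete immune
phenotypes (hot / intermediate / cold by default), drives every observable
the pipeline consumes:

* immune-cell fractions — Dirichlet draws with phenotype-specific
  concentration vectors over the 22 reference cell types;
* expression — marker genes mix the signature basis linearly with the true
  fractions (then log2(1+x) + Gaussian noise); signal-gene set A rises with
  the latent score, set B falls with it; the remaining genes are noise;
* immunophenoscore (IPS) — a noisy monotone map of the latent score onto a
  0–10 scale;
* survival — exponential proportional hazards in the standardized latent
  score, with uniform censoring calibrated to a target censoring rate;
* mutation burden — per-phenotype Poisson counts scattered over a driver
  gene pool into MAF records;
* immunotherapy response — logistic in the latent score, reported on the
  4-level CR/PR/SD/PD scale.

Because the truth (fractions, phenotype, latent score) is returned next to
the observables, every downstream stage can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ACTIVATION_GENES, CELL_TYPES, CHECKPOINT_GENES, load_synthetic_signature
from .io import ClinicalTable, ExpressionMatrix, MAFTable

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort", "simulate_validation_cohort"]

_PANEL_GENES = CHECKPOINT_GENES + ACTIVATION_GENES

# phenotype-enriched cell-type blocks (indices into CELL_TYPES):
# hot: CD8 T, CD4 memory activated, Tfh, NK activated, M1
# intermediate: B naive, plasma, CD4 naive, NK resting, monocytes
# cold: CD4 memory resting, M0, M2, DC activated, mast resting
_PHENOTYPE_BLOCKS = [
    [3, 6, 7, 11, 14],
    [0, 2, 4, 10, 12],
    [5, 13, 15, 17, 18],
]


def _default_concentrations(n_phenotypes: int) -> np.ndarray:
    if n_phenotypes > len(_PHENOTYPE_BLOCKS):
        raise ValueError(
            f"n_phenotypes={n_phenotypes} exceeds the {len(_PHENOTYPE_BLOCKS)} built-in "
            "concentration vectors; supply fraction_dirichlet_concentration explicitly"
        )
    conc = np.ones((n_phenotypes, len(CELL_TYPES)))
    for k in range(n_phenotypes):
        conc[k, _PHENOTYPE_BLOCKS[k]] += 8.0
    return conc


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults define the study conditions."""

    n_samples: int = 300
    n_phenotypes: int = 3
    n_genes: int = 2000
    n_signal_genes_A: int = 200
    n_signal_genes_B: int = 200
    #: per-phenotype Dirichlet concentration over the 22 cell types
    fraction_dirichlet_concentration: np.ndarray | None = None
    expression_noise_sd: float = 0.5
    #: planted log2 effect of one unit of standardized latent score
    signal_effect_size: float = 1.0
    #: log-hazard per unit standardized latent score (negative: hot = protective)
    hazard_coefficient: float = -0.8
    baseline_median_survival_days: float = 1800.0
    censoring_rate: float = 0.9
    #: per-phenotype mean nonsilent mutation count (hot > cold, as observed)
    tmb_poisson_means: tuple[float, ...] | None = None
    responder_logit_coefficient: float = 1.5
    responder_logit_intercept: float = -0.5
    #: latent-score phenotype means span [+1, ..., -1]; within-phenotype sd
    latent_within_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_phenotypes", "n_genes", "n_signal_genes_A", "n_signal_genes_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.fraction_dirichlet_concentration is None:
            self.fraction_dirichlet_concentration = _default_concentrations(self.n_phenotypes)
        else:
            conc = np.asarray(self.fraction_dirichlet_concentration, dtype=float)
            if conc.shape != (self.n_phenotypes, len(CELL_TYPES)):
                raise ValueError(
                    f"fraction_dirichlet_concentration must be {self.n_phenotypes} x "
                    f"{len(CELL_TYPES)} (one vector per phenotype)"
                )
            if (conc <= 0).any():
                raise ValueError("Dirichlet concentrations must be > 0")
            self.fraction_dirichlet_concentration = conc
        if self.tmb_poisson_means is None:
            # hot-to-cold gradient; /38 Mb puts the means on the 0.1-0.5 TMB scale
            self.tmb_poisson_means = tuple(
                np.linspace(16.0, 6.0, self.n_phenotypes).tolist()
            )
        elif len(self.tmb_poisson_means) != self.n_phenotypes:
            raise ValueError("tmb_poisson_means needs one mean per phenotype")
        minimal = 110 + self.n_signal_genes_A + self.n_signal_genes_B
        if self.n_genes < minimal:
            raise ValueError(f"n_genes must be >= {minimal} (markers + signal genes)")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its generating truth."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    maf: MAFTable
    true_fractions: pd.DataFrame
    true_phenotype: np.ndarray
    true_latent_score: np.ndarray
    response: pd.Series | None = None

    def __post_init__(self) -> None:
        ids = self.expression.sample_ids
        assert list(self.true_fractions.index) == ids
        assert list(self.clinical.table.index) == ids
        sums = self.true_fractions.to_numpy().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def responder(self) -> pd.Series | None:
        """Binary objective response: CR/PR = responder, SD/PD = non-responder."""
        if self.response is None:
            return None
        return self.response.isin(["CR", "PR"]).astype(int)


def _gene_universe(config: SimulationConfig, marker_names: list[str]) -> tuple[list[str], list[str], list[str]]:
    nA, nB = config.n_signal_genes_A, config.n_signal_genes_B
    genes_A = list(_PANEL_GENES[:nA]) + [f"SIGA_{i:03d}" for i in range(len(_PANEL_GENES), nA)]
    genes_B = [f"SIGB_{i:03d}" for i in range(nB)]
    n_noise = config.n_genes - len(marker_names) - nA - nB
    noise = [f"GENE_{i:04d}" for i in range(n_noise)]
    return genes_A, genes_B, noise


def _calibrate_censoring(hazards: np.ndarray, target_event_rate: float) -> float:
    """Upper bound of the uniform censoring window hitting the target event rate."""

    def event_rate(c_max: float) -> float:
        lam_c = hazards * c_max
        return float(np.mean(1.0 - (1.0 - np.exp(-lam_c)) / lam_c))

    lo, hi = 1e-6, 1e9
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if event_rate(mid) < target_event_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort (expression, clinical, MAF, response) plus truth.

    Deterministic given ``config.seed``; no global random state is touched.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # latent immune phenotype and continuous activity score
    phenotype = rng.integers(0, config.n_phenotypes, size=n)
    if config.n_phenotypes > 1:
        pheno_means = np.linspace(1.0, -1.0, config.n_phenotypes)
    else:
        pheno_means = np.zeros(1)
    latent = pheno_means[phenotype] + rng.normal(0.0, config.latent_within_sd, size=n)
    z = (latent - latent.mean()) / latent.std()

    # cell fractions
    conc = config.fraction_dirichlet_concentration
    fractions = np.empty((n, len(CELL_TYPES)))
    for k in range(config.n_phenotypes):
        mask = phenotype == k
        fractions[mask] = rng.dirichlet(conc[k], size=int(mask.sum()))
    frac_df = pd.DataFrame(fractions, index=sample_ids, columns=CELL_TYPES)

    # expression: markers mix the basis linearly; signal genes follow the score
    sig = load_synthetic_signature()
    marker_linear = sig.basis @ fractions.T  # markers x samples
    marker_expr = np.log2(1.0 + marker_linear)

    genes_A, genes_B, noise_genes = _gene_universe(config, sig.marker_gene_ids)
    base_A = rng.uniform(4.0, 8.0, size=len(genes_A))
    base_B = rng.uniform(4.0, 8.0, size=len(genes_B))
    base_N = rng.uniform(2.0, 9.0, size=len(noise_genes))
    eff = config.signal_effect_size
    expr_A = base_A[:, None] + eff * z[None, :]
    expr_B = base_B[:, None] - eff * z[None, :]
    expr_N = np.broadcast_to(base_N[:, None], (len(noise_genes), n)).copy()

    values = np.vstack([marker_expr, expr_A, expr_B, expr_N])
    if config.expression_noise_sd > 0:
        values = values + rng.normal(0.0, config.expression_noise_sd, size=values.shape)
    gene_ids = list(sig.marker_gene_ids) + genes_A + genes_B + noise_genes
    expression = ExpressionMatrix(gene_ids, sample_ids, values)

    # immunophenoscore on a 0-10 scale, monotone in the latent score
    ips = np.clip(5.5 + 1.5 * z + rng.normal(0.0, 0.8, size=n), 0.0, 10.0)

    # survival: exponential PH in z, uniform censoring at the target rate
    h0 = np.log(2.0) / config.baseline_median_survival_days
    hazards = h0 * np.exp(config.hazard_coefficient * z)
    event_times = rng.exponential(1.0 / hazards)
    target_event_rate = 1.0 - config.censoring_rate
    c_max = _calibrate_censoring(hazards, target_event_rate)
    censor_times = rng.uniform(0.0, c_max, size=n)
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)

    # clinical covariates (uninformative decoration apart from ips/survival)
    clin = pd.DataFrame(
        {
            "os_time": np.round(os_time, 1),
            "os_event": os_event,
            "age": rng.integers(25, 81, size=n),
            "gender": rng.choice(["Female", "Male"], size=n, p=[0.7, 0.3]),
            "stage": rng.choice(
                ["Stage_I", "Stage_II", "Stage_III", "Stage_IV"], size=n,
                p=[0.56, 0.10, 0.22, 0.12],
            ),
            "rt": rng.choice(["YES", "NO", "UN"], size=n, p=[0.6, 0.36, 0.04]),
            "tmt": rng.choice(["YES", "NO", "UN"], size=n, p=[0.02, 0.18, 0.8]),
            "ips": np.round(ips, 3),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    clinical = ClinicalTable(clin)

    maf = _simulate_maf(rng, sample_ids, phenotype, config)

    # immunotherapy response, logistic in z
    p_resp = 1.0 / (1.0 + np.exp(-(config.responder_logit_intercept
                                   + config.responder_logit_coefficient * z)))
    responder = rng.random(n) < p_resp
    labels = np.where(
        responder,
        np.where(rng.random(n) < 0.3, "CR", "PR"),
        np.where(rng.random(n) < 0.4, "SD", "PD"),
    )
    response = pd.Series(labels, index=sample_ids, name="response")

    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        maf=maf,
        true_fractions=frac_df,
        true_phenotype=phenotype,
        true_latent_score=z,
        response=response,
    )


_DRIVER_POOL = [f"MUT_{i:03d}" for i in range(50)]
_VARIANT_CLASSES = np.array(
    ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins",
     "Splice_Site", "In_Frame_Del", "Silent"]
)
_VARIANT_PROBS = np.array([0.60, 0.08, 0.06, 0.04, 0.05, 0.02, 0.15])


def _simulate_maf(rng: np.random.Generator, sample_ids: Sequence[str],
                  phenotype: np.ndarray, config: SimulationConfig) -> MAFTable:
    means = np.asarray(config.tmb_poisson_means)
    # Zipf-like driver-gene weights; the first five drivers are enriched in
    # the hottest phenotype so group frequency contrasts carry signal
    base_w = 1.0 / np.arange(1, len(_DRIVER_POOL) + 1)
    rows = []
    for i, sid in enumerate(sample_ids):
        n_var = rng.poisson(means[phenotype[i]])
        if n_var == 0:
            continue
        w = base_w.copy()
        if phenotype[i] == 0:
            w[:5] *= 3.0
        w /= w.sum()
        genes = rng.choice(_DRIVER_POOL, size=n_var, p=w)
        classes = rng.choice(_VARIANT_CLASSES, size=n_var, p=_VARIANT_PROBS)
        chroms = rng.integers(1, 23, size=n_var).astype(str)
        pos = rng.integers(1, 10_000_000, size=n_var)
        for g, c, ch, p in zip(genes, classes, chroms, pos):
            rows.append((g, sid, c, ch, int(p)))
    df = pd.DataFrame(
        rows,
        columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
                 "Chromosome", "Start_Position"],
    )
    if df.empty:
        df = pd.DataFrame(columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                                   "Variant_Classification", "Chromosome", "Start_Position"])
    return MAFTable(df.astype({"Hugo_Symbol": str, "Tumor_Sample_Barcode": str}))


def simulate_validation_cohort(config: SimulationConfig, truth_model) -> SyntheticCohort:
    """A fresh cohort for external validation of a frozen ICI model.

    The model's gene lists must be contained in the simulated gene universe;
    response labels are coupled to the cohort's own latent score, so a model
    that recovers the latent axis predicts response.
    """
    sig = load_synthetic_signature()
    genes_A, genes_B, noise_genes = _gene_universe(config, sig.marker_gene_ids)
    universe = set(sig.marker_gene_ids) | set(genes_A) | set(genes_B) | set(noise_genes)
    missing = [g for g in list(truth_model.genes_A) + list(truth_model.genes_B)
               if g not in universe]
    if missing:
        raise ValueError(f"model genes absent from simulated universe: {missing}")
    return simulate_cohort(config)
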