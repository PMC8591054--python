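"""Survival machinery and the shared statistical tests.

Kaplan–Meier and the log-rank test are implemented directly (the cutpoint
search needs the standardized two-group statistic, which wrapper libraries
do not expose); `lifelines` serves as an independent cross-check in the
test suite.  The "optimal cutpoint" is the maximally selected rank
statistic: the observed score value whose induced two-group split maximizes
the absolute standardized log-rank statistic, subject to a minimum group
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KMEstimate",
    "LogrankResult",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "logrank_z",
    "optimal_cutpoint",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "spearman",
    "chi_square_table",
    "bh_adjust",
]


@dataclass
class KMEstimate:
    """Product-limit estimate: right-continuous step function."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    median: float | None       # earliest t with S(t) <= 0.5; None if not reached
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogrankResult:
    statistic: float     # chi-square
    p_value: float
    df: int


@dataclass
class CutpointResult:
    threshold: float               # an observed score value; high = score > threshold
    standardized_statistic: float  # signed log-rank z at the threshold
    n_high: int
    n_low: int
    minprop: float


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no survival records")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMEstimate:
    """Kaplan–Meier product-limit estimator with median survival."""
    t, e = _as_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv = []
    s = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
    surv_arr = np.array(surv)
    median = None
    reached = np.nonzero(surv_arr <= 0.5)[0]
    if reached.size:
        median = float(event_times[reached[0]])
    return KMEstimate(event_times, surv_arr, median, n=t.size, n_events=int(e.sum()))


def _logrank_tables(t: np.ndarray, e: np.ndarray, g: np.ndarray, n_groups: int):
    """Observed/expected event counts and covariance over distinct event times."""
    event_times = np.unique(t[e == 1])
    O = np.zeros(n_groups)
    E = np.zeros(n_groups)
    V = np.zeros((n_groups, n_groups))
    for et in event_times:
        at_risk = t >= et
        N = int(at_risk.sum())
        d = int(((t == et) & (e == 1)).sum())
        Ng = np.array([(at_risk & (g == k)).sum() for k in range(n_groups)], dtype=float)
        dg = np.array([((t == et) & (e == 1) & (g == k)).sum() for k in range(n_groups)], dtype=float)
        O += dg
        E += d * Ng / N
        if N > 1:
            c = d * (N - d) / (N - 1)
            p = Ng / N
            V += c * (np.diag(p) - np.outer(p, p))
    return O, E, V


def logrank_z(times, events, high: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O-E)/sqrt(V) for the high group."""
    t, e = _as_arrays(times, events)
    g = np.asarray(high, dtype=int)
    O, E, V = _logrank_tables(t, e, g, 2)
    v = V[1, 1]
    if v <= 0:
        return 0.0
    return float((O[1] - E[1]) / np.sqrt(v))


def logrank_test(times, events, groups) -> LogrankResult:
    """Multi-group log-rank test; chi-square with (groups-1) df."""
    t, e = _as_arrays(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    g = np.searchsorted(labels, groups)
    O, E, V = _logrank_tables(t, e, g, labels.size)
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    if np.allclose(Vsub, 0.0):
        stat = 0.0
    else:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
        stat = max(stat, 0.0)
    df = labels.size - 1
    p = float(sps.chi2.sf(stat, df))
    return LogrankResult(stat, p, df)


def optimal_cutpoint(score, times, events, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected rank statistic over admissible dichotomizations.

    Candidates are the observed score values; a sample is "high" when its
    score is strictly greater than the threshold (ties go low).  A candidate
    is admissible when both sides hold at least ``minprop`` of the cohort.
    Among admissible candidates, the one maximizing |z| wins (smallest
    threshold on exact ties).
    """
    s = np.asarray(score, dtype=float)
    t, e = _as_arrays(times, events)
    if s.size != t.size:
        raise ValueError("score and survival records differ in length")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct score values")
    n = s.size
    min_count = minprop * n
    best = None
    for thr in uniq[:-1]:  # splitting at the max leaves the high side empty
        high = s > thr
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_high, n_low) < min_count:
            continue
        z = logrank_z(t, e, high.astype(int))
        if best is None or abs(z) > abs(best[1]) + 1e-12:
            best = (float(thr), z, n_high, n_low)
    if best is None:
        raise ValueError(f"no candidate threshold satisfies minprop={minprop}")
    thr, z, n_high, n_low = best
    return CutpointResult(thr, z, n_high, n_low, minprop)


# --- shared rank/contingency tests -------------------------------------------

def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney/Wilcoxon rank-sum; exact enumeration for combined n <= 10
    without ties, midrank normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    exact = (pooled.size <= 10) and (np.unique(pooled).size == pooled.size)
    res = sps.mannwhitneyu(x, y, alternative=alternative,
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


def spearman(x, y) -> tuple[float, float]:
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def chi_square_table(table) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("contingency table must be non-negative")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
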