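"""Consensus clustering for subtype discovery.

Repeatedly subsamples the cohort, partitions each subsample with PAM
(k-medoids, BUILD + SWAP on Euclidean distances; Ward hierarchical
clustering available as the alternative base learner), and accumulates how
often each sample pair lands in the same cluster.  The per-k consensus
matrix, its empirical CDF, and the PAC statistic (proportion of ambiguous
consensus entries) drive the choice of k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = ["ConsensusResult", "pam_cluster", "consensus_cluster", "select_k"]


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus_matrices: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]          # 1-based cluster labels per k
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # (sorted values, ECDF)
    pac: dict[int, float]
    chosen_k: int | None = None
    n_zero_cooccurrence: int = 0


def pam_cluster(dist_matrix: np.ndarray, k: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a precomputed distance matrix.

    BUILD greedily seeds the medoids, SWAP exchanges a medoid for a
    non-medoid while any exchange lowers the total within-cluster distance.
    Deterministic: exact ties resolve to the smallest index, so the seed
    never changes the result on non-degenerate data.

    Returns (labels in 0..k-1, medoid indices).
    """
    D = np.asarray(dist_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not (2 <= k <= n):
        raise ValueError(f"k={k} out of range for n={n}")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dn = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dn[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        m = int(np.argmax(gains))
        medoids.append(m)
        dn = np.minimum(dn, D[:, m])

    medoid_arr = np.array(sorted(medoids))
    # SWAP
    for _ in range(200):
        dm = D[:, medoid_arr]                       # n x k
        order = np.argsort(dm, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = dm[np.arange(n), nearest]
        d2 = dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            is_mine = nearest == mi
            # cost change of swapping medoid mi for candidate h, all h at once
            gain_other = np.minimum(D[~is_mine] - d1[~is_mine, None], 0.0).sum(axis=0)
            gain_mine = (np.minimum(D[is_mine], d2[is_mine, None]) - d1[is_mine, None]).sum(axis=0)
            delta = gain_other + gain_mine          # negative = improvement
            delta[medoid_arr] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoid_arr[mi] = h
        medoid_arr = np.sort(medoid_arr)
    labels = np.argmin(D[:, medoid_arr], axis=1)
    return labels, medoid_arr


def _partition_subsample(data: np.ndarray, D: np.ndarray, idx: np.ndarray,
                         k: int, base: str) -> np.ndarray:
    if base == "pam":
        labels, _ = pam_cluster(D[np.ix_(idx, idx)], k)
        return labels
    if base == "ward":
        Z = linkage(data[idx], method="ward")
        return fcluster(Z, t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown base learner {base!r}")


def consensus_cluster(
    data_matrix,
    k_range,
    n_resample: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    standardize: bool = True,
    base: str = "pam",
) -> ConsensusResult:
    """Resampled consensus clustering over a samples x features matrix.

    For each k, ``n_resample`` subsamples of ceil(frac*n) samples are
    partitioned; consensus(i,j) = co-cluster count / co-sampled count.
    Final per-k labels come from an average-linkage cut of 1 - consensus.
    """
    X = np.asarray(data_matrix, dtype=float)
    n = X.shape[0]
    k_range = sorted(int(k) for k in k_range)
    if any(k < 2 for k in k_range):
        raise ValueError("all k must be >= 2")
    m = int(np.ceil(subsample_frac * n))
    if m < max(k_range):
        raise ValueError(f"subsample size {m} smaller than max k {max(k_range)}")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    D = squareform(pdist(X, metric="euclidean"))

    rng = np.random.default_rng(seed)
    matrices, labels_out, cdf_out, pac_out = {}, {}, {}, {}
    n_zero = 0
    iu = np.triu_indices(n, k=1)
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(n_resample):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            lab = _partition_subsample(X, D, idx, k, base)
            same = (lab[:, None] == lab[None, :]).astype(float)
            co_cluster[np.ix_(idx, idx)] += same
            co_sampled[np.ix_(idx, idx)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
        n_zero += int((co_sampled[iu] == 0).sum())
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        matrices[k] = cons

        Z = linkage(squareform(1.0 - cons, checks=False), method="average")
        labels_out[k] = fcluster(Z, t=k, criterion="maxclust")

        vals = np.sort(cons[iu])
        ecdf = np.arange(1, vals.size + 1) / vals.size
        cdf_out[k] = (vals, ecdf)
        pac_out[k] = float(np.mean((vals > 0.1) & (vals < 0.9)))

    result = ConsensusResult(k_range, matrices, labels_out, cdf_out, pac_out,
                             n_zero_cooccurrence=n_zero)
    result.chosen_k = select_k(result, "pac")
    return result


def _cdf_area(vals: np.ndarray, ecdf: np.ndarray) -> float:
    xs = np.concatenate([[0.0], vals, [1.0]])
    ys = np.concatenate([[0.0], ecdf, [1.0]])
    return float(np.sum(np.diff(xs) * ys[:-1]))


def select_k(result: ConsensusResult, method: str = "pac", override: int | None = None) -> int:
    """Choose k: 'pac' = argmin PAC (ties to the smaller k); 'delta_area' =
    smallest k whose relative CDF-area increase drops below 0.1."""
    if override is not None:
        if override not in result.k_range:
            raise ValueError(f"override k={override} not in k_range")
        return int(override)
    if not result.k_range:
        raise ValueError("empty consensus result")
    if method == "pac":
        return min(result.k_range, key=lambda k: (result.pac[k], k))
    if method == "delta_area":
        areas = {k: _cdf_area(*result.cdf[k]) for k in result.k_range}
        ks = result.k_range
        for prev, k in zip(ks[:-1], ks[1:]):
            rel = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
            if rel < 0.1:
                return k
        return ks[-1]
    raise ValueError(f"unknown method {method!r}")
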