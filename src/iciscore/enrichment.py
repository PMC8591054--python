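"""Gene-set enrichment: preranked GSEA and hypergeometric ORA.

`preranked_gsea` computes the classic weighted Kolmogorov–Smirnov-like
running-sum enrichment score over a ranked gene list, with a gene-label
permutation null for nominal p, sign-matched normalization for NES, and the
standard pooled positive/negative FDR.  `ora_hypergeometric` is upper-tail
over-representation of a query list against gene sets within a universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSetCollection
from .survival import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["GSEAResult", "enrichment_score", "preranked_gsea", "ora_hypergeometric"]


@dataclass
class GSEAResult:
    table: pd.DataFrame                # es, nes, nominal_p, fdr_q, size per set
    leading_edge: dict[str, list[str]]
    n_perm: int
    skipped_sets: list[str]


def enrichment_score(ranked_genes: list[str], scores: np.ndarray,
                     gene_set, weight: float = 1.0) -> tuple[float, list[str]]:
    """Signed maximum deviation of the weighted running sum, plus leading edge.

    ``ranked_genes`` must be ordered by decreasing score.  Hits increment by
    |score|^weight (normalized); misses decrement by 1/(N - Nh).
    """
    members = set(gene_set)
    hits = np.array([g in members for g in ranked_genes])
    nh = int(hits.sum())
    N = len(ranked_genes)
    if nh == 0 or nh == N:
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(np.asarray(scores, dtype=float)) ** weight
    w_hit = np.where(hits, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:
        w_hit = hits.astype(float)
        denom = float(nh)
    running = np.cumsum(w_hit / denom - (~hits) / (N - nh))
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for g, h in zip(ranked_genes[: i_max + 1], hits[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked_genes[i_max:], hits[i_max:]) if h]
    return es, leading


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 5,
    seed: int = 0,
) -> GSEAResult:
    """Preranked GSEA over a gene -> score ranking (duplicates forbidden).

    The null permutes gene labels: set membership is redrawn uniformly at
    the observed set size, ``n_perm`` times per set.  NES divides ES by the
    mean |null ES| of matching sign; nominal p carries the +1 correction.
    FDR q follows the pooled positive/negative procedure.
    """
    ranking = pd.Series(ranking).astype(float)
    if ranking.index.has_duplicates:
        raise ValueError("ranking has duplicate genes")
    ranking = ranking.sort_values(ascending=False, kind="stable")
    genes = list(ranking.index)
    scores = ranking.to_numpy()
    rng = np.random.default_rng(seed)

    rows, skipped, leading_edges = [], [], {}
    null_store: dict[str, np.ndarray] = {}
    for name, members in gene_sets.items():
        overlap = [g for g in members if g in set(genes)]
        if len(overlap) < min_size:
            skipped.append(name)
            logger.info("preranked_gsea: skipping %s (overlap %d < %d)",
                        name, len(overlap), min_size)
            continue
        es, leading = enrichment_score(genes, scores, overlap, weight)
        size = len(overlap)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_idx = rng.choice(len(genes), size=size, replace=False)
            perm_set = [genes[i] for i in perm_idx]
            null_es[b], _ = enrichment_score(genes, scores, perm_set, weight)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = max(int(same_sign.sum()), 1)
        nominal_p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (n_same + 1)
        mean_same = float(np.mean(np.abs(null_es[same_sign]))) if same_sign.any() else np.nan
        nes = es / mean_same if mean_same and mean_same > 0 else np.nan
        null_nes = np.where(
            null_es >= 0,
            null_es / (np.mean(np.abs(null_es[null_es >= 0])) if (null_es >= 0).any() else np.nan),
            null_es / (np.mean(np.abs(null_es[null_es < 0])) if (null_es < 0).any() else np.nan),
        )
        null_store[name] = null_nes
        leading_edges[name] = leading
        rows.append((name, size, es, nes, nominal_p))

    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "nominal_p"]).set_index("set")

    # pooled FDR: compare each observed NES to the pooled null NES of its sign
    if len(table):
        all_null = np.concatenate(list(null_store.values()))
        all_null = all_null[np.isfinite(all_null)]
        obs = table["nes"].to_numpy()
        fdr = np.ones(len(table))
        for i, nes in enumerate(obs):
            if not np.isfinite(nes):
                continue
            if nes >= 0:
                null_frac = np.mean(all_null[all_null >= 0] >= nes) if (all_null >= 0).any() else 1.0
                obs_frac = np.mean(obs[np.isfinite(obs) & (obs >= 0)] >= nes)
            else:
                null_frac = np.mean(all_null[all_null < 0] <= nes) if (all_null < 0).any() else 1.0
                obs_frac = np.mean(obs[np.isfinite(obs) & (obs < 0)] <= nes)
            fdr[i] = min(1.0, null_frac / max(obs_frac, 1e-12))
        table["fdr_q"] = fdr
    else:
        table["fdr_q"] = []
    return GSEAResult(table, leading_edges, n_perm, skipped)


def ora_hypergeometric(
    query_genes,
    universe_genes,
    gene_sets: GeneSetCollection,
    top_k_report: int = 10,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query gene list.

    Sets are intersected with the universe first; p = P(X >= overlap) for X
    hypergeometric(N=universe, K=set size, n=query size).  BH adjustment
    runs across all tested sets; when set names carry a ``NAMESPACE:`` tag
    the top ``top_k_report`` per namespace are flagged in ``top_hit``.
    """
    universe = list(dict.fromkeys(universe_genes))
    uni = set(universe)
    query = list(dict.fromkeys(query_genes))
    if not query:
        raise ValueError("empty query gene list")
    stray = [g for g in query if g not in uni]
    if stray:
        raise ValueError(f"query genes outside the universe: {stray[:5]}...")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        K = len(uni & set(members))
        if K == 0:
            continue
        k = len(set(query) & set(members) & uni)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        expected = n * K / N
        fold = (k / expected) if expected > 0 else np.nan
        rows.append((name, k, K, p, fold))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                        "p_value", "fold_enrichment"]).set_index("set")
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
        namespaces = [s.split(":", 1)[0] if ":" in s else "" for s in table.index]
        table["namespace"] = namespaces
        table["top_hit"] = False
        for ns in set(namespaces):
            sub = table[table["namespace"] == ns].nsmallest(top_k_report, "p_value")
            table.loc[sub.index, "top_hit"] = True
    return table
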