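"""Ordered-query over-representation analysis with BH-FDR correction.

The query is a *ranked* target-gene list (decreasing best zzscore).  For
each gene set, every prefix of the ranked query is tested with the exact
hypergeometric tail against the universe, and the minimum p over prefixes
is reported together with the smallest prefix achieving it — the
incremental-query semantics popularized by g:Profiler's ``gost``.  The
minimum is taken without an internal multiplicity correction across
prefixes; correction is applied *across sets* with Benjamini-Hochberg,
since FDR was the chosen correction method.

The default universe is the full gene complement of the pocket annotation
table (every gene reachable when all pockets are considered), which is the
appropriate background for a pocketome-wide screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, PocketfishError


@dataclass(frozen=True)
class EnrichmentResult:
    """Term-level ORA statistics at the best query prefix."""

    set_id: str
    name: str
    p_value: float
    adjusted_p: float
    best_prefix_size: int
    overlap_at_best: int
    set_size: int
    universe_size: int


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n):
    draw n from a universe of N containing K marked items."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise PocketfishError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ordered_enrichment(
    ranked_query: Sequence[str],
    gene_set: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> tuple[float, int, int]:
    """Best hypergeometric tail over all prefixes of the ranked query.

    Returns ``(min p, smallest prefix length achieving it, overlap at that
    prefix)``.  The gene set is intersected with the universe before
    testing; the query must lie within the universe.
    """
    universe = {g.upper() for g in universe}
    query = [g.upper() for g in ranked_query]
    if not query or not universe:
        raise PocketfishError("empty query or universe")
    outside = [g for g in query if g not in universe]
    if outside:
        raise PocketfishError(f"query genes outside universe: {outside[:5]}")
    if len(set(query)) != len(query):
        raise PocketfishError("ranked query contains duplicate genes")
    members = {g.upper() for g in gene_set} & universe
    N, K = len(universe), len(members)
    best_p, best_len, best_k = 1.0, len(query), 0
    overlap = 0
    for ell, gene in enumerate(query, start=1):
        if gene in members:
            overlap += 1
        p = hypergeom_tail(overlap, K, ell, N) if K else 1.0
        if p < best_p:
            best_p, best_len, best_k = p, ell, overlap
    return best_p, best_len, best_k


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise PocketfishError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def run_ora(
    ranked_genes: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str] | frozenset[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Ordered ORA of a ranked gene list against every set in a collection.

    All sets are tested and BH-adjusted jointly; only those with
    ``adjusted_p <= alpha`` are returned, sorted by adjusted p then set_id.
    """
    uni = {str(g).upper() for g in universe}
    if not ranked_genes or not collection.sets or not uni:
        raise PocketfishError("empty query, collection, or universe")
    rows = []
    for sid in sorted(collection.sets):
        name, members = collection.sets[sid]
        p, ell, k = ordered_enrichment(ranked_genes, members, uni)
        rows.append((sid, name, p, ell, k, len(members & uni)))
    adj = bh_adjust([r[2] for r in rows])
    results = [
        EnrichmentResult(
            set_id=sid,
            name=name,
            p_value=p,
            adjusted_p=a,
            best_prefix_size=ell,
            overlap_at_best=k,
            set_size=ksize,
            universe_size=len(uni),
        )
        for (sid, name, p, ell, k, ksize), a in zip(rows, adj)
        if a <= alpha
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.set_id))
    return results
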