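"""Preranked gene-set enrichment analysis with a permutation null.

The running enrichment score is the classic weighted Kolmogorov-Smirnov-like
statistic: walking down the ranked list, set members ("hits") increment the
running sum by ``|w|^q / sum_hits |w|^q`` and non-members decrement it by
``1 / (N - K)``; the enrichment score (ES) is the running-sum value of
maximum absolute deviation from zero, signed.  The leading edge ("core
enrichment") is the set members at or before the peak for positive ES, at
or after it for negative ES.

Significance uses gene-label permutation — the null ES distribution of
uniformly random same-size gene sets — which is the only null available for
preranked input.  NES divides ES by the mean of *same-sign* permuted ES
(sign-stratified, because the raw mean of a near-symmetric null sits near
zero and would be numerically unstable); the permutation p-value uses the
add-one estimator, so p is never exactly zero.

All randomness flows from a single integer seed through numpy's PCG64
generator, making results bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GeneSetCollection, PocketfishError
from .ora import bh_adjust


class DegenerateSetError(PocketfishError):
    """The gene set covers the whole ranked list: no misses exist."""


@dataclass(frozen=True)
class GseaResult:
    set_id: str
    es: float
    nes: float
    p_value: float
    adjusted_p: float
    leading_edge: tuple[str, ...]
    n_permutations: int
    seed: int
    significant: bool = False
    n_overlap: int = 0


def _hit_increments(
    weights: np.ndarray, hit_mask: np.ndarray, exponent: float
) -> tuple[np.ndarray, float]:
    w = np.abs(weights[hit_mask]) ** exponent
    total = float(sum(w.tolist()))  # sequential sum, matching the running walk
    if total == 0:
        # all hit weights zero: fall back to unweighted (uniform) increments
        w = np.ones(w.shape)
        total = float(w.size)
    return w, total


def running_enrichment_score(
    ranked: Sequence[tuple[str, float]],
    gene_set: frozenset[str] | set[str],
    exponent: float = 1.0,
) -> tuple[float, int, list[str]]:
    """ES, peak index (0-based) and leading edge for one gene set.

    ``ranked`` is the (gene, weight) list in ranking order; genes must be
    unique.  Raises :class:`DegenerateSetError` when the set covers the
    whole list; an empty intersection raises :class:`PocketfishError`
    (callers that tolerate no-overlap sets should check first).
    """
    genes = [g for g, _ in ranked]
    if len(set(genes)) != len(genes):
        raise PocketfishError("ranked list contains duplicate genes")
    members = {g.upper() for g in gene_set}
    hit_mask = np.array([g.upper() in members for g in genes], dtype=bool)
    N = len(genes)
    K = int(hit_mask.sum())
    if K == 0:
        raise PocketfishError("gene set does not overlap the ranked list")
    if K == N:
        raise DegenerateSetError("gene set covers the entire ranked list")
    weights = np.array([w for _, w in ranked], dtype=float)
    hit_w, total = _hit_increments(weights, hit_mask, exponent)
    steps = np.full(N, -1.0 / (N - K))
    steps[hit_mask] = hit_w / total
    # strict left-to-right accumulation (cumsum's pairwise summation can
    # differ in the last bit from the definitional sequential walk)
    running = np.array(list(itertools.accumulate(steps.tolist())))
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es > 0:
        leading = [g for g, hit in zip(genes[: peak + 1], hit_mask[: peak + 1]) if hit]
    elif es < 0:
        leading = [g for g, hit in zip(genes[peak:], hit_mask[peak:]) if hit]
    else:
        leading = []
    return es, peak, leading


def permutation_null(
    ranked: Sequence[tuple[str, float]],
    set_size: int,
    n_perm: int,
    seed: int,
    exponent: float = 1.0,
) -> np.ndarray:
    """Null ES values for ``n_perm`` uniformly random gene sets of the given
    size (drawn without replacement from the ranked list).  Deterministic
    for a fixed seed."""
    rng = np.random.default_rng(seed)
    return _permutation_null_rng(ranked, set_size, n_perm, rng, exponent)


def _permutation_null_rng(
    ranked: Sequence[tuple[str, float]],
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
) -> np.ndarray:
    N = len(ranked)
    K = int(set_size)
    if not (1 <= K < N):
        raise PocketfishError(f"set_size must be in [1, {N - 1}], got {K}")
    if n_perm < 1:
        raise PocketfishError("n_perm must be >= 1")
    weights = np.abs(np.array([w for _, w in ranked], dtype=float)) ** exponent
    miss = -1.0 / (N - K)
    out = np.empty(n_perm)
    # chunk the (n_perm x N) running-sum matrix to bound memory
    chunk = max(1, int(4_000_000 // max(N, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # b random K-subsets of positions, via partial argsort of random keys
        keys = rng.random((b, N))
        hits = np.argpartition(keys, K - 1, axis=1)[:, :K]
        steps = np.full((b, N), miss)
        hit_w = weights[hits]
        totals = hit_w.sum(axis=1, keepdims=True)
        zero = totals[:, 0] == 0
        if np.any(zero):
            hit_w[zero] = 1.0
            totals[zero] = K
        np.put_along_axis(steps, hits, hit_w / totals, axis=1)
        running = np.cumsum(steps, axis=1)
        peaks = np.argmax(np.abs(running), axis=1)
        out[done : done + b] = running[np.arange(b), peaks]
        done += b
    return out


def nes_and_p(es: float, null_es: Sequence[float]) -> tuple[float, float]:
    """Sign-stratified NES and add-one permutation p-value.

    For es > 0, NES = es / mean(positive null); for es < 0, NES preserves
    the negative sign with magnitude es / mean(negative null).  p counts
    same-sign null values at least as extreme as es.  When no same-sign
    null value exists, NES is undefined (NaN) and p = 1/(1+0) = 1.
    """
    null = np.asarray(null_es, dtype=float)
    if null.size == 0:
        raise PocketfishError("empty permutation null")
    if es == 0:
        return 0.0, 1.0
    same = null[null > 0] if es > 0 else null[null < 0]
    if same.size == 0:
        return math.nan, 1.0
    nes = abs(es) / float(np.abs(same).mean())
    if es < 0:
        nes = -nes
    n_extreme = int((np.abs(same) >= abs(es)).sum())
    p = (1 + n_extreme) / (1 + same.size)
    return float(nes), float(p)


def rank_genes(scores: Sequence[tuple[str, float]]) -> list[tuple[str, float]]:
    """Sort (gene, score) by decreasing score, ties broken by gene symbol."""
    return sorted(scores, key=lambda t: (-t[1], t[0]))


def run_gsea(
    ranked_genes_by_zzscore: Sequence[tuple[str, float]],
    collection: GeneSetCollection,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    exponent: float = 1.0,
    presorted: bool = False,
) -> list[GseaResult]:
    """Preranked GSEA of every collection set against a scored gene list.

    The list is sorted by decreasing score (ties by symbol) unless
    ``presorted``.  Each set gets its own permutation null (per-set sizes
    differ); BH adjustment runs across all sets with overlap, and a result
    is flagged significant when ``adjusted_p < alpha`` and ``nes > 0``.
    Sets with no overlap are reported with NaN statistics.
    """
    ranked = (
        list(ranked_genes_by_zzscore)
        if presorted
        else rank_genes(ranked_genes_by_zzscore)
    )
    if not ranked:
        raise PocketfishError("empty ranked list")
    if any(not math.isfinite(w) for _, w in ranked):
        raise PocketfishError("ranked scores must be finite")
    listed = {g.upper() for g, _ in ranked}
    rng = np.random.default_rng(seed)

    tested: list[tuple[str, float, float, float, list[str], int]] = []
    skipped: list[str] = []
    # one shared null per distinct overlap size keeps 10 K-permutation runs
    # affordable when many sets have equal size
    null_cache: dict[int, np.ndarray] = {}
    for sid in sorted(collection.sets):
        _, members = collection.sets[sid]
        overlap = {g.upper() for g in members} & listed
        K = len(overlap)
        if K == 0 or K == len(ranked):
            skipped.append(sid)
            continue
        es, _, leading = running_enrichment_score(ranked, members, exponent)
        if K not in null_cache:
            null_cache[K] = _permutation_null_rng(
                ranked, K, n_perm, rng, exponent
            )
        nes, p = nes_and_p(es, null_cache[K])
        tested.append((sid, es, nes, p, leading, K))

    adj = bh_adjust([t[3] for t in tested]) if tested else []
    results = [
        GseaResult(
            set_id=sid,
            es=es,
            nes=nes,
            p_value=p,
            adjusted_p=a,
            leading_edge=tuple(leading),
            n_permutations=n_perm,
            seed=seed,
            significant=bool(a < alpha and nes > 0),
            n_overlap=K,
        )
        for (sid, es, nes, p, leading, K), a in zip(tested, adj)
    ]
    for sid in skipped:
        results.append(
            GseaResult(
                set_id=sid,
                es=math.nan,
                nes=math.nan,
                p_value=math.nan,
                adjusted_p=math.nan,
                leading_edge=(),
                n_permutations=n_perm,
                seed=seed,
                significant=False,
                n_overlap=0,
            )
        )
    results.sort(key=lambda r: (math.isnan(r.p_value), r.p_value if not math.isnan(r.p_value) else 0.0, r.set_id))
    return results
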