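"""Independent brute-force oracles used only by the tests.

Each function here recomputes a statistic by the most literal method
available (explicit scans, combinatorial sums) and stays independent of
the package code paths it checks.
"""

from __future__ import annotations

from math import comb
from typing import Sequence


def hypergeom_tail_bruteforce(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by explicit combinatorial summation."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += comb(K, x) * comb(N - K, n - x)
    return acc / total


def bh_stepup_bruteforce(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook recursion."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj_sorted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p_values[i] * m / rank)
        adj_sorted[rank - 1] = val
        prev = val
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out


def running_es_bruteforce(
    ranked: Sequence[tuple[str, float]],
    gene_set: set[str],
    exponent: float = 1.0,
) -> tuple[float, int]:
    """Enrichment score by an explicit position-by-position walk."""
    members = {g.upper() for g in gene_set}
    hits = [g.upper() in members for g, _ in ranked]
    N = len(ranked)
    K = sum(hits)
    denom_hit = sum(abs(w) ** exponent for (g, w), h in zip(ranked, hits) if h)
    running = 0.0
    best = 0.0
    best_i = 0
    for i, ((g, w), h) in enumerate(zip(ranked, hits)):
        if h:
            if denom_hit == 0:
                running += 1.0 / K
            else:
                running += abs(w) ** exponent / denom_hit
        else:
            running -= 1.0 / (N - K)
        if abs(running) > abs(best):
            best = running
            best_i = i
    return best, best_i
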