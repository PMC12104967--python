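"""Synthetic pocketome screens with planted ground truth.

The generator emulates the dominant nuisance structure of a large
inverse-docking screen — ligand-level and pocket-level additive effects
(molecule size and flexibility inflate a row; pocket volume inflates a
column) plus unstructured noise:

    score(m, p) = mu + a_m + b_p + eps_{m,p}

with ``a ~ N(0, sigma_a^2)``, ``b ~ N(0, sigma_b^2)``,
``eps ~ N(0, sigma_eps^2)``.  Planted true interactions add
``delta * sigma_eps`` to selected (query, pocket) cells on the raw-score
scale, so delta is an effect size in noise units.  A configurable fraction
of entries is deleted at random to exercise the missing-data path.  Every
draw flows from one integer seed.

This additive Gaussian model is the simplest structure exhibiting the
row/column confounding the double normalization is designed to remove; it
makes no claim about the true distribution of docking scores.  By default
each pocket maps to its own synthetic gene, which keeps gene-level recovery
bookkeeping unambiguous; ``pockets_per_gene > 1`` exercises the
pocket-to-gene collapse instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import (
    AffinityTable,
    GeneSetCollection,
    LigandRecord,
    LigandRole,
    PocketfishError,
    PocketRecord,
)
from .targets import GeneTargetCall


@dataclass
class SimulationParams:
    """Knobs for one synthetic screen.

    Defaults mirror a small two-enantiomer study design: 2 query ligands
    normalized against a 10-drug inactive panel, with equal nuisance and
    noise scales (sigma_a = sigma_b = sigma_eps = 1).
    """

    n_pockets: int = 500
    n_query: int = 2
    n_inactive: int = 10
    mu: float = 50.0
    sigma_a: float = 1.0
    sigma_b: float = 1.0
    sigma_eps: float = 1.0
    planted: list[tuple[int, int]] = field(default_factory=list)
    delta: float = 6.0
    missing_fraction: float = 0.0
    pockets_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inactive < 2:
            raise PocketfishError("n_inactive must be >= 2")
        if not 0 <= self.missing_fraction < 1:
            raise PocketfishError("missing_fraction must be in [0, 1)")
        per_ligand: dict[int, set[int]] = {}
        for q, p in self.planted:
            if not (0 <= q < self.n_query and 0 <= p < self.n_pockets):
                raise PocketfishError(f"planted pair ({q}, {p}) out of range")
            if p in per_ligand.setdefault(q, set()):
                raise PocketfishError(
                    f"planted pocket {p} repeated for query ligand {q}"
                )
            per_ligand[q].add(p)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated screen."""

    planted_pairs: list[tuple[str, str]]
    delta: float
    gene_of_pocket: dict[str, str]
    planted_genes: frozenset[str]
    planted_set_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_pairs": [list(t) for t in self.planted_pairs],
            "delta": self.delta,
            "gene_of_pocket": self.gene_of_pocket,
            "planted_genes": sorted(self.planted_genes),
            "planted_set_ids": self.planted_set_ids,
        }


def default_planted_pairs(
    n_query: int, n_pockets: int, n_planted: int, seed: int
) -> list[tuple[int, int]]:
    """Spread ``n_planted`` planted pairs round-robin over the query
    ligands, with distinct pockets per ligand, chosen uniformly."""
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    per_ligand = [
        n_planted // n_query + (1 if i < n_planted % n_query else 0)
        for i in range(n_query)
    ]
    for q, count in enumerate(per_ligand):
        pockets = rng.choice(n_pockets, size=count, replace=False)
        pairs.extend((q, int(p)) for p in pockets)
    return pairs


def simulate_affinity(
    params: SimulationParams,
) -> tuple[AffinityTable, list[LigandRecord], list[PocketRecord], SyntheticTruth]:
    """Draw one synthetic screen.

    Returns the affinity table, a ligand manifest (queries named ``Q01``…,
    inactives ``I01``…), pocket annotations (pockets ``poc00001``… mapped
    to genes ``GENE0001``…), and the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    n_lig = params.n_query + params.n_inactive
    a = rng.normal(0.0, params.sigma_a, size=n_lig)
    b = rng.normal(0.0, params.sigma_b, size=params.n_pockets)
    eps = rng.normal(0.0, params.sigma_eps, size=(n_lig, params.n_pockets))
    scores = params.mu + a[:, None] + b[None, :] + eps
    for q, p in params.planted:
        scores[q, p] += params.delta * params.sigma_eps

    query_ids = [f"Q{i + 1:02d}" for i in range(params.n_query)]
    inactive_ids = [f"I{i + 1:02d}" for i in range(params.n_inactive)]
    ligands = query_ids + inactive_ids
    pockets = [f"poc{i + 1:05d}" for i in range(params.n_pockets)]

    keep = np.ones(scores.shape, dtype=bool)
    if params.missing_fraction > 0:
        keep = rng.random(scores.shape) >= params.missing_fraction
    score_map = {
        (ligands[i], pockets[j]): float(scores[i, j])
        for i in range(n_lig)
        for j in range(params.n_pockets)
        if keep[i, j]
    }
    table = AffinityTable(ligands, pockets, score_map)

    manifest = [
        LigandRecord(m, LigandRole.QUERY) for m in query_ids
    ] + [LigandRecord(m, LigandRole.INACTIVE) for m in inactive_ids]

    gene_of: dict[str, str] = {}
    annotations: list[PocketRecord] = []
    for j, pid in enumerate(pockets):
        gene = f"GENE{j // params.pockets_per_gene + 1:04d}"
        gene_of[pid] = gene
        annotations.append(
            PocketRecord(pocket_id=pid, pdb_entry=f"S{j % 9000 + 1000:04d}",
                         gene_symbol=gene)
        )

    planted_pairs = [
        (query_ids[q], pockets[p]) for q, p in params.planted
    ]
    truth = SyntheticTruth(
        planted_pairs=planted_pairs,
        delta=params.delta,
        gene_of_pocket=gene_of,
        planted_genes=frozenset(gene_of[p] for _, p in planted_pairs),
    )
    return table, manifest, annotations, truth


def simulate_collection(
    truth: SyntheticTruth,
    n_decoy_sets: int,
    set_size: int,
    seed: int,
) -> GeneSetCollection:
    """Gene-set collection with one planted set (the planted genes, padded
    to ``set_size`` with random non-planted genes) plus random decoy sets
    of the same size.  Deterministic by seed."""
    rng = np.random.default_rng(seed)
    all_genes = sorted(set(truth.gene_of_pocket.values()))
    if set_size > len(all_genes):
        raise PocketfishError("set_size exceeds number of synthetic genes")
    planted = sorted(truth.planted_genes)
    pool = [g for g in all_genes if g not in truth.planted_genes]
    pad_n = max(0, set_size - len(planted))
    pad = list(rng.choice(pool, size=pad_n, replace=False)) if pad_n else []
    sets: dict[str, tuple[str, frozenset[str]]] = {
        "PLANTED": ("planted true-target set", frozenset(planted + pad))
    }
    for d in range(n_decoy_sets):
        members = rng.choice(all_genes, size=set_size, replace=False)
        sets[f"DECOY{d + 1:03d}"] = (
            f"random decoy set {d + 1}",
            frozenset(str(g) for g in members),
        )
    truth.planted_set_ids = ["PLANTED"]
    return GeneSetCollection(sets, universe=frozenset(all_genes))


def evaluate_recovery(
    calls: Sequence[GeneTargetCall], truth: SyntheticTruth
) -> tuple[float, float, dict[str, int]]:
    """Gene-level precision and recall of target calls against the planted
    genes.  Precision is 1.0 when there are no calls (vacuous)."""
    called = {c.gene_symbol for c in calls}
    tp = len(called & truth.planted_genes)
    fp = len(called - truth.planted_genes)
    fn = len(truth.planted_genes - called)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return precision, recall, {"tp": tp, "fp": fp, "fn": fn}
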