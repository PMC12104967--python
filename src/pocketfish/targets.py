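"""Threshold filtering, pocket-to-gene collapse, and gene-list comparison.

A pocket-level pair passes a threshold regime iff all three inclusive
conditions hold: ``zzscore >= zz_min``, ``zscore_poc >= zpoc_min`` and
``zscore_mol >= zmol_min``.  The component bounds exist so that a high
combined score driven entirely by one addend (e.g. a ligand that scores
uniformly well everywhere) does not pass.  Two presets mirror common
practice: *relaxed* (2.0 / 0.8 / 0.8) and *stringent* (2.0 / 1.0 / 1.0);
because every comparison is inclusive and the stringent bounds dominate the
relaxed ones, stringent output is always a subset of relaxed output.

Genes, not pockets, are the unit of biological interpretation: different
ligands may reach the same gene through different PDB entries.  A gene is
called for a ligand iff at least one of its pockets passes all thresholds;
the reported "best pocket" is the passing pocket with maximal zzscore
(ties broken lexicographically by pocket_id, for determinism).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import PocketfishError, PocketRecord, ThresholdConfig
from .scoring import ScoredPair


@dataclass(frozen=True)
class GeneTargetCall:
    """Gene-level target verdict for one ligand under one regime."""

    ligand_id: str
    gene_symbol: str
    best_pocket_id: str
    best_zzscore: float
    best_zscore_poc: float
    best_zscore_mol: float
    n_passing_pockets: int


def apply_thresholds(
    pairs: Iterable[ScoredPair], config: ThresholdConfig
) -> list[ScoredPair]:
    """Keep exactly the pairs passing all three inclusive thresholds.
    Pairs with undefined components automatically fail."""
    return [
        p
        for p in pairs
        if p.defined
        and p.zzscore >= config.zz_min
        and p.zscore_poc >= config.zpoc_min
        and p.zscore_mol >= config.zmol_min
    ]


def collapse_to_genes(
    passing: Iterable[ScoredPair],
    annotations: Sequence[PocketRecord],
) -> tuple[list[GeneTargetCall], int]:
    """Collapse passing pocket-level pairs to one call per (ligand, gene).

    Passing pockets without a gene annotation are excluded; the second
    return value counts them (the caller should surface it as a warning).
    Output order is deterministic: by ligand then gene.
    """
    gene_of = {a.pocket_id: a.gene_symbol for a in annotations}
    groups: dict[tuple[str, str], list[ScoredPair]] = {}
    n_unmapped = 0
    for p in passing:
        gene = gene_of.get(p.pocket_id)
        if gene is None:
            n_unmapped += 1
            continue
        groups.setdefault((p.ligand_id, gene), []).append(p)
    calls: list[GeneTargetCall] = []
    for (lig, gene), members in sorted(groups.items()):
        best = min(members, key=lambda p: (-p.zzscore, p.pocket_id))
        calls.append(
            GeneTargetCall(
                ligand_id=lig,
                gene_symbol=gene,
                best_pocket_id=best.pocket_id,
                best_zzscore=best.zzscore,
                best_zscore_poc=best.zscore_poc,
                best_zscore_mol=best.zscore_mol,
                n_passing_pockets=len(members),
            )
        )
    return calls, n_unmapped


def compare_gene_lists(
    list_a: Iterable[str], list_b: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition two gene lists into (common, only_a, only_b).

    Symbols compare case-insensitively; the three parts partition the
    union exactly, so ``|common| + |only_a| == |set(list_a)|``.
    """
    a = {str(g).strip().upper() for g in list_a}
    b = {str(g).strip().upper() for g in list_b}
    return a & b, a - b, b - a


def venn_summary_frame(
    list_a: Iterable[str], list_b: Iterable[str], name_a: str, name_b: str
) -> pd.DataFrame:
    common, only_a, only_b = compare_gene_lists(list_a, list_b)
    rows = (
        [("common", g) for g in sorted(common)]
        + [(f"only_{name_a}", g) for g in sorted(only_a)]
        + [(f"only_{name_b}", g) for g in sorted(only_b)]
    )
    return pd.DataFrame(rows, columns=["partition", "gene_symbol"])


def genes_for_ligand(
    calls: Iterable[GeneTargetCall], ligand_id: str
) -> list[str]:
    """Gene symbols called for one ligand, ranked by decreasing best
    zzscore (ties broken alphabetically) — the ranking used downstream for
    ordered enrichment."""
    mine = [c for c in calls if c.ligand_id == ligand_id]
    mine.sort(key=lambda c: (-c.best_zzscore, c.gene_symbol))
    return [c.gene_symbol for c in mine]


def export_heatmap_table(
    calls: Sequence[GeneTargetCall], ligands: Sequence[str]
) -> pd.DataFrame:
    """Genes x ligands matrix of best zzscores (NaN where no call), rows
    ordered by each gene's maximum score, descending."""
    if not calls:
        raise PocketfishError("no gene calls: empty heatmap")
    genes = sorted({c.gene_symbol for c in calls})
    data = {
        lig: [math.nan] * len(genes) for lig in ligands
    }
    idx = {g: i for i, g in enumerate(genes)}
    for c in calls:
        if c.ligand_id in data:
            data[c.ligand_id][idx[c.gene_symbol]] = c.best_zzscore
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene_symbol"))
    order = df.max(axis=1).sort_values(ascending=False, kind="stable").index
    return df.loc[order]


def calls_to_frame(calls: Iterable[GeneTargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.ligand_id,
                c.gene_symbol,
                c.best_pocket_id,
                c.best_zzscore,
                c.best_zscore_poc,
                c.best_zscore_mol,
                c.n_passing_pockets,
            )
            for c in calls
        ],
        columns=[
            "ligand_id",
            "gene_symbol",
            "best_pocket_id",
            "best_zzscore",
            "best_zscore_poc",
            "best_zscore_mol",
            "n_passing_pockets",
        ],
    )
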