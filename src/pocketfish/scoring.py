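"""Double z-normalization of an affinity matrix: the ZZscore.

Inverse-docking screens that compare many ligands against many pockets are
confounded by ligand- and pocket-level nuisance effects (size, shape,
conformational freedom inflate or deflate raw affinity scores wholesale).
The ZZscore removes both in one additive metric:

* ``zscore_poc`` standardizes a pair's raw score against the scores of a
  panel of phenotypically *inactive* reference drugs on the **same pocket**
  — it asks "does this ligand bind this pocket better than drugs known to
  do nothing?".
* ``zscore_mol`` standardizes the same raw score against the ligand's own
  scores over the **whole pocketome** — it asks "is this pocket special for
  this ligand?".
* ``zzscore = zscore_poc + zscore_mol`` weights the two equally and is the
  ranking metric.

Both standardizations use the sample standard deviation (n - 1 denominator),
the convention of the statistical environments these pipelines are scripted
in; with a 10-drug inactive panel this differs from the population sd by
about 5%, so the choice is recorded in the output metadata.  The query
ligand's own score is never part of the inactive background; the focal
pocket's score *is* part of the ligand's pocketome background (the
background is "all pockets", with no exclusion).  Backgrounds with zero
spread or fewer than two values yield *undefined* scores — flagged and
excluded from ranking — never infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    AffinityTable,
    LigandRecord,
    LigandRole,
    PanelTooSmallError,
    PocketfishError,
)


class DegenerateBackgroundError(PocketfishError):
    """The background has zero spread: a z-score is undefined."""


class MissingLigandError(PocketfishError):
    """A manifest ligand has no scores in the affinity table."""


@dataclass(frozen=True)
class ScoredPair:
    """One query-ligand / pocket pair with its raw and normalized scores.

    ``zzscore`` is defined iff both components are (NaN marks undefined);
    when defined it equals ``zscore_poc + zscore_mol`` exactly.
    """

    ligand_id: str
    pocket_id: str
    globsum: float
    zscore_poc: float = math.nan
    zscore_mol: float = math.nan

    @property
    def zzscore(self) -> float:
        return self.zscore_poc + self.zscore_mol

    @property
    def defined(self) -> bool:
        return math.isfinite(self.zscore_poc) and math.isfinite(self.zscore_mol)


def _standardize(value: float, background: Sequence[float]) -> float:
    bg = np.asarray(background, dtype=float)
    if bg.size < 2:
        raise PanelTooSmallError(
            f"background has {bg.size} value(s); need >= 2"
        )
    if not np.all(np.isfinite(bg)):
        raise PocketfishError("background contains non-finite values")
    sd = float(bg.std(ddof=1))
    if sd == 0.0:
        raise DegenerateBackgroundError("background has zero spread")
    return (float(value) - float(bg.mean())) / sd


def zscore_poc(globsum: float, inactive_scores: Sequence[float]) -> float:
    """Standardize ``globsum`` against the inactive-panel scores observed on
    the same pocket: ``(globsum - mean) / sd`` with sample sd.  A value one
    sample sd above the panel mean maps to exactly 1.0."""
    return _standardize(globsum, inactive_scores)


def zscore_mol(globsum: float, pocket_scores_for_ligand: Sequence[float]) -> float:
    """Standardize ``globsum`` against the ligand's scores over all pockets
    (the focal pocket's own score included in the background)."""
    return _standardize(globsum, pocket_scores_for_ligand)


@dataclass
class ScoringMetadata:
    """Self-describing sidecar for a scored-pairs table."""

    sd_convention: str
    inactive_panel: list[str]
    focal_in_mol_background: bool
    n_pockets_scored: int
    n_pockets_dropped_small_panel: int
    n_pairs_undefined: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def score_all(
    table: AffinityTable,
    manifest: Sequence[LigandRecord],
    *,
    include_inactive: bool = False,
    leave_one_out: bool = False,
) -> tuple[list[ScoredPair], ScoringMetadata]:
    """Score every (query ligand, pocket) pair with a finite raw score.

    A pocket contributes defined ``zscore_poc`` values only if at least two
    inactive-panel scores exist for it; pairs failing that (or any
    degenerate background) are emitted with NaN components and counted in
    the metadata rather than silently dropped.

    With ``include_inactive=True`` the inactive ligands are scored too
    (useful for simulator ROC work); their pocket background is the full
    inactive panel including themselves unless ``leave_one_out=True``.
    """
    roles = {r.ligand_id: r.role for r in manifest}
    unknown = [m for m in table.ligands if m not in roles]
    if unknown:
        raise PocketfishError(
            f"table ligands missing from manifest: {unknown}"
        )
    inactive_ids = [
        r.ligand_id for r in manifest if r.role is LigandRole.INACTIVE
    ]
    query_ids = [r.ligand_id for r in manifest if r.role is LigandRole.QUERY]
    if len(inactive_ids) < 2:
        raise PanelTooSmallError(
            f"{len(inactive_ids)} inactive ligand(s); need >= 2"
        )
    for q in query_ids:
        if not any((q, p) in table.score for p in table.pockets):
            raise MissingLigandError(
                f"query ligand {q!r} has no scores in the table"
            )

    targets = query_ids + (inactive_ids if include_inactive else [])

    # per-ligand pocketome backgrounds (all of that ligand's finite scores)
    lig_scores: dict[str, dict[str, float]] = {
        m: table.ligand_scores(m) for m in targets
    }
    # per-pocket inactive backgrounds
    poc_bg: dict[str, dict[str, float]] = {}
    for (m, p), v in table.score.items():
        if m in inactive_ids:
            poc_bg.setdefault(p, {})[m] = v

    pairs: list[ScoredPair] = []
    dropped_pockets: set[str] = set()
    n_undefined = 0
    for m in targets:
        own = lig_scores[m]
        mol_bg = list(own.values())
        for p in table.pockets:
            if p not in own:
                continue
            g = own[p]
            bg_map = poc_bg.get(p, {})
            if m in inactive_ids and leave_one_out:
                bg = [v for lid, v in bg_map.items() if lid != m]
            else:
                bg = list(bg_map.values())
            zp = zm = math.nan
            try:
                zp = zscore_poc(g, bg)
            except (PanelTooSmallError, DegenerateBackgroundError):
                if len(bg) < 2:
                    dropped_pockets.add(p)
            try:
                zm = zscore_mol(g, mol_bg)
            except (PanelTooSmallError, DegenerateBackgroundError):
                pass
            pair = ScoredPair(m, p, g, zp, zm)
            if not pair.defined:
                n_undefined += 1
            pairs.append(pair)

    meta = ScoringMetadata(
        sd_convention="sample (ddof=1)",
        inactive_panel=sorted(inactive_ids),
        focal_in_mol_background=True,
        n_pockets_scored=len({p.pocket_id for p in pairs}),
        n_pockets_dropped_small_panel=len(dropped_pockets),
        n_pairs_undefined=n_undefined,
    )
    return pairs, meta


def pairs_to_frame(pairs: Iterable[ScoredPair]) -> pd.DataFrame:
    rows = [
        (
            p.ligand_id,
            p.pocket_id,
            p.globsum,
            p.zscore_poc,
            p.zscore_mol,
            p.zzscore,
            p.defined,
        )
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ligand_id",
            "pocket_id",
            "globsum",
            "zscore_poc",
            "zscore_mol",
            "zzscore",
            "defined",
        ],
    )


def write_scored_pairs(
    pairs: Iterable[ScoredPair], path: str | Path
) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_scored_pairs(path: str | Path) -> list[ScoredPair]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return [
        ScoredPair(
            str(r.ligand_id),
            str(r.pocket_id),
            float(r.globsum),
            float(r.zscore_poc) if pd.notna(r.zscore_poc) else math.nan,
            float(r.zscore_mol) if pd.notna(r.zscore_mol) else math.nan,
        )
        for r in df.itertuples(index=False)
    ]
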