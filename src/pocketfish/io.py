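"""Domain types and tabular readers/writers.

All tabular inputs and outputs are tab-delimited UTF-8 text with a header
row.  The canonical affinity layout is *long* (``ligand_id``, ``pocket_id``,
``score``) because a ligand x pocketome screen is naturally sparse: pockets
for which a ligand produced no pose are simply absent.  A *wide* layout
(pockets as rows, ligands as columns, blank/NA cells for missing pairs) is
accepted as a convenience.

Missing affinities are first-class: an absent (ligand, pocket) pair is
"no score", never 0.  Gene symbols are whitespace-trimmed and uppercased on
ingest so that downstream set operations are case-insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class PocketfishError(Exception):
    """Base class for all domain errors raised by this package."""


class SchemaError(PocketfishError):
    """A required column or field is missing or malformed."""


class DuplicateKeyError(PocketfishError):
    """A key that must be unique appears more than once."""


class ParseError(PocketfishError):
    """A cell could not be parsed (carries a line number when known)."""


class PanelTooSmallError(PocketfishError):
    """Fewer than two inactive reference ligands: no background sd exists."""


class LigandRole(str, Enum):
    QUERY = "query"
    INACTIVE = "inactive"


@dataclass(frozen=True)
class LigandRecord:
    """One screened ligand: a phenotypic *query* compound or a member of the
    phenotypically *inactive* reference panel used as normalization
    background."""

    ligand_id: str
    role: LigandRole
    label: str | None = None


@dataclass(frozen=True)
class PocketRecord:
    """One binding pocket with its PDB provenance and gene annotation.

    ``pocket_id`` is an opaque unique string (e.g. ``6d5w1_018``);
    ``gene_symbol`` is ``None`` for unmapped pockets.
    """

    pocket_id: str
    pdb_entry: str
    gene_symbol: str | None = None
    uniprot: str | None = None
    resolution: float | None = None


@dataclass
class ThresholdConfig:
    """Score thresholds for pocket-level target filtering (all inclusive).

    ``zz_min`` bounds the combined ZZscore; ``zpoc_min`` / ``zmol_min``
    bound the two addends so that a pass cannot be driven by one term alone.
    """

    zz_min: float = 2.0
    zpoc_min: float = 0.8
    zmol_min: float = 0.8
    name: str = "custom"

    def __post_init__(self) -> None:
        for v in (self.zz_min, self.zpoc_min, self.zmol_min):
            if not math.isfinite(v):
                raise SchemaError("thresholds must be finite")

    @classmethod
    def relaxed(cls) -> "ThresholdConfig":
        return cls(2.0, 0.8, 0.8, name="relaxed")

    @classmethod
    def stringent(cls) -> "ThresholdConfig":
        return cls(2.0, 1.0, 1.0, name="stringent")

    @classmethod
    def preset(cls, name: str) -> "ThresholdConfig":
        try:
            return {"relaxed": cls.relaxed, "stringent": cls.stringent}[name]()
        except KeyError:
            raise SchemaError(f"unknown threshold regime {name!r}") from None


def normalize_gene(symbol: str) -> str | None:
    """Trim and uppercase a gene symbol; empty/NA-like cells become None."""
    s = str(symbol).strip().upper()
    if s in ("", "NA", "NAN", "NONE"):
        return None
    return s


@dataclass
class AffinityTable:
    """Sparse ligand x pocket matrix of raw affinity scores (GlobSum-like,
    dimensionless).  ``score`` maps (ligand_id, pocket_id) to a finite real;
    absent keys are missing observations."""

    ligands: list[str]
    pockets: list[str]
    score: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lig, poc = set(self.ligands), set(self.pockets)
        if len(lig) != len(self.ligands):
            raise DuplicateKeyError("duplicate ligand_id in table")
        if len(poc) != len(self.pockets):
            raise DuplicateKeyError("duplicate pocket_id in table")
        for (m, p), v in self.score.items():
            if m not in lig or p not in poc:
                raise SchemaError(f"score key ({m}, {p}) not declared")
            if not math.isfinite(v):
                raise ParseError(f"non-finite score for ({m}, {p})")

    def get(self, ligand_id: str, pocket_id: str) -> float | None:
        return self.score.get((ligand_id, pocket_id))

    def ligand_scores(self, ligand_id: str) -> dict[str, float]:
        """All observed scores for one ligand, keyed by pocket."""
        return {
            p: v for (m, p), v in self.score.items() if m == ligand_id
        }

    def pocket_scores(self, pocket_id: str) -> dict[str, float]:
        """All observed scores for one pocket, keyed by ligand."""
        return {
            m: v for (m, p), v in self.score.items() if p == pocket_id
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (ligand_id, pocket_id, score), row order
        following the declared ligand then pocket order."""
        rows = [
            (m, p, self.score[(m, p)])
            for m in self.ligands
            for p in self.pockets
            if (m, p) in self.score
        ]
        return pd.DataFrame(rows, columns=["ligand_id", "pocket_id", "score"])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): ``sets`` maps set_id -> (name,
    frozenset of uppercased member symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise SchemaError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_affinity_table(path: str | Path, layout: str = "long") -> AffinityTable:
    """Read an affinity table from TSV.

    ``layout='long'`` expects columns ligand_id, pocket_id, score;
    ``layout='wide'`` expects a ``pocket_id`` column followed by one column
    per ligand.  Blank or NA score cells become missing pairs, never zero.
    """
    path = Path(path)
    if layout not in ("long", "wide"):
        raise SchemaError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if layout == "long":
        _require_columns(df, ["ligand_id", "pocket_id", "score"], path)
        ligands: list[str] = []
        pockets: list[str] = []
        seen_l: set[str] = set()
        seen_p: set[str] = set()
        score: dict[tuple[str, str], float] = {}
        for i, row in enumerate(df.itertuples(index=False), start=2):
            m, p, raw = str(row.ligand_id), str(row.pocket_id), str(row.score)
            if m not in seen_l:
                seen_l.add(m)
                ligands.append(m)
            if p not in seen_p:
                seen_p.add(p)
                pockets.append(p)
            cell = raw.strip()
            if cell in ("", "NA", "NaN", "nan"):
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{i}: non-numeric score {cell!r}"
                ) from None
            if (m, p) in score:
                raise DuplicateKeyError(
                    f"{path}: duplicate pair ({m}, {p})"
                )
            score[(m, p)] = v
        return AffinityTable(ligands, pockets, score)

    # wide: pockets as rows, ligands as columns
    _require_columns(df, ["pocket_id"], path)
    lig_cols = [c for c in df.columns if c != "pocket_id"]
    if not lig_cols:
        raise SchemaError(f"{path}: wide layout needs ligand columns")
    pockets = list(df["pocket_id"].astype(str))
    if len(set(pockets)) != len(pockets):
        raise DuplicateKeyError(f"{path}: duplicate pocket_id row")
    score = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        p = str(row.pocket_id)
        for j, m in enumerate(lig_cols):
            cell = str(row[j + 1]).strip()
            if cell in ("", "NA", "NaN", "nan"):
                continue
            try:
                score[(m, p)] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{i}: non-numeric score {cell!r} for ligand {m}"
                ) from None
    return AffinityTable(list(lig_cols), pockets, score)


def write_affinity_table(
    table: AffinityTable, path: str | Path, layout: str = "long"
) -> None:
    """Write an affinity table as TSV; round-trips bit-exactly through
    :func:`read_affinity_table` (float repr is shortest-exact)."""
    path = Path(path)
    if layout == "long":
        rows = [
            (m, p, repr(table.score[(m, p)]))
            for m in table.ligands
            for p in table.pockets
            if (m, p) in table.score
        ]
        pd.DataFrame(rows, columns=["ligand_id", "pocket_id", "score"]).to_csv(
            path, sep="\t", index=False
        )
        return
    if layout != "wide":
        raise SchemaError(f"unknown layout {layout!r}")
    data = {
        "pocket_id": table.pockets,
        **{
            m: [
                repr(table.score[(m, p)]) if (m, p) in table.score else ""
                for p in table.pockets
            ]
            for m in table.ligands
        },
    }
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_ligand_manifest(path: str | Path) -> list[LigandRecord]:
    """Read the ligand manifest TSV (columns ligand_id, role[, label]).

    Roles parse case-insensitively.  At least one query and two inactive
    ligands are required: the inactive panel defines a standard deviation,
    which is undefined for n < 2.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["ligand_id", "role"], path)
    records: list[LigandRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        lid = str(row.ligand_id).strip()
        if lid in seen:
            raise DuplicateKeyError(f"{path}:{i}: duplicate ligand_id {lid!r}")
        seen.add(lid)
        raw_role = str(row.role).strip().lower()
        try:
            role = LigandRole(raw_role)
        except ValueError:
            raise SchemaError(
                f"{path}:{i}: unknown role {row.role!r} "
                "(expected 'query' or 'inactive')"
            ) from None
        label = str(getattr(row, "label", "")).strip() or None
        records.append(LigandRecord(lid, role, label))
    n_query = sum(r.role is LigandRole.QUERY for r in records)
    n_inactive = sum(r.role is LigandRole.INACTIVE for r in records)
    if n_query < 1:
        raise SchemaError(f"{path}: manifest declares no query ligand")
    if n_inactive < 2:
        raise PanelTooSmallError(
            f"{path}: {n_inactive} inactive ligand(s); need >= 2 for a "
            "background standard deviation"
        )
    return records


def read_pocket_annotations(path: str | Path) -> list[PocketRecord]:
    """Read pocket -> PDB entry -> gene annotations (columns pocket_id,
    pdb_entry, gene_symbol[, uniprot, resolution]).  Blank genes are kept
    as unmapped records."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["pocket_id", "pdb_entry", "gene_symbol"], path)
    records: list[PocketRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(row.pocket_id).strip()
        if pid in seen:
            raise DuplicateKeyError(f"{path}:{i}: duplicate pocket_id {pid!r}")
        seen.add(pid)
        uniprot = str(getattr(row, "uniprot", "")).strip() or None
        res_raw = str(getattr(row, "resolution", "")).strip()
        resolution = float(res_raw) if res_raw else None
        records.append(
            PocketRecord(
                pocket_id=pid,
                pdb_entry=str(row.pdb_entry).strip(),
                gene_symbol=normalize_gene(row.gene_symbol),
                uniprot=uniprot,
                resolution=resolution,
            )
        )
    return records


def write_pocket_annotations(
    records: Iterable[PocketRecord], path: str | Path
) -> None:
    rows = [
        (
            r.pocket_id,
            r.pdb_entry,
            r.gene_symbol or "",
            r.uniprot or "",
            "" if r.resolution is None else repr(r.resolution),
        )
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["pocket_id", "pdb_entry", "gene_symbol", "uniprot", "resolution"],
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: ``set_id <tab> description <tab> members...``

    Members are uppercased and deduplicated; a line with fewer than three
    fields, an empty member list, or an empty file is a format error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{i}: GMT line has {len(fields)} fields, needs >= 3"
                )
            sid, desc = fields[0].strip(), fields[1].strip()
            members = frozenset(
                g for g in (normalize_gene(f) for f in fields[2:]) if g
            )
            if not members:
                raise SchemaError(f"{path}:{i}: gene set {sid!r} has no members")
            if sid in sets:
                raise DuplicateKeyError(f"{path}:{i}: duplicate set_id {sid!r}")
            sets[sid] = (desc, members)
    if not sets:
        raise SchemaError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def write_rnk(ranked: Sequence[tuple[str, float]], path: str | Path) -> None:
    """Write a two-column ranked gene list (gene <tab> score)."""
    pd.DataFrame(ranked, columns=["gene", "score"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_rnk(path: str | Path) -> list[tuple[str, float]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    out: list[tuple[str, float]] = []
    for row in df.itertuples(index=False):
        g = normalize_gene(row.gene)
        if g is None:
            raise SchemaError(f"{path}: blank gene symbol in ranked list")
        out.append((g, float(row.score)))
    return out
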