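"""Worked-example gene lists for the two mirtazapine enantiomers.

These are the stringent-regime target lists (ZZscore >= 2.0, both addends
>= 1.0) and the GSEA core-enrichment lists for the S(+) and R(-)
enantiomers of mirtazapine screened against the human liganded pocketome
with a 10-drug inactive reference panel.  They serve as small real-world
inputs for the set-comparison operations: the two stringent lists share
exactly five genes (ALDH2, NOTUM, NSD2, PYGL, PYGM) and the two
core-enrichment lists share eleven.

Symbols follow the source tables verbatim, which mix UniProt-style and
HGNC-style names (e.g. RASH for HRAS, MK14 for MAPK14); list comparison is
case-insensitive but does not translate between naming schemes.
"""

from __future__ import annotations

STRINGENT_TARGETS_S: tuple[str, ...] = (
    "ALDH2", "PPARG", "PYGL", "PTN1", "EED", "PNMT", "CAH2", "NOTUM",
    "KMT5B", "PARG", "TP53B", "BRPF1", "NSD2", "PYGM", "ERR3", "QPCT",
)

STRINGENT_TARGETS_R: tuple[str, ...] = (
    "PYGL", "ALDH2", "MK14", "NCOA2", "RXRG", "NOTUM", "CHKB", "B2CL1",
    "RIOK2", "HS90A", "PYGM", "NSD2", "MGA", "ESR1",
)

CORE_ENRICHMENT_S: tuple[str, ...] = (
    "PPARG", "HDAC6", "SOS1", "KDM5A", "EZH2", "HMOX1", "EHMT2", "MAP2",
    "EHMT1", "NQO1", "BRD4", "NTRK1", "NCOR2", "PDE4D", "NPC1", "FKBP5",
    "BCL2", "NCOR1", "AKT1", "GSK3B",
)

CORE_ENRICHMENT_R: tuple[str, ...] = (
    "PPARG", "BRD4", "SOS1", "HDAC6", "PDE4D", "FKBP5", "EZH2", "MAP2",
    "BCL2", "KAT2B", "NCOR2", "HIF1A", "BRD2", "NQO1",
)

#: The ten phenotypically inactive reference drugs of the worked example.
INACTIVE_PANEL: tuple[str, ...] = (
    "alprenolol", "amiloride", "felodipine", "galantamine", "meglumine",
    "piroxicam", "pravadoline", "spectinomycin", "tizanidine", "tubocurarine",
)
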