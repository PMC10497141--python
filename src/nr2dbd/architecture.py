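"""Architecture classification, inter-DBD linker, NTSS and CTE analysis.

Covers the four modular-architecture categories of nuclear receptors
(plus NOT_NR), the 17–22-residue region between the two DBDs of a
2DBD-NR, the N-terminal signature sequences (NTSS) of parasitic
platyhelminth 2DBD-NRs, and the C-terminal extension of the DBD: the
Grip box (G-box, consensus RXGRZP with group-specific variants), the
pre-Grip stretch before it, the 12-residue T-box criterion and the
conserved H five residues after the G-box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from . import motifs
from .seq_io import Architecture, SequenceRecord
from .zf_scan import DBD

logger = logging.getLogger(__name__)


class GBoxVariant(str, Enum):
    GENERAL = "GENERAL"          # RXGRZP, X in {F,R,G}, Z hydrophobic
    A_VARIANT = "A_VARIANT"      # RXGRQ(P/S), group A
    B_VARIANT = "B_VARIANT"      # KXGR(P/H), group B (5 residues)
    C_AAVENAE = "C_AAVENAE"      # RDRRGP, Aphelenchus avenae group C


#: Token lists for the G-box variants (see :mod:`nr2dbd.motifs`).
GBOX_TOKENS: dict[str, list[str]] = {
    "GENERAL": ["R", "FRG", "G", "R", "hydrophobic", "P"],
    "A_VARIANT": ["R", "x", "G", "R", "Q", "PS"],
    "B_VARIANT": ["K", "x", "G", "R", "PH"],
    "C_AAVENAE": ["R", "D", "R", "R", "G", "P"],
}

#: Variant to try first for each 2DBD-NR group.
GROUP_GBOX_VARIANT = {"A": "A_VARIANT", "B": "B_VARIANT", "C": "C_AAVENAE"}

#: N-terminal signature sequences of parasitic platyhelminth 2DBD-NRs.
NTSS_TOKENS: dict[str, list[str]] = {
    # CNLGXKDRRP — trematode 2DBD-NRA1
    "TREMATODE_A1": list("CNLG") + ["x"] + list("KDRRP"),
    # TNDVTAMKEKTP — cestode 2DBD-NRA1
    "CESTODE_A1": list("TNDVTAMKEKTP"),
    # (S/T)PEXAFXQYQXR(M/S)EGQX — platyhelminth 2DBD-NRA2/A3
    "A2_A3": ["ST", "P", "E", "x", "A", "F", "x", "Q", "Y", "Q", "x",
              "R", "MS", "E", "G", "Q", "x"],
}


@dataclass(frozen=True)
class GBoxHit:
    """A located G-box.  ``pre_grip_len`` counts residues between the end
    of the (second) DBD and the G-box start; ``fifth_after`` is the
    residue five positions after the G-box end (None if past the
    sequence end).  Coordinates 0-based, half-open."""

    start: int
    end: int
    sequence: str
    variant: GBoxVariant
    pre_grip_len: int
    fifth_after: str | None

    def __post_init__(self) -> None:
        if self.pre_grip_len < 0:
            raise ValueError("pre_grip_len must be non-negative")
        want = 5 if self.variant == GBoxVariant.B_VARIANT else 6
        if self.end - self.start != want:
            raise ValueError("G-box span inconsistent with its variant")


@dataclass(frozen=True)
class NTSSHit:
    pattern_name: str
    start: int
    end: int
    sequence: str


def classify_architecture(dbds: Sequence[DBD], lbd_detected: bool) -> Architecture:
    """Map detected domains to the modular-architecture category.

    LBD presence decides the branch first; more than two DBDs is logged
    and classified from the first two (the report flags it as multi-DBD).
    """
    n = len(dbds)
    if n > 2:
        logger.warning("MULTI_DBD: %d DBDs detected; classifying from the first two", n)
    if lbd_detected:
        if n == 0:
            return Architecture.LBD_ONLY
        if n == 1:
            return Architecture.TYPICAL_NR
        return Architecture.TWO_DBD_NR
    return Architecture.DBD_ONLY if n >= 1 else Architecture.NOT_NR


def measure_linker(dbd1: DBD, dbd2: DBD) -> int:
    """Residues strictly between two ordered DBDs (dbd2.start − dbd1.end)."""
    if dbd2.start < dbd1.end:
        raise ValueError("DBDs overlap; cannot measure linker")
    return dbd2.start - dbd1.end


def scan_gbox(record: SequenceRecord, cte_start: int,
              group_hint: str | None = None, window: int = 30,
              z_strict: bool = True,
              variants: dict[str, list[str]] | None = None) -> GBoxHit | None:
    """Leftmost G-box starting within ``[cte_start, cte_start + window)``.

    The group hint's variant is tried first, then the GENERAL consensus
    RXGRZP; ``z_strict`` restricts Z to the hydrophobic class.
    """
    tables = dict(variants or GBOX_TOKENS)
    if not z_strict:
        tables["GENERAL"] = ["R", "FRG", "G", "R", "x", "P"]
    order: list[str] = []
    if group_hint is not None:
        hint_variant = GROUP_GBOX_VARIANT.get(group_hint, group_hint)
        if hint_variant in tables:
            order.append(hint_variant)
    if "GENERAL" not in order:
        order.append("GENERAL")
    hi = min(len(record.residues), cte_start + window)
    for name in order:
        tokens = tables[name]
        for s, e, seq in motifs.find_all(tokens, record.residues, cte_start, None):
            if s >= hi:
                break
            fifth = record.residues[e + 4] if e + 4 < len(record.residues) else None
            return GBoxHit(start=s, end=e, sequence=seq,
                           variant=GBoxVariant(name),
                           pre_grip_len=s - cte_start, fifth_after=fifth)
    return None


def tbox_present(gbox_hit: GBoxHit) -> bool:
    """True iff the pre-Grip stretch could hold a 12-residue T-box."""
    return gbox_hit.pre_grip_len >= 12


def scan_ntss(record: SequenceRecord, ab_end: int,
              patterns: dict[str, list[str]] | None = None) -> list[NTSSHit]:
    """All NTSS hits wholly inside the A/B domain ``[0, ab_end)``."""
    patterns = patterns or NTSS_TOKENS
    hits: list[NTSSHit] = []
    for name, tokens in patterns.items():
        for s, e, seq in motifs.find_all(tokens, record.residues, 0, ab_end):
            hits.append(NTSSHit(pattern_name=name, start=s, end=e, sequence=seq))
    hits.sort(key=lambda h: (h.start, h.pattern_name))
    return hits
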