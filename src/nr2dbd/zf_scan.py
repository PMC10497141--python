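"""C4 zinc-finger detection, DBD assembly and P-box / D-box extraction.

The nuclear-receptor DBD carries two C4 zinc fingers with fixed anchor
spacings: CI is C-X2-C-X13-C-X2-C and CII is C-X5-C-X9-C-X2-C.  The
P-box is the five residues that follow CI's third cysteine (so its middle
letter is CI's fourth cysteine), and the D-box is the five residues
between CII's first two cysteines (C-X5-C).  The atypical CHC2 motif
(C-X6-C-X9-H-X2-C) is scanned as a diagnostic: it occurs in some
platyhelminth NRs but never in 2DBD-NRs.

Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from .seq_io import SequenceRecord

logger = logging.getLogger(__name__)


class FingerKind(str, Enum):
    CI = "CI"
    CII = "CII"
    CHC2 = "CHC2"


#: Canonical spacer counts (residues between consecutive anchors).
SPACERS = {
    FingerKind.CI: (2, 13, 2),
    FingerKind.CII: (5, 9, 2),
    FingerKind.CHC2: (6, 9, 2),
}

#: Anchor residue expected at each of the four anchor slots.
ANCHOR_RESIDUES = {
    FingerKind.CI: "CCCC",
    FingerKind.CII: "CCCC",
    FingerKind.CHC2: "CCHC",
}


@dataclass(frozen=True)
class ZincFinger:
    """A located zinc-finger motif; ``end - start == 4 + sum(spacers)``."""

    kind: FingerKind
    start: int
    end: int
    anchor_positions: tuple[int, int, int, int]
    spacers: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.end - self.start != 4 + sum(self.spacers):
            raise ValueError("inconsistent zinc-finger geometry")


class PartialDBDError(ValueError):
    """Raised when a DBD is truncated before its P-box can be read."""


@dataclass(frozen=True)
class DBD:
    """A DNA-binding domain: CI followed by CII, with P-box and D-box.

    ``p_box`` is None when the sequence is truncated before the P-box end;
    use :func:`extract_pbox` to obtain it with a proper error.
    """

    cI: ZincFinger
    cII: ZincFinger
    start: int
    end: int
    p_box: str | None
    d_box: str
    ordinal: str | None = None  # FIRST / SECOND / ONLY

    def __post_init__(self) -> None:
        if self.cI.end > self.cII.start:
            raise ValueError("CI must precede CII in a DBD")


def _spacer_choices(kind: FingerKind, tolerance: bool) -> list[tuple[int, int, int]]:
    s1, s2, s3 = SPACERS[kind]
    if not tolerance:
        return [(s1, s2, s3)]
    # relaxation: +/-1 on the long middle spacer only (13 of CI, 9 of CII/CHC2)
    return [(s1, s2 + d, s3) for d in (-1, 0, 1)]


def scan_zinc_fingers(record: SequenceRecord,
                      kinds: Iterable[FingerKind | str] = (FingerKind.CI, FingerKind.CII),
                      spacer_tolerance: bool = False) -> list[ZincFinger]:
    """All occurrences of the requested finger kinds, sorted by start.

    Anchors must be literal C (or H at the third slot of CHC2); the
    ambiguity letter X never satisfies an anchor.  Overlapping matches of
    the same kind are all reported.
    """
    kinds = [FingerKind(k) for k in kinds]
    seq = record.residues
    hits: list[ZincFinger] = []
    for kind in kinds:
        anchors = ANCHOR_RESIDUES[kind]
        for spacers in _spacer_choices(kind, spacer_tolerance):
            length = 4 + sum(spacers)
            offsets = (0,
                       1 + spacers[0],
                       2 + spacers[0] + spacers[1],
                       3 + spacers[0] + spacers[1] + spacers[2])
            for i in range(len(seq) - length + 1):
                if all(seq[i + off] == a for off, a in zip(offsets, anchors)):
                    hits.append(ZincFinger(
                        kind=kind, start=i, end=i + length,
                        anchor_positions=tuple(i + off for off in offsets),  # type: ignore[arg-type]
                        spacers=spacers))
    hits.sort(key=lambda f: (f.start, f.kind.value, f.spacers))
    return hits


def scan_chc2(record: SequenceRecord, spacer_tolerance: bool = False) -> list[ZincFinger]:
    """Convenience scan for the atypical CHC2 motif (C-X6-C-X9-H-X2-C)."""
    return scan_zinc_fingers(record, kinds=[FingerKind.CHC2],
                             spacer_tolerance=spacer_tolerance)


def assemble_dbds(fingers: Sequence[ZincFinger], record: SequenceRecord,
                  max_inter_finger_gap: int = 30) -> list[DBD]:
    """Greedy left-to-right pairing of CI fingers with following CII fingers.

    Each CI pairs with the nearest following CII whose start lies within
    ``max_inter_finger_gap`` residues of the CI end; every finger is used
    at most once.  Unpaired fingers are simply not part of any DBD (see
    :func:`orphan_fingers`).
    """
    seq = record.residues
    cis = sorted((f for f in fingers if f.kind == FingerKind.CI), key=lambda f: f.start)
    ciis = sorted((f for f in fingers if f.kind == FingerKind.CII), key=lambda f: f.start)
    used: set[int] = set()
    dbds: list[DBD] = []
    for ci in cis:
        match = None
        for j, cii in enumerate(ciis):
            if j in used or cii.start < ci.end:
                continue
            if cii.start - ci.end <= max_inter_finger_gap:
                match = j
            break  # ciis sorted: the first following CII is the nearest
        if match is None:
            continue
        cii = ciis[match]
        used.add(match)
        a3 = ci.anchor_positions[2]
        pbox = seq[a3 + 1:a3 + 6]
        dbds.append(DBD(
            cI=ci, cII=cii, start=ci.start, end=cii.end,
            p_box=pbox if len(pbox) == 5 else None,
            d_box=seq[cii.anchor_positions[0] + 1:cii.anchor_positions[1]]))
    dbds.sort(key=lambda d: d.start)
    if len(dbds) == 1:
        dbds = [replace(dbds[0], ordinal="ONLY")]
    elif len(dbds) >= 2:
        dbds = ([replace(dbds[0], ordinal="FIRST"),
                 replace(dbds[1], ordinal="SECOND")] + dbds[2:])
    return dbds


def orphan_fingers(fingers: Sequence[ZincFinger], dbds: Sequence[DBD]) -> list[ZincFinger]:
    """Fingers reported by the scan that ended up in no DBD."""
    paired = {id(d.cI) for d in dbds} | {id(d.cII) for d in dbds}
    return [f for f in fingers if id(f) not in paired]


def extract_pbox(dbd: DBD) -> str:
    """The P-box: five residues following CI's third cysteine."""
    if dbd.p_box is None:
        raise PartialDBDError("DBD truncated before the P-box end")
    return dbd.p_box


def extract_dbox(dbd: DBD) -> str:
    """The D-box: the five residues between CII's first two cysteines."""
    if len(dbd.d_box) != 5:
        raise PartialDBDError("malformed D-box")
    return dbd.d_box
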