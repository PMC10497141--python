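"""Ligand-binding-domain signatures: Ti, AF2-AD core and dimerization class.

The LBD is detected through its 20-residue NR-superfamily signature (Ti)
between helices H3 and H5:

    (F,W,Y)(A,S,I)(K,R,E,G)xxxx(F,L)xx(L,V,I)xxx(D,S)(Q,K)xx(L,V)(L,I,F)

The AF2-AD core at the LBD C-terminus has the common consensus ΦΦxEΦΦ
(Φ hydrophobic) with group variants ΦΦx(E,Q,R)ΦΦ (group A), ΦΦx(E,K)Φh
(group B, h hydrophilic) and xxΦΦΦΦ (Caenorhabditis brenneri group C).

Dimerization class follows the Brelivet residue sets on a user-supplied
LBD alignment row: class I NRs carry E5, E50, KR55 and RK93; class II
carry ED42, E50, R62 and HRK90.  RK93 is strictly class I and R62
strictly class II, so those two discriminate the call; 2DBD-NRs show
E50 and RK93 but lack KR55.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from . import motifs
from .motifs import HYDROPHILIC, HYDROPHOBIC, NEUTRAL
from .seq_io import SequenceRecord


@dataclass(frozen=True)
class ResidueClasses:
    """Hydrophilic / neutral / hydrophobic partition of the alphabet."""

    hydrophilic: frozenset[str] = HYDROPHILIC
    neutral: frozenset[str] = NEUTRAL
    hydrophobic: frozenset[str] = HYDROPHOBIC

    def __post_init__(self) -> None:
        motifs.assert_partition((self.hydrophilic, self.neutral, self.hydrophobic))


#: Token list of the 20-residue Ti signature.
TI_TOKENS: list[str] = [
    "FWY", "ASI", "KREG", "x", "x", "x", "x", "FL", "x", "x",
    "LVI", "x", "x", "x", "DS", "QK", "x", "x", "LV", "LIF",
]


class AF2Variant(str, Enum):
    GENERAL = "GENERAL"
    A = "A"
    B = "B"
    C_CBRENNERI = "C_CBRENNERI"


AF2_TOKENS: dict[str, list[str]] = {
    "GENERAL": ["hydrophobic", "hydrophobic", "x", "E", "hydrophobic", "hydrophobic"],
    "A": ["hydrophobic", "hydrophobic", "x", "EQR", "hydrophobic", "hydrophobic"],
    "B": ["hydrophobic", "hydrophobic", "x", "EK", "hydrophobic", "hydrophilic"],
    "C_CBRENNERI": ["x", "x", "hydrophobic", "hydrophobic", "hydrophobic", "hydrophobic"],
}

GROUP_AF2_VARIANT = {"A": "A", "B": "B", "C": "C_CBRENNERI"}


@dataclass(frozen=True)
class TiHit:
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != 20:
            raise ValueError("Ti hit must span exactly 20 residues")


@dataclass(frozen=True)
class AF2Hit:
    start: int
    end: int
    sequence: str
    variant: AF2Variant

    def __post_init__(self) -> None:
        if self.end - self.start != 6:
            raise ValueError("AF2 hit must span exactly 6 residues")


class DimerClass(str, Enum):
    CLASS_I = "CLASS_I"
    CLASS_II = "CLASS_II"
    AMBIGUOUS = "AMBIGUOUS"
    NONE = "NONE"


#: Allowed residues at each conserved marker (Brelivet numbering).
MARKER_SETS: dict[str, frozenset[str]] = {
    "E5": frozenset("E"),
    "E50": frozenset("E"),
    "KR55": frozenset("KR"),
    "RK93": frozenset("RK"),
    "ED42": frozenset("ED"),
    "R62": frozenset("R"),
    "HRK90": frozenset("HRK"),
}


@dataclass(frozen=True)
class DimerClassProfile:
    """Marker presence flags and the class call they induce."""

    markers: Mapping[str, bool]
    call: DimerClass

    def __post_init__(self) -> None:
        if self.call == DimerClass.CLASS_I and (
                not self.markers.get("RK93") or self.markers.get("R62")):
            raise ValueError("CLASS_I call requires RK93 present and R62 absent")


def scan_ti(record: SequenceRecord, search_start: int = 0,
            tokens: Sequence[str] = TI_TOKENS) -> list[TiHit]:
    """All Ti windows in ``[search_start, len)``, left to right."""
    return [TiHit(start=s, end=e, sequence=seq)
            for s, e, seq in motifs.find_all(tokens, record.residues, search_start)]


def detect_lbd(record: SequenceRecord, search_start: int = 0) -> bool:
    """LBD presence proxy: at least one Ti hit after ``search_start``."""
    return bool(scan_ti(record, search_start))


def scan_af2(record: SequenceRecord, from_pos: int = 0,
             group_hint: str | None = None,
             variants: dict[str, list[str]] | None = None) -> AF2Hit | None:
    """AF2-AD core hit nearest the C-terminus, or None.

    The group hint's variant is tried first, falling back to the GENERAL
    ΦΦxEΦΦ consensus.
    """
    tables = variants or AF2_TOKENS
    order: list[str] = []
    if group_hint is not None:
        hint = GROUP_AF2_VARIANT.get(group_hint, group_hint)
        if hint in tables:
            order.append(hint)
    if "GENERAL" not in order:
        order.append("GENERAL")
    for name in order:
        hits = list(motifs.find_all(tables[name], record.residues, from_pos))
        if hits:
            s, e, seq = hits[-1]
            return AF2Hit(start=s, end=e, sequence=seq, variant=AF2Variant(name))
    return None


def dimer_class_profile(aligned_lbd_row: str,
                        column_map: Mapping[str, int],
                        marker_sets: Mapping[str, frozenset[str]] | None = None
                        ) -> DimerClassProfile:
    """Class I / class II marker profile of one LBD alignment row.

    ``column_map`` maps marker labels to 0-based alignment columns (the
    Brelivet numbering presumes variable inserts are deleted, so the map
    is supplied by the user/config).  A gap ('-') at a column counts as
    absent.  A column beyond the row length is an error.
    """
    sets = dict(MARKER_SETS if marker_sets is None else marker_sets)
    flags: dict[str, bool] = {}
    for label, col in column_map.items():
        if label not in sets:
            raise ValueError(f"unknown marker label {label!r}")
        if col >= len(aligned_lbd_row) or col < 0:
            raise ValueError(
                f"column {col} for marker {label} beyond alignment row length "
                f"{len(aligned_lbd_row)}")
        flags[label] = aligned_lbd_row[col] in sets[label]
    rk93 = flags.get("RK93", False)
    r62 = flags.get("R62", False)
    if rk93 and not r62:
        call = DimerClass.CLASS_I
    elif r62 and not rk93:
        call = DimerClass.CLASS_II
    elif rk93 and r62:
        call = DimerClass.AMBIGUOUS
    else:
        call = DimerClass.NONE
    return DimerClassProfile(markers=flags, call=call)
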