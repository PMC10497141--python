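"""P-P module construction, group assignment and 2DBD-NR nomenclature.

The P-P module is the ordered pair of P-boxes from the first and second
DBD, written with the display C restored ("CEACKK-CEGCKG").  Four exact
signatures are group-diagnostic:

    CEACKK-CEGCKG  -> A   (most 2DBD-NRA)
    CEACKK-CEACKG  -> A   (Rotifera NR7A3/NR7A5 members)
    CLPCKS-CEGCKK  -> B   (Mollusca/Annelida/Brachiopoda/Phoronida)
    CEACKS-CEGCKG  -> B   (Echinodermata)

Group C (Nematoda) has a highly variable P-P module, so it is assigned
by taxon gating when no signature is within the mismatch budget.

Names follow the proposed nomenclature: species code + "2DBD-NR" +
group letter + gene numeral + optional lowercase variant letter,
e.g. "Bc2DBD-NRA1a".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .zf_scan import DBD, extract_pbox

#: Rendered P-P signature -> group letter.
PP_SIGNATURES: dict[str, str] = {
    "CEACKK-CEGCKG": "A",
    "CEACKK-CEACKG": "A",
    "CLPCKS-CEGCKK": "B",
    "CEACKS-CEGCKG": "B",
}

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class PPModule:
    first: str
    second: str

    def __post_init__(self) -> None:
        if len(self.first) != 5 or len(self.second) != 5:
            raise ValueError("P-boxes must be 5 residues")

    @property
    def rendered(self) -> str:
        return f"C{self.first}-C{self.second}"

    @classmethod
    def from_rendered(cls, rendered: str) -> "PPModule":
        if len(rendered) != 13 or rendered[6] != "-" or rendered[0] != "C" or rendered[7] != "C":
            raise ValueError(f"malformed P-P module string {rendered!r}")
        return cls(first=rendered[1:6], second=rendered[8:13])


@dataclass(frozen=True)
class GroupCall:
    group: str                       # A / B / C / UNCLASSIFIED
    matched_signature: str | None    # rendered signature, or None
    distance: int                    # mismatches to the nearest signature

    def __post_init__(self) -> None:
        # distance 0 means an exact signature match, which must be recorded
        if self.distance == 0 and self.matched_signature is None:
            raise ValueError("distance 0 requires a matched signature")


@dataclass(frozen=True)
class NomenclatureName:
    species_code: str
    group_letter: str
    gene_number: int
    variant_letter: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= len(self.species_code) <= 4) or not self.species_code.isalpha():
            raise ValueError("species code must be 1-4 letters")
        if self.group_letter not in "ABC":
            raise ValueError("group letter must be A, B or C")
        if self.gene_number < 1:
            raise ValueError("gene number must be positive")
        if self.variant_letter is not None and (
                len(self.variant_letter) != 1 or not self.variant_letter.islower()):
            raise ValueError("variant letter must be one lowercase letter")

    @property
    def rendered(self) -> str:
        return (f"{self.species_code}2DBD-NR{self.group_letter}"
                f"{self.gene_number}{self.variant_letter or ''}")


_NAME_RE = re.compile(r"^([A-Za-z]{1,4})2DBD-NR([ABC])(\d+)([a-z]?)$")


def parse_name(rendered: str) -> NomenclatureName:
    """Inverse of ``NomenclatureName.rendered``."""
    m = _NAME_RE.match(rendered)
    if not m:
        raise ValueError(f"not a 2DBD-NR nomenclature name: {rendered!r}")
    code, group, num, var = m.groups()
    return NomenclatureName(species_code=code, group_letter=group,
                            gene_number=int(num), variant_letter=var or None)


def pp_module(dbd1: DBD, dbd2: DBD) -> PPModule:
    """P-P module from two position-ordered DBDs."""
    if dbd1.start > dbd2.start:
        raise ValueError("DBDs must be ordered by position")
    return PPModule(first=extract_pbox(dbd1), second=extract_pbox(dbd2))


def _hamming10(ppm: PPModule, signature: str) -> int:
    sig = PPModule.from_rendered(signature)
    return (sum(a != b for a, b in zip(ppm.first, sig.first))
            + sum(a != b for a, b in zip(ppm.second, sig.second)))


def assign_group(ppm: PPModule, max_mismatch: int = 1,
                 taxon: str | None = None,
                 signatures: Mapping[str, str] | None = None) -> GroupCall:
    """Assign group A/B/C from the P-P module.

    Exact signature match wins; otherwise the nearest signature by total
    Hamming distance over the 10 P-box letters is used when within
    ``max_mismatch`` (distance ties -> UNCLASSIFIED).  Beyond the budget
    the call is C for Nematoda (whose P-P module is highly variable) and
    UNCLASSIFIED otherwise.
    """
    sigs = dict(signatures or PP_SIGNATURES)
    dists = {sig: _hamming10(ppm, sig) for sig in sigs}
    best = min(dists.values())
    nearest = [sig for sig, d in dists.items() if d == best]
    if best == 0:
        sig = nearest[0]
        return GroupCall(group=sigs[sig], matched_signature=sig, distance=0)
    if best <= max_mismatch:
        if len(nearest) > 1:
            return GroupCall(group=UNCLASSIFIED, matched_signature=None, distance=best)
        sig = nearest[0]
        return GroupCall(group=sigs[sig], matched_signature=sig, distance=best)
    if taxon is not None and taxon.strip().lower() == "nematoda":
        return GroupCall(group="C", matched_signature=None, distance=best)
    return GroupCall(group=UNCLASSIFIED, matched_signature=None, distance=best)


def assign_name(species_code: str, group_call: GroupCall, gene_number: int,
                variant_letter: str | None = None) -> NomenclatureName:
    """Construct a nomenclature name for a classified record."""
    if group_call.group not in "ABC" or len(group_call.group) != 1:
        raise ValueError("cannot name an UNCLASSIFIED record")
    return NomenclatureName(species_code=species_code,
                            group_letter=group_call.group,
                            gene_number=gene_number,
                            variant_letter=variant_letter)


def number_genes(group_members_ordered: Sequence[tuple[str, str]]
                 ) -> dict[str, tuple[int, str | None]]:
    """Assign gene numbers and variant letters within one species+group.

    Input is an ordered list of ``(member_id, subgroup_identity)``; the
    ordering usually comes from a tree (else a documented default).
    Distinct subgroup identities get successive integers from 1; members
    sharing a subgroup get the same integer with variants a, b, c… in
    input order (no variant letter when a subgroup has a single member).
    """
    subgroup_number: dict[str, int] = {}
    by_subgroup: dict[str, list[str]] = {}
    for member, sub in group_members_ordered:
        if sub not in subgroup_number:
            subgroup_number[sub] = len(subgroup_number) + 1
            by_subgroup[sub] = []
        by_subgroup[sub].append(member)
    out: dict[str, tuple[int, str | None]] = {}
    for sub, members in by_subgroup.items():
        num = subgroup_number[sub]
        if len(members) == 1:
            out[members[0]] = (num, None)
        else:
            for i, member in enumerate(members):
                out[member] = (num, chr(ord("a") + i))
    return out
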