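"""Seeded generator of synthetic NR protein panels with ground truth.

Every architectural and motif feature the scanners must recover is
emitted by construction: the A/B domain (optionally ending in an NTSS),
two tandem DBDs built from canonical CI/CII zinc fingers with
configurable P-boxes and D-boxes, a linker of configurable length
(default uniform in 17–22), a CTE with pre-Grip + G-box (+ the conserved
H five residues after it), and an LBD carrying a Ti instance, class
marker residues and an AF2-AD core.

Filler residues are drawn from the neutral class minus C and H
({S,G,T,A,P}), so no spurious zinc-finger anchors, Ti starts or G-box
starts can arise — a deliberate simplification relative to real
sequences (see the methods note).  ``hard_mode`` widens the filler to
all residues except C and H, rejecting draws that collide with a
scanner motif.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .architecture import NTSS_TOKENS
from .lbd import TI_TOKENS
from .motifs import AMINO_ACIDS, token_alternatives
from .seq_io import Architecture, SequenceRecord

#: Neutral-class filler alphabet (C and H excluded to avoid spurious anchors).
FILLER = "SGTAP"

#: Default LBD column of each dimerization-class marker (synthetic
#: sequences are emitted ungapped, so LBD offsets double as alignment
#: columns).
DEFAULT_COLUMN_MAP: dict[str, int] = {
    "E5": 5, "ED42": 42, "E50": 50, "KR55": 55,
    "R62": 62, "HRK90": 90, "RK93": 93,
}

#: Concrete AF2-AD core instances used for embedding, per variant.
AF2_INSTANCES = {
    "GENERAL": "LLGELL",
    "A": "LLDELL",
    "B": "IVTKVR",
    "C_CBRENNERI": "GGLLVI",
}

#: Default G-box string per group (A/B/C variants from the group tables).
GROUP_GBOX = {"A": "RFGRQP", "B": "KSGRP", "C": "RDRRGP", None: "RFGRLP"}

#: The five P-P module templates of the panel plus per-group settings.
GROUP_TEMPLATES: dict[str, dict] = {
    "A1": dict(group="A", pbox1="EACKK", pbox2="EGCKG"),
    "A2": dict(group="A", pbox1="EACKK", pbox2="EACKG"),
    "B1": dict(group="B", pbox1="LPCKS", pbox2="EGCKK"),
    "B2": dict(group="B", pbox1="EACKS", pbox2="EGCKG"),
    # group C: highly variable P-P module, Aphelenchus avenae style
    # (G-box RDRRGP, pre-Grip 8, Ti present, AF2 absent), Nematoda taxon
    "C1": dict(group="C", pbox1="KGCNV", pbox2="DSCRT", taxon="Nematoda",
               af2=None),
}


@dataclass
class GenParams:
    """Generator parameters; None means the per-group default applies."""

    architecture: Architecture = Architecture.TWO_DBD_NR
    group: str | None = None                # A / B / C template or None
    pbox1: str = "EACKK"
    pbox2: str = "EGCKG"
    dbox1: str = "KYEGA"
    dbox2: str = "NSGAK"
    linker_len: int | None = None           # default: uniform in [17, 22]
    pre_grip_len: int | None = None         # default 5; 8 for group C
    gbox: str | None = None                 # default per group variant
    post_gbox_fifth: str | None = None      # default 'H' for group A
    ntss: str | None = None                 # NTSS pattern name or None
    ti: bool = True
    af2: str | None | object = "default"    # AF2 variant name, None = omit
    class_markers: str | None = "CLASS_I"   # CLASS_I / CLASS_II / None
    ab_len: int = 40
    intra_dbd_gap: int = 10
    hinge_len: int = 25
    lbd_len: int = 110
    ti_offset: int = 10                     # Ti start within the LBD
    taxon: str | None = None
    hard_mode: bool = False                 # full-alphabet filler (minus C/H)
    seed: int = 0

    def resolved(self) -> "GenParams":
        p = GenParams(**asdict(self))
        if p.linker_len is None:
            p.linker_len = -1               # drawn at generation time
        if p.pre_grip_len is None:
            p.pre_grip_len = 8 if p.group == "C" else 5
        if p.gbox is None:
            p.gbox = GROUP_GBOX.get(p.group, GROUP_GBOX[None])
        if p.post_gbox_fifth is None and p.group == "A":
            p.post_gbox_fifth = "H"
        if p.af2 == "default":
            p.af2 = {"A": "A", "B": "B", "C": "C_CBRENNERI"}.get(p.group, "GENERAL")
        return p


@dataclass
class TruthRecord:
    """Ground truth for one generated sequence (coordinates 0-based)."""

    seq_id: str
    architecture: Architecture
    group: str | None = None
    taxon: str | None = None
    pbox1: str | None = None
    dbox1: str | None = None
    pbox2: str | None = None
    dbox2: str | None = None
    pp_module: str | None = None
    linker_len: int | None = None
    pre_grip_len: int | None = None
    gbox: str | None = None
    gbox_variant: str | None = None
    gbox_span: tuple[int, int] | None = None
    post_gbox_fifth: str | None = None
    tbox_present: bool | None = None
    ntss_pattern: str | None = None
    ntss_seq: str | None = None
    ntss_span: tuple[int, int] | None = None
    ti_seq: str | None = None
    ti_span: tuple[int, int] | None = None
    af2_variant: str | None = None
    af2_seq: str | None = None
    class_markers: str | None = None
    lbd_start: int | None = None
    dbd1_span: tuple[int, int] | None = None
    dbd2_span: tuple[int, int] | None = None


#: Hard-mode filler: every residue except the anchor letters C and H.
HARD_FILLER = "".join(c for c in AMINO_ACIDS if c not in "CH")


def _fill(rng: np.random.Generator, n: int, hard_mode: bool = False) -> str:
    if n <= 0:
        return ""
    alphabet = HARD_FILLER if hard_mode else FILLER
    return "".join(rng.choice(list(alphabet), size=n))


def _instantiate(tokens: Sequence[str], rng: np.random.Generator) -> str:
    """One concrete string matching a token motif (never C/H at choices)."""
    out = []
    for tok in tokens:
        alts = token_alternatives(tok)
        if alts is None:
            out.append(str(rng.choice(list(FILLER))))
        else:
            safe = [c for c in alts if c not in "CH"] or list(alts)
            out.append(str(rng.choice(safe)))
    return "".join(out)


#: Seed of the per-group conserved DBD core stream.
GROUP_CORE_SEEDS = {"A": 11, "B": 12, "C": 13}


def _dbd_block(pbox: str, dbox: str, rng: np.random.Generator,
               intra_gap: int,
               core_rng: np.random.Generator | None = None) -> tuple[str, int]:
    """Sequence of one DBD (CI..CII) plus trailing P-box residues.

    Returns (block, dbd_len) where dbd_len is CI.start..CII.end; the
    block itself additionally carries nothing beyond CII.  The P-box tail
    (pbox[3:5]) occupies the first two residues after CI inside the
    intra-DBD gap.
    """
    if len(pbox) != 5 or pbox[2] != "C":
        raise ValueError(f"P-box {pbox!r} must be 5 residues with C at index 2")
    if len(dbox) != 5 or "C" in dbox or "H" in dbox:
        raise ValueError(f"D-box {dbox!r} must be 5 residues without C or H")
    if intra_gap < 2:
        raise ValueError("intra-DBD gap must hold the P-box tail (>= 2)")
    core = core_rng if core_rng is not None else rng
    # CI anchors at relative 0, 3, 17, 20; the X2 spacer between anchors
    # 3 and 4 holds pbox[0:2], so the P-box reads pbox[0] pbox[1] C(=anchor4)
    # pbox[3] pbox[4].  Spacer residues come from the group's conserved
    # core stream so that group members share their DBD internals, as
    # real 2DBD-NR groups do.
    ci = ("C" + _fill(core, 2) + "C" + _fill(core, 13)
          + "C" + pbox[0] + pbox[1] + "C")
    spacer = pbox[3] + pbox[4] + _fill(core, intra_gap - 2)
    cii = "C" + dbox + "C" + _fill(core, 9) + "C" + _fill(core, 2) + "C"
    block = ci + spacer + cii
    return block, len(block)


def _lbd_block(params: GenParams, rng: np.random.Generator
               ) -> tuple[str, dict]:
    """The LBD: filler with Ti, class markers and AF2 laid in."""
    n = params.lbd_len
    if n < max(DEFAULT_COLUMN_MAP.values()) + 12:
        raise ValueError("lbd_len too short for the default marker columns")
    lbd = list(_fill(rng, n, params.hard_mode))
    info: dict = {}
    if params.ti:
        ti = _instantiate(TI_TOKENS, rng)
        off = params.ti_offset
        lbd[off:off + 20] = ti
        info["ti_seq"] = ti
        info["ti_offset"] = off
    if params.class_markers == "CLASS_I":
        lbd[DEFAULT_COLUMN_MAP["E5"]] = "E"
        lbd[DEFAULT_COLUMN_MAP["E50"]] = "E"
        lbd[DEFAULT_COLUMN_MAP["RK93"]] = str(rng.choice(["K", "R"]))
    elif params.class_markers == "CLASS_II":
        lbd[DEFAULT_COLUMN_MAP["ED42"]] = str(rng.choice(["E", "D"]))
        lbd[DEFAULT_COLUMN_MAP["E50"]] = "E"
        lbd[DEFAULT_COLUMN_MAP["R62"]] = "R"
        lbd[DEFAULT_COLUMN_MAP["HRK90"]] = str(rng.choice(["H", "R", "K"]))
    if params.af2 is not None:
        af2 = AF2_INSTANCES[str(params.af2)]
        lbd[n - 6:n] = af2
        info["af2_seq"] = af2
        info["af2_variant"] = str(params.af2)
    return "".join(lbd), info


def _generate_once(p: GenParams, rng: np.random.Generator,
                   seq_id: str) -> tuple[SequenceRecord, TruthRecord]:
    truth = TruthRecord(seq_id=seq_id, architecture=p.architecture,
                        group=p.group, taxon=p.taxon,
                        class_markers=p.class_markers)

    if p.architecture == Architecture.NOT_NR:
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=200))
        return SequenceRecord(id=seq_id, residues=seq), truth

    parts: list[str] = []

    def cursor() -> int:
        return sum(len(s) for s in parts)

    # --- A/B domain, optionally ending in an NTSS instance
    if p.ntss is not None:
        inst = _instantiate(NTSS_TOKENS[p.ntss], rng)
        parts.append(_fill(rng, p.ab_len - len(inst), p.hard_mode))
        truth.ntss_pattern = p.ntss
        truth.ntss_seq = inst
        truth.ntss_span = (cursor(), cursor() + len(inst))
        parts.append(inst)
    else:
        parts.append(_fill(rng, p.ab_len, p.hard_mode))

    if p.architecture == Architecture.LBD_ONLY:
        lbd_start = cursor()
        block, info = _lbd_block(p, rng)
        parts.append(block)
        truth.lbd_start = lbd_start
        if "ti_seq" in info:
            truth.ti_seq = info["ti_seq"]
            truth.ti_span = (lbd_start + info["ti_offset"],
                             lbd_start + info["ti_offset"] + 20)
        truth.af2_variant = info.get("af2_variant")
        truth.af2_seq = info.get("af2_seq")
        return SequenceRecord(id=seq_id, residues="".join(parts)), truth

    # --- first DBD (group members share a conserved DBD core stream)
    core_rng = (np.random.default_rng(GROUP_CORE_SEEDS[p.group])
                if p.group in GROUP_CORE_SEEDS else None)
    d1_start = cursor()
    block, d1_len = _dbd_block(p.pbox1, p.dbox1, rng, p.intra_dbd_gap, core_rng)
    parts.append(block)
    truth.dbd1_span = (d1_start, d1_start + d1_len)
    truth.pbox1, truth.dbox1 = p.pbox1, p.dbox1

    two_dbd = p.architecture == Architecture.TWO_DBD_NR
    if two_dbd:
        linker = (int(rng.integers(17, 23)) if p.linker_len == -1
                  else p.linker_len)
        parts.append(_fill(rng, linker, p.hard_mode))
        truth.linker_len = linker
        d2_start = cursor()
        block, d2_len = _dbd_block(p.pbox2, p.dbox2, rng, p.intra_dbd_gap, core_rng)
        parts.append(block)
        truth.dbd2_span = (d2_start, d2_start + d2_len)
        truth.pbox2, truth.dbox2 = p.pbox2, p.dbox2
        truth.pp_module = f"C{p.pbox1}-C{p.pbox2}"

    # --- CTE: pre-Grip + G-box + post-G-box residues
    parts.append(_fill(rng, p.pre_grip_len, p.hard_mode))
    g_start = cursor()
    parts.append(p.gbox)
    truth.gbox = p.gbox
    truth.gbox_span = (g_start, g_start + len(p.gbox))
    truth.pre_grip_len = p.pre_grip_len
    truth.tbox_present = p.pre_grip_len >= 12
    variant_of = {"RFGRQP": "A_VARIANT", "KSGRP": "B_VARIANT",
                  "RDRRGP": "C_AAVENAE"}
    truth.gbox_variant = variant_of.get(p.gbox, "GENERAL")
    if p.post_gbox_fifth is not None:
        parts.append(_fill(rng, 4, p.hard_mode) + p.post_gbox_fifth
                     + _fill(rng, 5, p.hard_mode))
        truth.post_gbox_fifth = p.post_gbox_fifth
    else:
        parts.append(_fill(rng, 10, p.hard_mode))

    if p.architecture == Architecture.DBD_ONLY:
        parts.append(_fill(rng, 10, p.hard_mode))
        return SequenceRecord(id=seq_id, residues="".join(parts)), truth

    # --- hinge + LBD
    parts.append(_fill(rng, p.hinge_len, p.hard_mode))
    lbd_start = cursor()
    block, info = _lbd_block(p, rng)
    parts.append(block)
    truth.lbd_start = lbd_start
    if "ti_seq" in info:
        truth.ti_seq = info["ti_seq"]
        truth.ti_span = (lbd_start + info["ti_offset"],
                         lbd_start + info["ti_offset"] + 20)
    truth.af2_variant = info.get("af2_variant")
    truth.af2_seq = info.get("af2_seq")
    return SequenceRecord(id=seq_id, residues="".join(parts)), truth


def _collision_free(record: SequenceRecord, truth: TruthRecord) -> bool:
    """True iff scanning recovers exactly the embedded motifs — used to
    reject hard-mode draws whose widened filler created spurious hits."""
    from .architecture import scan_gbox, scan_ntss
    from .lbd import scan_ti
    from .zf_scan import FingerKind, assemble_dbds, scan_zinc_fingers

    fingers = scan_zinc_fingers(record)
    dbds = assemble_dbds(fingers, record)
    expected_spans = [s for s in (truth.dbd1_span, truth.dbd2_span)
                      if s is not None]
    if [(d.start, d.end) for d in dbds] != expected_spans:
        return False
    if len(fingers) != 2 * len(expected_spans):
        return False
    ti_start = dbds[-1].end if dbds else 0
    ti = scan_ti(record, ti_start)
    if [(h.start, h.end) for h in ti] != ([truth.ti_span] if truth.ti_span else []):
        return False
    if truth.gbox_span is not None:
        hit = scan_gbox(record, dbds[-1].end,
                        group_hint=truth.group)
        if hit is None or (hit.start, hit.end) != truth.gbox_span:
            return False
    if dbds:
        n_ntss = len(scan_ntss(record, dbds[0].start))
        if n_ntss != (1 if truth.ntss_pattern else 0):
            return False
    return True


def make_sequence(params: GenParams,
                  rng: np.random.Generator | None = None,
                  seq_id: str = "synth") -> tuple[SequenceRecord, TruthRecord]:
    """Assemble one synthetic protein and its ground truth.

    Deterministic for a fixed seed / rng state.  In ``hard_mode`` the
    filler alphabet widens to all residues except C and H, and draws
    whose filler collides with a scanner motif are rejected and redrawn.
    """
    p = params.resolved()
    if rng is None:
        rng = np.random.default_rng(p.seed)
    attempts = 25 if p.hard_mode else 1
    for _ in range(attempts):
        record, truth = _generate_once(p, rng, seq_id)
        if not p.hard_mode or truth.architecture == Architecture.NOT_NR \
                or _collision_free(record, truth):
            return record, truth
    raise RuntimeError(
        f"hard-mode generation kept colliding for {seq_id} after {attempts} tries")


def _chc2_decoy(rng: np.random.Generator, seq_id: str
                ) -> tuple[SequenceRecord, TruthRecord]:
    """A protein carrying one CHC2 motif (C-X6-C-X9-H-X2-C), no DBD."""
    seq = (_fill(rng, 50)
           + "C" + _fill(rng, 6) + "C" + _fill(rng, 9) + "H" + _fill(rng, 2) + "C"
           + _fill(rng, 50))
    truth = TruthRecord(seq_id=seq_id, architecture=Architecture.NOT_NR)
    return SequenceRecord(id=seq_id, residues=seq), truth


def make_panel(n_per_template: int, seed: int
               ) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """A full panel: n copies of each of the five P-P templates plus
    n copies of each decoy (single-DBD typical NR, LBD-only, CHC2
    protein, random protein).  n=1 gives 5 positives + 4 decoys.
    """
    if n_per_template < 1:
        raise ValueError("n_per_template must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []

    for i in range(n_per_template):
        for tmpl, spec in GROUP_TEMPLATES.items():
            params = GenParams(architecture=Architecture.TWO_DBD_NR,
                               **{k: v for k, v in spec.items()})
            rec, truth = make_sequence(params, rng=rng,
                                       seq_id=f"{tmpl}_{i:03d}")
            records.append(rec)
            truths.append(truth)
        for decoy, arch in (("typical", Architecture.TYPICAL_NR),
                            ("lbdonly", Architecture.LBD_ONLY),
                            ("random", Architecture.NOT_NR)):
            params = GenParams(architecture=arch, group=None)
            rec, truth = make_sequence(params, rng=rng,
                                       seq_id=f"{decoy}_{i:03d}")
            records.append(rec)
            truths.append(truth)
        rec, truth = _chc2_decoy(rng, f"chc2_{i:03d}")
        records.append(rec)
        truths.append(truth)
    return records, truths


def truth_table_rows(truths: Sequence[TruthRecord]) -> list[dict[str, str]]:
    """Flatten truth records to TSV-ready string dicts."""
    rows = []
    for t in truths:
        row = {}
        for k, v in asdict(t).items():
            if v is None:
                row[k] = ""
            elif isinstance(v, tuple):
                row[k] = f"{v[0]}-{v[1]}"
            elif isinstance(v, Architecture):
                row[k] = v.value
            else:
                row[k] = str(v)
        rows.append(row)
    return rows
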