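"""Independent brute-force oracles, deliberately written without reusing
the package's scanning code paths."""

from __future__ import annotations

ANCHOR_SPEC = {
    "CI": ("CCCC", (2, 13, 2)),
    "CII": ("CCCC", (5, 9, 2)),
    "CHC2": ("CCHC", (6, 9, 2)),
}


def brute_force_fingers(seq: str, kind: str) -> list[tuple[int, int]]:
    """Every (start, end) where the finger's anchor geometry holds,
    checked residue by residue at every start position."""
    anchors, spacers = ANCHOR_SPEC[kind]
    length = 4 + sum(spacers)
    hits = []
    for i in range(len(seq)):
        if i + length > len(seq):
            break
        pos = i
        ok = True
        for k in range(4):
            if seq[pos] != anchors[k]:
                ok = False
                break
            if k < 3:
                pos += spacers[k] + 1
        if ok:
            hits.append((i, i + length))
    return hits


def brute_force_windows(seq: str, position_sets: list[str | None]) -> list[int]:
    """Start positions where every consensus position is satisfied;
    ``None`` entries are wildcards.  Checked per window, per position."""
    n = len(position_sets)
    starts = []
    for i in range(len(seq) - n + 1):
        for off, allowed in enumerate(position_sets):
            if allowed is not None and seq[i + off] not in allowed:
                break
        else:
            starts.append(i)
    return starts


def brute_force_affine_score(a: str, b: str, score, gap_open: float,
                             gap_extend: float) -> float:
    """Optimal global alignment score by exhaustive enumeration of all
    monotone alignments.  The first residue of every gap costs
    ``gap_open``, each further residue ``gap_extend``; switching the
    gapped sequence reopens.  Only feasible for tiny sequences."""
    best = [float("-inf")]

    def rec(i: int, j: int, acc: float, last: str | None) -> None:
        if i == len(a) and j == len(b):
            if acc > best[0]:
                best[0] = acc
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + score(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, acc - (gap_extend if last == "D" else gap_open), "D")
        if j < len(b):
            rec(i, j + 1, acc - (gap_extend if last == "I" else gap_open), "I")

    rec(0, 0, 0.0, None)
    return best[0]
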