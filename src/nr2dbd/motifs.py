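"""Degenerate-consensus machinery shared by the motif scanners.

A motif is written as a list of *tokens*, one per consensus position:

* a string of amino-acid letters — the allowed alternatives at that
  position (a single letter means an invariant residue);
* ``"x"`` — any residue (including the ambiguity letter ``X``);
* ``"hydrophobic"`` / ``"hydrophilic"`` / ``"neutral"`` — one of the three
  physicochemical residue classes (Φ, h and the neutral class).

Tokens compile to a regular expression that is applied through a
lookahead so overlapping occurrences are all reported.  The ambiguity
letter ``X`` found in input sequences deliberately matches only the
wildcard token, never a fixed position or a residue class.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Sequence

#: Residue classes used throughout: hydrophilic / neutral / hydrophobic.
HYDROPHILIC = frozenset("RKDENQ")
NEUTRAL = frozenset("SGHTAP")
HYDROPHOBIC = frozenset("YVMCLFIW")

CLASS_NAMES = {
    "hydrophilic": HYDROPHILIC,
    "neutral": NEUTRAL,
    "hydrophobic": HYDROPHOBIC,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def token_alternatives(token: str) -> str | None:
    """Return the letters a token allows, or ``None`` for the wildcard."""
    if token == "x":
        return None
    if token in CLASS_NAMES:
        return "".join(sorted(CLASS_NAMES[token]))
    if not token or not all(c in AMINO_ACIDS for c in token):
        raise ValueError(f"bad motif token {token!r}")
    return token


def compile_tokens(tokens: Sequence[str]) -> re.Pattern[str]:
    """Compile a token list into an overlap-reporting regex."""
    parts = []
    for tok in tokens:
        alts = token_alternatives(tok)
        if alts is None:
            parts.append(".")
        elif len(alts) == 1:
            parts.append(alts)
        else:
            parts.append(f"[{alts}]")
    return re.compile(f"(?=({''.join(parts)}))")


def find_all(tokens: Sequence[str], residues: str,
             start: int = 0, end: int | None = None) -> Iterator[tuple[int, int, str]]:
    """Yield ``(start, end, matched)`` for every (overlapping) occurrence.

    Matches must start in ``[start, end)`` but may extend past ``end`` only
    if ``end`` is None; with an explicit ``end`` the whole match must fit.
    """
    pat = compile_tokens(tokens)
    hi = len(residues) if end is None else end
    for m in pat.finditer(residues, start):
        s = m.start()
        if s >= hi:
            break
        e = s + len(tokens)
        if e > hi:
            continue
        yield s, e, m.group(1)


def matches_at(tokens: Sequence[str], residues: str, pos: int) -> bool:
    """Position-wise check (no regex) that the motif occurs at ``pos``."""
    if pos < 0 or pos + len(tokens) > len(residues):
        return False
    for off, tok in enumerate(tokens):
        alts = token_alternatives(tok)
        if alts is not None and residues[pos + off] not in alts:
            return False
    return True


def parse_token_string(spec: str) -> list[str]:
    """Parse a comma-separated token string (config-file form)."""
    return [t.strip() for t in spec.split(",") if t.strip()]


def assert_partition(classes: Iterable[frozenset[str]] = (HYDROPHILIC, NEUTRAL, HYDROPHOBIC)) -> None:
    """The three residue classes must partition the 20-letter alphabet."""
    union: set[str] = set()
    total = 0
    for c in classes:
        union |= c
        total += len(c)
    if union != set(AMINO_ACIDS) or total != 20:
        raise AssertionError("residue classes do not partition the amino-acid alphabet")
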