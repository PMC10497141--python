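"""Pipeline configuration: motif tables, scanner tolerances, alignment
parameters and the LBD marker column map.

Defaults reproduce the published motif grammar; every constant can be
overridden from a single YAML file (``Config.from_yaml`` /
``Config.to_yaml``) so divergent sequences can be accommodated without
code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .architecture import GBOX_TOKENS, NTSS_TOKENS
from .classify import PP_SIGNATURES
from .lbd import AF2_TOKENS, MARKER_SETS, TI_TOKENS
from .synth import DEFAULT_COLUMN_MAP


@dataclass
class Config:
    # signature tables
    pp_signatures: dict[str, str] = field(default_factory=lambda: dict(PP_SIGNATURES))
    gbox_variants: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in GBOX_TOKENS.items()})
    ntss_patterns: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in NTSS_TOKENS.items()})
    ti_tokens: list[str] = field(default_factory=lambda: list(TI_TOKENS))
    af2_variants: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in AF2_TOKENS.items()})
    marker_sets: dict[str, list[str]] = field(default_factory=lambda: {k: sorted(v) for k, v in MARKER_SETS.items()})
    column_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    # scanner tolerances
    max_inter_finger_gap: int = 30
    spacer_tolerance: bool = False
    cte_window: int = 30
    gbox_z_strict: bool = True
    max_mismatch: int = 1
    # alignment parameters
    substitution: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    # optional per-record taxon labels (seq_id -> taxon), for group C gating
    taxon_map: dict[str, str] = field(default_factory=dict)

    def marker_frozensets(self) -> dict[str, frozenset[str]]:
        return {k: frozenset(v) for k, v in self.marker_sets.items()}

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        base = cls()
        for key, value in data.items():
            if not hasattr(base, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(base, key, value)
        return base
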