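"""Protein FASTA I/O, the universal sequence record and the annotation report.

All coordinates in this package are 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class Architecture(str, Enum):
    """Modular architecture categories of nuclear receptors.

    ``TYPICAL_NR``  one DBD plus an LBD;
    ``DBD_ONLY``    DBD(s) but no LBD;
    ``LBD_ONLY``    an LBD but no DBD;
    ``TWO_DBD_NR``  two tandem DBDs plus an LBD;
    ``NOT_NR``      neither domain detected.
    """

    TYPICAL_NR = "TYPICAL_NR"
    DBD_ONLY = "DBD_ONLY"
    LBD_ONLY = "LBD_ONLY"
    TWO_DBD_NR = "TWO_DBD_NR"
    NOT_NR = "NOT_NR"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: id (no whitespace), description, residues.

    Residues are uppercase letters over the 20 standard amino acids plus
    the ambiguity letter ``X``.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id {self.id!r} must be a non-empty token")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for i, c in enumerate(self.residues):
            if c not in VALID_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {c!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    Residues are uppercased and a single terminal ``*`` stop is stripped.
    An empty file or a duplicated id is an error.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        records.append(SequenceRecord(id=rec.id, residues=residues,
                                      description=rec.description))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.residues), id=r.id,
                      description=r.description or "") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


#: Fixed TSV column order of the annotation report.
REPORT_COLUMNS = (
    "seq_id", "architecture", "n_dbds", "linker_len",
    "pbox1", "dbox1", "pbox2", "dbox2", "pp_module", "group",
    "gbox", "pre_grip_len", "tbox_present", "ti_span", "af2", "ntss",
    "nr_class",
)


@dataclass
class AnnotationReport:
    """Per-sequence annotation summary written to TSV/JSON.

    ``linker_len`` and ``pp_module`` are present iff at least two DBDs
    were detected (computed from the first two); ``multi_dbd`` flags the
    rare >2-DBD case.  ``ti_span`` is a 0-based half-open pair.
    """

    seq_id: str
    architecture: Architecture
    n_dbds: int = 0
    linker_len: int | None = None
    pbox1: str | None = None
    dbox1: str | None = None
    pbox2: str | None = None
    dbox2: str | None = None
    pp_module: str | None = None
    group: str | None = None
    gbox: str | None = None
    pre_grip_len: int | None = None
    tbox_present: bool | None = None
    ti_span: tuple[int, int] | None = None
    af2: str | None = None
    ntss: str | None = None
    nr_class: str | None = None
    multi_dbd: bool = False

    def __post_init__(self) -> None:
        if (self.linker_len is not None) != (self.n_dbds >= 2):
            raise ValueError(
                f"{self.seq_id}: linker_len must be present iff two DBDs detected")
        if (self.pp_module is not None) != (self.n_dbds >= 2):
            raise ValueError(
                f"{self.seq_id}: pp_module must be present iff two DBDs detected")

    def to_row(self) -> dict[str, str]:
        row = {}
        for col in REPORT_COLUMNS:
            v = getattr(self, col)
            if v is None:
                row[col] = ""
            elif col == "architecture":
                row[col] = v.value
            elif col == "tbox_present":
                row[col] = "true" if v else "false"
            elif col == "ti_span":
                row[col] = f"{v[0]}-{v[1]}"
            else:
                row[col] = str(v)
        return row

    @classmethod
    def from_row(cls, row: dict[str, str]) -> "AnnotationReport":
        def opt(col: str) -> str | None:
            v = row.get(col, "")
            return v if v != "" else None

        ti = opt("ti_span")
        tbox = opt("tbox_present")
        return cls(
            seq_id=row["seq_id"],
            architecture=Architecture(row["architecture"]),
            n_dbds=int(row["n_dbds"]),
            linker_len=None if opt("linker_len") is None else int(row["linker_len"]),
            pbox1=opt("pbox1"), dbox1=opt("dbox1"),
            pbox2=opt("pbox2"), dbox2=opt("dbox2"),
            pp_module=opt("pp_module"), group=opt("group"),
            gbox=opt("gbox"),
            pre_grip_len=None if opt("pre_grip_len") is None else int(row["pre_grip_len"]),
            tbox_present=None if tbox is None else tbox == "true",
            ti_span=None if ti is None else tuple(int(x) for x in ti.split("-")),  # type: ignore[arg-type]
            af2=opt("af2"), ntss=opt("ntss"), nr_class=opt("nr_class"),
        )

    def to_json_obj(self) -> dict:
        obj = {}
        for col in REPORT_COLUMNS:
            v = getattr(self, col)
            if col == "architecture":
                obj[col] = v.value
            elif col == "ti_span" and v is not None:
                obj[col] = list(v)
            else:
                obj[col] = v
        return obj

    @classmethod
    def from_json_obj(cls, obj: dict) -> "AnnotationReport":
        kw = dict(obj)
        kw["architecture"] = Architecture(kw["architecture"])
        if kw.get("ti_span") is not None:
            kw["ti_span"] = tuple(kw["ti_span"])
        return cls(**{k: v for k, v in kw.items() if k in {f.name for f in fields(cls)}})


def write_report(reports: Sequence[AnnotationReport], path: str | Path,
                 format: str = "tsv") -> None:
    """Write annotation reports as TSV (fixed column order) or JSON."""
    if format not in ("tsv", "json"):
        raise ValueError(f"unsupported report format {format!r}")
    path = Path(path)
    if format == "tsv":
        with path.open("w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(REPORT_COLUMNS), delimiter="\t")
            w.writeheader()
            for rep in reports:
                w.writerow(rep.to_row())
    else:
        with path.open("w") as fh:
            json.dump([r.to_json_obj() for r in reports], fh, indent=1)
            fh.write("\n")


def read_report(path: str | Path, format: str = "tsv") -> list[AnnotationReport]:
    path = Path(path)
    if format == "tsv":
        with path.open(newline="") as fh:
            return [AnnotationReport.from_row(row)
                    for row in csv.DictReader(fh, delimiter="\t")]
    if format == "json":
        with path.open() as fh:
            return [AnnotationReport.from_json_obj(o) for o in json.load(fh)]
    raise ValueError(f"unsupported report format {format!r}")
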