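"""Distance-based corroboration of group assignments.

Pairwise global alignment (affine gaps, BLOSUM62 by default) over the
concatenated first+second DBD regions gives a p-distance matrix
(1 − fraction identity), and a hand-rolled neighbor-joining
agglomeration turns it into an unrooted tree.  This is a desk-scale
corroborator of the rule-based grouping, not publication phylogenetics:
no model correction, no support values.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from .seq_io import SequenceRecord
from .zf_scan import DBD, assemble_dbds, scan_zinc_fingers

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseResult:
    alignment: object          # Bio.Align.Alignment
    score: float
    fraction_identity: float


def _make_aligner(substitution_table: str | object = "BLOSUM62",
                  gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if isinstance(substitution_table, str):
        substitution_table = substitution_matrices.load(substitution_table)
    aligner.substitution_matrix = substitution_table
    # first residue of a gap costs gap_open, each further residue gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_align(a: str, b: str,
                   substitution_table: str | object = "BLOSUM62",
                   gap_open: float = 10.0,
                   gap_extend: float = 1.0) -> PairwiseResult:
    """Optimal global alignment of two protein sequences.

    Returns the first optimal alignment, its score and the fraction of
    identical residues over aligned columns (a global pairwise alignment
    has no double-gap columns).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(substitution_table, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    best = alignments[0]
    counts = best.counts()
    frac = counts.identities / best.length
    return PairwiseResult(alignment=best, score=best.score, fraction_identity=frac)


def concat_dbd_region(record: SequenceRecord, dbds: Sequence[DBD]) -> str:
    """First-DBD span + second-DBD span of one record."""
    return (record.residues[dbds[0].start:dbds[0].end]
            + record.residues[dbds[1].start:dbds[1].end])


def dbd_distance_matrix(records: Sequence[SequenceRecord],
                        dbds_per_record: Sequence[Sequence[DBD]] | None = None,
                        substitution_table: str | object = "BLOSUM62",
                        gap_open: float = 10.0,
                        gap_extend: float = 1.0,
                        max_inter_finger_gap: int = 30) -> DistanceMatrix:
    """p-distance matrix over concatenated DBD regions.

    Every record must carry two DBDs (detected here when
    ``dbds_per_record`` is not supplied); offenders are listed in the
    error.  d(i, j) = 1 − fraction identity of the global alignment.
    """
    if dbds_per_record is None:
        dbds_per_record = [
            assemble_dbds(scan_zinc_fingers(r), r, max_inter_finger_gap)
            for r in records
        ]
    offenders = [r.id for r, d in zip(records, dbds_per_record) if len(d) < 2]
    if offenders:
        raise ValueError(
            "records lacking two DBDs: " + ", ".join(offenders))
    seqs = [concat_dbd_region(r, d) for r, d in zip(records, dbds_per_record)]
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = pairwise_align(seqs[i], seqs[j], substitution_table,
                                 gap_open, gap_extend)
            mat[i, j] = mat[j, i] = 1.0 - res.fraction_identity
    return DistanceMatrix(mat, ids=[r.id for r in records])


def _clamp(length: float) -> float:
    if length < 0:
        logger.info("negative NJ branch length %.6g clamped to 0", length)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (n >= 3), unrooted.

    Classic agglomeration: minimize Q(i,j) = (n−2)d(i,j) − r(i) − r(j),
    deterministic first-minimum tie-break, negative branch lengths
    clamped to zero.  On an additive matrix the generating tree (topology
    and branch lengths) is recovered exactly.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    # each active node is a growing newick fragment
    nodes: list[str] = [str(i) for i in dm.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li), _clamp(lj)
        merged = f"({nodes[i]}:{li:.12g},{nodes[j]}:{lj:.12g})"
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [merged]
        d = d2
    # resolve the final three nodes around one internal vertex
    l0 = _clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    l1 = _clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    l2 = _clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    newick = (f"({nodes[0]}:{l0:.12g},{nodes[1]}:{l1:.12g},"
              f"{nodes[2]}:{l2:.12g});")
    return TreeNode.read(io.StringIO(newick))


def write_newick(tree: TreeNode, path: str) -> None:
    tree.write(path, format="newick")
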