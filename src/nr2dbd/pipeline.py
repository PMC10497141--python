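"""End-to-end annotation: scanners -> classifier -> report.

``annotate_record`` runs the full motif grammar on one protein:
zinc-finger scan, DBD assembly, Ti-based LBD detection, architecture
call, linker measurement, P-P module + group assignment, G-box / T-box /
NTSS / AF2 scans, and (when an aligned LBD row and column map are at
hand) the dimerization-class profile.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence

from . import architecture as arch
from . import classify, lbd, zf_scan
from .config import Config
from .seq_io import AnnotationReport, SequenceRecord

logger = logging.getLogger(__name__)


def annotate_record(record: SequenceRecord, config: Config | None = None,
                    taxon: str | None = None,
                    aligned_lbd_row: str | None = None) -> AnnotationReport:
    """Full annotation of one protein sequence.

    ``taxon`` feeds the group-C gate of the classifier (falls back to
    ``config.taxon_map``); ``aligned_lbd_row`` plus ``config.column_map``
    enable the class I/II call.
    """
    cfg = config or Config()
    if taxon is None:
        taxon = cfg.taxon_map.get(record.id)

    fingers = zf_scan.scan_zinc_fingers(
        record, kinds=[zf_scan.FingerKind.CI, zf_scan.FingerKind.CII],
        spacer_tolerance=cfg.spacer_tolerance)
    dbds = zf_scan.assemble_dbds(fingers, record, cfg.max_inter_finger_gap)

    search_start = dbds[-1].end if dbds else 0
    ti_hits = lbd.scan_ti(record, search_start, cfg.ti_tokens)
    lbd_detected = bool(ti_hits)

    fields: dict = dict(seq_id=record.id,
                        architecture=arch.classify_architecture(dbds, lbd_detected),
                        n_dbds=len(dbds), multi_dbd=len(dbds) > 2)

    group_hint: str | None = None
    if dbds:
        fields["pbox1"] = dbds[0].p_box
        fields["dbox1"] = dbds[0].d_box
    if len(dbds) >= 2:
        d1, d2 = dbds[0], dbds[1]
        fields["pbox2"] = d2.p_box
        fields["dbox2"] = d2.d_box
        fields["linker_len"] = arch.measure_linker(d1, d2)
        ppm = classify.pp_module(d1, d2)
        fields["pp_module"] = ppm.rendered
        call = classify.assign_group(ppm, cfg.max_mismatch, taxon=taxon,
                                     signatures=cfg.pp_signatures)
        fields["group"] = call.group
        if call.group in ("A", "B", "C"):
            group_hint = call.group

    # CTE analysis from the end of the (second) DBD
    if dbds:
        cte_start = dbds[1].end if len(dbds) >= 2 else dbds[0].end
        hit = arch.scan_gbox(record, cte_start, group_hint=group_hint,
                             window=cfg.cte_window, z_strict=cfg.gbox_z_strict,
                             variants=cfg.gbox_variants)
        if hit is not None:
            fields["gbox"] = hit.sequence
            fields["pre_grip_len"] = hit.pre_grip_len
            fields["tbox_present"] = arch.tbox_present(hit)
        ntss_hits = arch.scan_ntss(record, dbds[0].start, cfg.ntss_patterns)
        if ntss_hits:
            fields["ntss"] = ntss_hits[0].pattern_name

    if ti_hits:
        fields["ti_span"] = (ti_hits[0].start, ti_hits[0].end)
        af2_hit = lbd.scan_af2(record, ti_hits[0].end, group_hint=group_hint,
                               variants=cfg.af2_variants)
        if af2_hit is not None:
            fields["af2"] = af2_hit.sequence

    if aligned_lbd_row is not None and cfg.column_map:
        profile = lbd.dimer_class_profile(aligned_lbd_row, cfg.column_map,
                                          cfg.marker_frozensets())
        fields["nr_class"] = profile.call.value

    return AnnotationReport(**fields)


def annotate(records: Sequence[SequenceRecord],
             config: Config | None = None) -> list[AnnotationReport]:
    """Annotate a batch and log a per-architecture summary."""
    reports = [annotate_record(r, config) for r in records]
    counts = Counter(r.architecture.value for r in reports)
    logger.info("annotated %d records: %s", len(reports),
                ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    return reports
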