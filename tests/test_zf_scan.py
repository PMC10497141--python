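import numpy as np
import pytest

from oracles import brute_force_fingers
from nr2dbd.seq_io import SequenceRecord
from nr2dbd.zf_scan import (FingerKind, PartialDBDError, assemble_dbds,
                            extract_dbox, extract_pbox, orphan_fingers,
                            scan_chc2, scan_zinc_fingers)

AA = "ACDEFGHIKLMNPQRSTVWY"


def rec(seq: str) -> SequenceRecord:
    return SequenceRecord(id="t", residues=seq)


class TestScan:
    def test_single_ci(self):
        seq = "C" + "AA" + "C" + "G" * 13 + "C" + "KK" + "C"
        hits = scan_zinc_fingers(rec(seq), kinds=[FingerKind.CI])
        assert len(hits) == 1
        f = hits[0]
        assert (f.start, f.end, f.spacers) == (0, 21, (2, 13, 2))
        assert f.anchor_positions == (0, 3, 17, 20)

    def test_single_cii(self):
        seq = "C" + "GEGEG" + "C" + "A" * 9 + "C" + "NL" + "C"
        hits = scan_zinc_fingers(rec(seq), kinds=[FingerKind.CII])
        assert len(hits) == 1
        assert hits[0].spacers == (5, 9, 2)

    def test_no_cysteines_no_hits(self):
        assert scan_zinc_fingers(rec("MKLV" * 10)) == []

    def test_ambiguity_x_never_matches_an_anchor(self):
        seq = "X" + "AA" + "C" + "G" * 13 + "C" + "KK" + "C"
        assert scan_zinc_fingers(rec(seq), kinds=[FingerKind.CI]) == []

    def test_chc2_needs_histidine_third_anchor(self):
        chc2 = "C" + "A" * 6 + "C" + "G" * 9 + "H" + "KK" + "C"
        assert len(scan_chc2(rec(chc2))) == 1
        all_c = chc2.replace("H", "C")
        assert scan_chc2(rec(all_c)) == []

    def test_tolerant_spacers_off_by_default(self):
        seq = "C" + "AA" + "C" + "G" * 14 + "C" + "KK" + "C"  # X14 middle
        assert scan_zinc_fingers(rec(seq), kinds=[FingerKind.CI]) == []
        hits = scan_zinc_fingers(rec(seq), kinds=[FingerKind.CI],
                                 spacer_tolerance=True)
        assert len(hits) == 1 and hits[0].spacers == (2, 14, 2)

    def test_reported_fingers_recheck_against_their_definition(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("CAGKL"), size=400))
        for f in scan_zinc_fingers(rec(seq), kinds=list(FingerKind)):
            anchors = "CCHC" if f.kind == FingerKind.CHC2 else "CCCC"
            for pos, want in zip(f.anchor_positions, anchors):
                assert seq[pos] == want
            assert f.end - f.start == 4 + sum(f.spacers)

    @pytest.mark.parametrize("kind", ["CI", "CII", "CHC2"])
    def test_equivalence_with_brute_force_oracle(self, kind):
        """Scan agrees with a position-by-position matcher on 1,000
        random 200-residue sequences (cysteine-enriched to force hits)."""
        rng = np.random.default_rng(123)
        alphabet = list(AA) + list("CCCH")  # boost anchor frequency
        n_hits = 0
        for _ in range(1000):
            seq = "".join(rng.choice(alphabet, size=200))
            got = [(f.start, f.end) for f in
                   scan_zinc_fingers(rec(seq), kinds=[kind])]
            expected = brute_force_fingers(seq, kind)
            assert got == expected
            n_hits += len(expected)
        assert n_hits > 0  # the comparison actually exercised matches


def make_two_dbd_seq():
    ci = "C" + "EA" + "C" + "G" * 13 + "C" + "EA" + "C"      # pbox EACKK
    mid = "KK" + "G" * 8
    cii = "C" + "KYEGA" + "C" + "A" * 9 + "C" + "NL" + "C"
    dbd1 = ci + mid + cii
    ci2 = "C" + "EA" + "C" + "G" * 13 + "C" + "EG" + "C"     # pbox EGCKG
    mid2 = "KG" + "G" * 8
    cii2 = "C" + "STGAK" + "C" + "A" * 9 + "C" + "NL" + "C"
    return "M" * 10 + dbd1 + "P" * 20 + ci2 + mid2 + cii2 + "Q" * 5


class TestAssemble:
    def test_two_dbds_with_paper_pboxes(self):
        r = rec(make_two_dbd_seq())
        dbds = assemble_dbds(scan_zinc_fingers(r), r)
        assert len(dbds) == 2
        assert extract_pbox(dbds[0]) == "EACKK"
        assert extract_pbox(dbds[1]) == "EGCKG"
        assert extract_dbox(dbds[0]) == "KYEGA"
        assert dbds[0].ordinal == "FIRST" and dbds[1].ordinal == "SECOND"

    def test_pbox_midpoint_is_ci_fourth_cysteine(self):
        r = rec(make_two_dbd_seq())
        for dbd in assemble_dbds(scan_zinc_fingers(r), r):
            a4 = dbd.cI.anchor_positions[3]
            assert r.residues[a4] == "C"
            assert extract_pbox(dbd)[2] == "C"
            assert dbd.cI.anchor_positions[2] + 3 == a4

    def test_orphan_ci_beyond_gap_yields_no_dbd(self):
        ci = "C" + "EA" + "C" + "G" * 13 + "C" + "EA" + "C"
        cii = "C" + "KYEGA" + "C" + "A" * 9 + "C" + "NL" + "C"
        r = rec(ci + "G" * 40 + cii)  # gap 40 > default 30
        fingers = scan_zinc_fingers(r)
        dbds = assemble_dbds(fingers, r)
        assert dbds == []
        assert len(orphan_fingers(fingers, dbds)) == 2

    def test_gap_is_configurable(self):
        ci = "C" + "EA" + "C" + "G" * 13 + "C" + "EA" + "C"
        cii = "C" + "KYEGA" + "C" + "A" * 9 + "C" + "NL" + "C"
        r = rec(ci + "G" * 40 + cii)
        assert len(assemble_dbds(scan_zinc_fingers(r), r,
                                 max_inter_finger_gap=50)) == 1

    def test_molluscan_first_dbd_pbox_lpcks(self):
        ci = "C" + "LP" + "C" + "G" * 13 + "C" + "LP" + "C"  # pbox LPCKS
        r = rec(ci + "KS" + "G" * 8
                + "C" + "KYEGA" + "C" + "A" * 9 + "C" + "NL" + "C")
        dbds = assemble_dbds(scan_zinc_fingers(r), r)
        assert extract_pbox(dbds[0]) == "LPCKS"

    def test_truncated_pbox_raises(self):
        from nr2dbd.zf_scan import DBD, ZincFinger
        ci = ZincFinger(kind=FingerKind.CI, start=0, end=21,
                        anchor_positions=(0, 3, 17, 20), spacers=(2, 13, 2))
        cii = ZincFinger(kind=FingerKind.CII, start=30, end=50,
                         anchor_positions=(30, 36, 46, 49), spacers=(5, 9, 2))
        dbd = DBD(cI=ci, cII=cii, start=0, end=50, p_box=None, d_box="KYEGA")
        with pytest.raises(PartialDBDError):
            extract_pbox(dbd)

    def test_embedded_ci_found_in_random_context(self):
        rng = np.random.default_rng(7)
        filler = "".join(rng.choice(list("AGKLMNPQRSTV"), size=300))
        ci = "C" + "EA" + "C" + "G" * 13 + "C" + "KK" + "C"
        seq = filler[:140] + ci + filler[140:]
        hits = scan_zinc_fingers(rec(seq), kinds=[FingerKind.CI])
        assert [(f.start, f.end) for f in hits] == [(140, 161)]
        assert brute_force_fingers(seq, "CI") == [(140, 161)]
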