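import io

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from oracles import brute_force_affine_score
from nr2dbd import synth
from nr2dbd.phylo import (dbd_distance_matrix, nj_tree, pairwise_align,
                          write_newick)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestPairwiseAlign:
    def test_identical_sequences_identity_one(self):
        res = pairwise_align("ACDE", "ACDE")
        assert res.fraction_identity == 1.0

    def test_one_mismatch_identity_three_quarters(self):
        res = pairwise_align("ACDE", "ACDW")
        assert res.fraction_identity == 0.75

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_align("", "ACDE")

    def test_optimal_scores_match_exhaustive_enumeration(self):
        """DP alignment score equals brute-force enumeration over every
        monotone alignment, for random short peptide pairs."""
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(17)
        for _ in range(25):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 6)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 6)))
            got = pairwise_align(a, b).score
            want = brute_force_affine_score(
                a, b, lambda x, y: blosum[x, y], 10.0, 1.0)
            assert got == pytest.approx(want)


def _panel(templates, seed=5):
    rng = np.random.default_rng(seed)
    out = []
    for i, tmpl in enumerate(templates):
        spec = synth.GROUP_TEMPLATES[tmpl]
        r, _ = synth.make_sequence(synth.GenParams(**spec), rng=rng,
                                   seq_id=f"{tmpl}x{i}")
        out.append(r)
    return out


class TestDistanceMatrix:
    def test_matrix_shape_symmetry_zero_diagonal(self):
        recs = _panel(["A1", "B1", "C1"])
        dm = dbd_distance_matrix(recs)
        m = np.asarray(dm.data)
        assert m.shape == (3, 3)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)
        assert (m >= 0).all() and (m <= 1).all()

    def test_identical_sequences_distance_zero(self):
        recs = _panel(["A1"]) * 2
        from dataclasses import replace
        from nr2dbd.seq_io import SequenceRecord
        r2 = SequenceRecord(id="copy", residues=recs[0].residues)
        dm = dbd_distance_matrix([recs[0], r2, _panel(["B1"])[0]])
        assert dm[0, 1] == 0.0

    def test_different_groups_positive_distance(self):
        a, b = _panel(["A1", "B1"])
        dm = dbd_distance_matrix([a, b, _panel(["C1"])[0]])
        assert dm[0, 1] > 0

    def test_record_order_permutes_matrix(self):
        recs = _panel(["A1", "B1", "C1"])
        dm1 = dbd_distance_matrix(recs)
        dm2 = dbd_distance_matrix(recs[::-1])
        assert dm1["A1x0", "B1x1"] == dm2["A1x0", "B1x1"]

    def test_record_without_two_dbds_listed_in_error(self):
        from nr2dbd.seq_io import SequenceRecord
        bad = SequenceRecord(id="bad", residues="MKLV" * 30)
        recs = _panel(["A1", "B1"]) + [bad]
        with pytest.raises(ValueError, match="bad"):
            dbd_distance_matrix(recs)


def random_additive_matrix(rng, n_taxa):
    """Distances induced by a random binary tree with known positive
    branch lengths; returns (DistanceMatrix, newick)."""
    nodes = [(f"t{i}", None) for i in range(n_taxa)]
    # leaf paths accumulate branch lengths; build by random joins
    import itertools
    dist = {(i, i): 0.0 for i in range(n_taxa)}
    # simpler: build tree newick, then read distances from skbio
    labels = [f"t{i}" for i in range(n_taxa)]
    parts = [f"{lab}:{rng.integers(1, 9)}" for lab in labels]
    while len(parts) > 3:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        merged = f"({parts[i]},{parts[j]}):{rng.integers(1, 9)}"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    newick = f"({parts[0]},{parts[1]},{parts[2]});"
    tree = TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    return DistanceMatrix(dm.data, ids=list(dm.ids)), tree


class TestNeighborJoining:
    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError, match="3"):
            nj_tree(dm)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # distances from the tree ((a:2,b:3):1,c:4,d:5);
        tree = TreeNode.read(io.StringIO("((a:2,b:3):1,c:4,d:5);"))
        ref = tree.tip_tip_distances()
        dm = DistanceMatrix(ref.data, ids=list(ref.ids))
        out = nj_tree(dm)
        got = out.tip_tip_distances()
        for x in ref.ids:
            for y in ref.ids:
                assert got[x, y] == pytest.approx(ref[x, y])
        assert out.compare_rfd(tree) == 0

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_random_additive_matrices_recovered(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            dm, tree = random_additive_matrix(rng, n_taxa)
            out = nj_tree(dm)
            assert out.compare_rfd(tree) == 0
            got = out.tip_tip_distances()
            for x in dm.ids:
                for y in dm.ids:
                    assert got[x, y] == pytest.approx(dm[x, y])

    def test_agrees_with_skbio_nj_topology(self):
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(99)
        dm, _ = random_additive_matrix(rng, 6)
        assert nj_tree(dm).compare_rfd(skbio_nj(dm)) == 0

    def test_identical_rows_become_siblings(self):
        m = np.array([[0.0, 0.0, 0.6, 0.7],
                      [0.0, 0.0, 0.6, 0.7],
                      [0.6, 0.6, 0.0, 0.3],
                      [0.7, 0.7, 0.3, 0.0]])
        tree = nj_tree(DistanceMatrix(m, ids=list("abcd")))
        # unrooted sibling check: rooting at c, the smallest clade holding
        # both a and b must contain nothing else
        rooted = tree.root_at(tree.find("c"))
        lca = rooted.lca(["a", "b"])
        assert {t.name for t in lca.tips()} == {"a", "b"}

    def test_synth_group_a_and_b_form_disjoint_clades(self):
        recs = _panel(["A1", "A1", "A2", "A2", "B1", "B1", "B2", "B2"])
        tree = nj_tree(dbd_distance_matrix(recs))
        rooted = tree.root_at(tree.find("B1x4"))
        a_tips = [n.name for n in rooted.tips() if n.name.startswith("A")]
        lca = rooted.lca(a_tips)
        assert sorted(t.name for t in lca.tips()) == sorted(a_tips)

    def test_newick_round_trip(self, tmp_path):
        dm, _ = random_additive_matrix(np.random.default_rng(3), 5)
        tree = nj_tree(dm)
        out = tmp_path / "t.nwk"
        write_newick(tree, str(out))
        back = TreeNode.read(str(out))
        assert back.compare_rfd(tree) == 0
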