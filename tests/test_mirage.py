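"""Mirage cluster detection, unit identities, splice signals, NJ, intron gain."""

import dendropy
import numpy as np
import pytest

from Bio.Seq import Seq

from globkit.genemodels import GeneModel, ValidationError
from globkit.mirage import (
    DetectorParams,
    detect_mirage,
    nj_tree,
    scan_splice_signals,
    simulate_intron_gain,
    unit_identity_matrix,
)
from globkit.simulate import PRESETS, MirageSpec, make_mirage_gene


def random_binary_newick(labels, rng, min_len=0.1, max_len=1.0):
    """Random binary tree by successive joins, positive branch lengths."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.uniform(min_len, max_len, size=2)
        merged = f"({nodes[i]}:{li:.4f},{nodes[j]}:{lj:.4f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def _jaccard(iv1, iv2):
    a = max(iv1[0], iv2[0])
    b = min(iv1[1], iv2[1])
    inter = max(0, b - a)
    union = (iv1[1] - iv1[0]) + (iv2[1] - iv2[0]) - inter
    return inter / union


class TestDetect:
    def test_bflgb6_h1_six_units(self, bflgb6_h1):
        seq, model, truth = bflgb6_h1
        clusters = detect_mirage(seq, model)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.side == "acceptor"
        assert c.n_units == 6
        assert c.consensus_length == 155

    def test_bflgb9_unit_length(self, bflgb9):
        seq, model, truth = bflgb9
        clusters = detect_mirage(seq, model)
        assert len(clusters) == 1
        assert clusters[0].consensus_length == 157
        assert clusters[0].side == "donor"

    def test_shuffled_sequence_no_clusters(self, bflgb6_h1):
        seq, model, _ = bflgb6_h1
        rng = np.random.default_rng(5)
        arr = np.array(list(seq))
        rng.shuffle(arr)
        assert detect_mirage("".join(arr), model) == []

    def test_detected_units_overlap_truth(self):
        spec = MirageSpec(unit_length=120, n_units=3, per_unit_divergence=0.02, boundary_kind="acceptor_side", seed=7)
        seq, model, truth = make_mirage_gene(spec)
        clusters = detect_mirage(seq, model)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_units == 3
        for det, tru in zip(c.unit_intervals, truth.unit_intervals):
            assert _jaccard(det, tru) >= 0.9

    def test_strand_symmetry(self, bflgb6_h1):
        """Reverse-complementing sequence and model yields the mirror cluster."""
        seq, model, _ = bflgb6_h1
        fwd = detect_mirage(seq, model)[0]
        n = len(seq)
        rc = str(Seq(seq).reverse_complement())
        rc_exons = sorted((n - b, n - a) for a, b in model.exons)
        rc_model = GeneModel(model.gene_id, model.seq_id, "-", rc_exons)
        rev = detect_mirage(rc, rc_model)
        assert len(rev) == 1
        assert rev[0].n_units == fwd.n_units
        assert rev[0].consensus_length == fwd.consensus_length
        lo, hi = fwd.span
        assert abs(rev[0].span[0] - (n - hi)) <= 5
        assert abs(rev[0].span[1] - (n - lo)) <= 5

    def test_gene_model_out_of_bounds(self):
        m = GeneModel("g", "s", "+", [(0, 100), (200, 400)])
        with pytest.raises(ValidationError, match="bounds"):
            detect_mirage("ACGT" * 20, m)


class TestIdentityMatrix:
    def test_zero_divergence_all_100(self):
        spec = MirageSpec(unit_length=100, n_units=4, per_unit_divergence=0.0, boundary_kind="acceptor_side", seed=3)
        seq, model, truth = make_mirage_gene(spec)
        c = detect_mirage(seq, model)[0]
        idm = unit_identity_matrix(c, seq)
        assert np.allclose(idm, 100.0)

    def test_preset_identity_band(self, bflgb6_h1):
        """Unit identities in the observed 75-100% band; minimum near truth."""
        seq, model, truth = bflgb6_h1
        c = detect_mirage(seq, model)[0]
        idm = unit_identity_matrix(c, seq)
        off = idm[np.triu_indices(c.n_units, k=1)]
        assert (off >= 75.0).all() and (off <= 100.0).all()
        assert abs(off.min() - min(truth.identities_pct.values())) <= 5.0

    def test_symmetry_and_diagonal(self, bflgb9):
        seq, model, _ = bflgb9
        c = detect_mirage(seq, model)[0]
        idm = unit_identity_matrix(c, seq)
        assert np.allclose(idm, idm.T)
        assert np.allclose(np.diag(idm), 100.0)


class TestSpliceSignals:
    def test_intact_signals_all_true(self):
        spec = MirageSpec(unit_length=100, n_units=4, per_unit_divergence=0.0, boundary_kind="acceptor_side", seed=3)
        seq, model, _ = make_mirage_gene(spec)
        c = detect_mirage(seq, model)[0]
        assert all(r["present"] for r in scan_splice_signals(c, seq))

    def test_knocked_out_signal_flagged(self):
        spec = MirageSpec(
            unit_length=100, n_units=4, per_unit_divergence=0.0, boundary_kind="acceptor_side",
            seed=3, knockout_signal_units=(3,),
        )
        seq, model, _ = make_mirage_gene(spec)
        c = detect_mirage(seq, model)[0]
        flags = [r["present"] for r in scan_splice_signals(c, seq)]
        assert flags == [True, True, False, True]

    def test_preset_many_but_not_all(self, bflgb6_h1):
        seq, model, _ = bflgb6_h1
        c = detect_mirage(seq, model)[0]
        flags = [r["present"] for r in scan_splice_signals(c, seq)]
        assert any(flags) and not all(flags)
        assert sum(flags) > len(flags) / 2


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 4.0, 6.0], [4.0, 0.0, 8.0], [6.0, 8.0, 0.0]])
        nwk = nj_tree(D, ["a", "b", "c"])
        t = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["b"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["c"] == pytest.approx((6 + 8 - 4) / 2)

    def test_classic_five_taxon_example(self):
        D = np.array(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            dtype=float,
        )
        nwk = nj_tree(D, list("abcde"))
        t = dendropy.Tree.get(data=nwk, schema="newick")
        # additive matrix: path distances reproduce D exactly
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for i, li in enumerate("abcde"):
            for j, lj in enumerate("abcde"):
                if i < j:
                    assert pdm.distance(taxa[li], taxa[lj]) == pytest.approx(D[i, j])

    def test_recovers_generating_topology(self, rng):
        """Additive distances from random trees are inverted with RF = 0."""
        from dendropy.calculate import treecompare

        for k in range(5):
            n_taxa = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n_taxa)]
            nwk = random_binary_newick(labels, rng)
            ns = dendropy.TaxonNamespace(labels)
            true = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=ns)
            pdm = true.phylogenetic_distance_matrix()
            D = np.array([[pdm.distance(ns.get_taxon(a), ns.get_taxon(b)) for b in labels] for a in labels])
            est = dendropy.Tree.get(data=nj_tree(D, labels), schema="newick", taxon_namespace=ns)
            true.encode_bipartitions()
            est.encode_bipartitions()
            assert treecompare.symmetric_difference(true, est, is_bipartitions_updated=True) == 0

    def test_matches_skbio_topology(self):
        """Cross-check against an independent NJ implementation."""
        skbio = pytest.importorskip("skbio")
        from dendropy.calculate import treecompare

        D = np.array(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            dtype=float,
        )
        labels = list("abcde")
        import io

        ours = nj_tree(D, labels)
        buf = io.StringIO()
        skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels)).write(buf, format="newick")
        ns = dendropy.TaxonNamespace(labels)
        t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=ns)
        t2 = dendropy.Tree.get(data=buf.getvalue(), schema="newick", taxon_namespace=ns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert treecompare.symmetric_difference(t1, t2, is_bipartitions_updated=True) == 0

    def test_concerted_evolution_clade(self):
        """Homogenized units D3/D4/D5 cluster to the exclusion of divergent D6."""
        labels = ["D3", "D4", "D5", "D6"]
        # distances: tight homogenized trio, distant boundary unit
        D = np.array(
            [
                [0.0, 2.0, 2.5, 15.0],
                [2.0, 0.0, 2.2, 15.5],
                [2.5, 2.2, 0.0, 15.2],
                [15.0, 15.5, 15.2, 0.0],
            ]
        )
        nwk = nj_tree(D, labels)
        t = dendropy.Tree.get(data=nwk, schema="newick")
        t.is_rooted = False
        t.encode_bipartitions()
        # D3+D4+D5 vs D6 must be a bipartition of the tree
        splits = {frozenset(leaf.taxon.label for leaf in e.head_node.leaf_iter()) for e in t.preorder_edge_iter()}
        assert frozenset({"D3", "D4", "D5"}) in splits or frozenset({"D6"}) in splits

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            nj_tree(D, list("abc"))


class TestIntronGain:
    SPEC = MirageSpec(unit_length=150, n_units=5, per_unit_divergence=0.05, boundary_kind="acceptor_side", seed=9)

    def test_exon_count_increments(self):
        seq, pre, post = simulate_intron_gain(self.SPEC, 2)
        assert len(post.exons) == len(pre.exons) + 1

    def test_flanking_exons_unchanged(self):
        seq, pre, post = simulate_intron_gain(self.SPEC, 2)
        assert post.exons[0] == pre.exons[0]
        assert post.exons[-1] == pre.exons[-1]

    def test_new_exon_has_splice_signals(self):
        seq, _, post = simulate_intron_gain(self.SPEC, 2)
        a, b = post.exons[1]
        assert seq[a - 2 : a] == "AG"
        assert seq[b : b + 2] == "GT"

    def test_new_intron_keeps_degenerate_repeats(self):
        """The gained intron still contains repeat copies near the consensus."""
        from globkit.mirage import _nuc_identity_pct

        seq, pre, post = simulate_intron_gain(self.SPEC, 2)
        truth_seq, _, truth = make_mirage_gene(self.SPEC)
        new_intron = (post.exons[1][1], post.exons[2][0])
        consensus = truth_seq[truth.unit_intervals[0][0] : truth.unit_intervals[0][1]]
        intron_seq = seq[new_intron[0] : new_intron[1]]
        assert len(intron_seq) >= len(consensus)
        best = max(
            _nuc_identity_pct(consensus, intron_seq[i : i + len(consensus)])
            for i in range(0, len(intron_seq) - len(consensus) + 1, 25)
        )
        assert best >= 60.0

    def test_detector_finds_residual_repeats(self):
        seq, _, post = simulate_intron_gain(self.SPEC, 2)
        clusters = detect_mirage(seq, post)
        assert any(c.n_units >= 2 for c in clusters)

    def test_missing_cryptic_site_rejected(self):
        spec = MirageSpec(
            unit_length=150, n_units=5, per_unit_divergence=0.0, boundary_kind="acceptor_side",
            seed=9, knockout_signal_units=(2,),
        )
        with pytest.raises(ValidationError, match="no cryptic site"):
            simulate_intron_gain(spec, 2)

    def test_boundary_unit_not_recruitable(self):
        with pytest.raises(ValidationError, match="interior"):
            simulate_intron_gain(self.SPEC, 5)
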