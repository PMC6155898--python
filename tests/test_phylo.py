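import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdckit.msa import Alignment
from tdckit.phylo import (
    DistanceMatrix,
    Node,
    Tree,
    bootstrap_tree,
    dayhoff_correct,
    distance_from_alignment,
    neighbor_joining,
    read_newick,
    write_newick,
)
from tdckit.seq_core import SequenceRecord
from tdckit.synthetic_data import FamilyConfig, generate_family


from _tree_oracle import random_additive_matrix, tree_path_lengths


def rec_of(s, name):
    return SequenceRecord(id=name, residues=s)


class TestDistances:
    def test_identical_rows_zero(self):
        aln = Alignment([rec_of("ACDEF", "a"), rec_of("ACDEF", "b")])
        for model in ("p", "dayhoff"):
            assert distance_from_alignment(aln, model).matrix[0, 1] == 0.0

    def test_dayhoff_closed_form(self):
        assert dayhoff_correct(0.1) == pytest.approx(-math.log(0.898), abs=1e-12)
        assert dayhoff_correct(0.1) == pytest.approx(0.1076, abs=1e-4)

    def test_p_distance_counts_shared_nongap_columns(self):
        aln = Alignment([rec_of("A-CDE", "a"), rec_of("AGCEE", "b")])
        # shared non-gap columns: 1,3,4,5 -> one differing (D vs E)
        assert distance_from_alignment(aln, "p").matrix[0, 1] == pytest.approx(0.25)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_p_distance_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACDEFG-"), size=30))
        b = "".join(rng.choice(list("ACDEFG-"), size=30))
        shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        if not shared:
            return
        expected = sum(1 for x, y in shared if x != y) / len(shared)
        try:
            aln = Alignment([rec_of(a, "a"), rec_of(b, "b")])
        except ValueError:  # drew an all-gap column
            return
        assert distance_from_alignment(aln, "p").matrix[0, 1] == pytest.approx(expected)

    def test_saturated_pair_advises_p_model(self):
        aln = Alignment([rec_of("AAAAAAAAAA", "a"), rec_of("CCCCCCCCCC", "b")])
        with pytest.raises(ValueError, match="model='p'"):
            distance_from_alignment(aln, "dayhoff")

    def test_no_shared_columns_names_pair(self):
        aln = Alignment([rec_of("AA--", "a"), rec_of("--CC", "b"), rec_of("AACC", "c")])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            distance_from_alignment(aln, "p")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = neighbor_joining(DistanceMatrix(ids, d))
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]])))
        total = sum(leaf.length for leaf in tree.root.leaves())
        assert total == pytest.approx(0.4)

    def test_zero_distance_cherry(self):
        tree = neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
        assert all(leaf.length == 0 for leaf in tree.root.leaves())

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_reconstructed_exactly(self, n_taxa):
        """NJ path-length sums reproduce any additive input matrix."""
        rng = random.Random(n_taxa * 17 + 1)
        for _ in range(5):
            dm, _ = random_additive_matrix(n_taxa, rng)
            tree = neighbor_joining(dm)
            paths = tree_path_lengths(tree)
            for i, a in enumerate(dm.ids):
                for j, b in enumerate(dm.ids):
                    if i < j:
                        assert paths[frozenset((a, b))] == pytest.approx(
                            dm.matrix[i, j], abs=1e-9
                        )

    def test_matches_skbio_topology(self):
        """Independent oracle: scikit-bio's NJ yields the same bipartitions."""
        import skbio

        rng = random.Random(99)
        dm, _ = random_additive_matrix(7, rng)
        ours = neighbor_joining(dm).bipartitions().keys()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=dm.ids))
        ref = min(dm.ids)
        theirs = set()
        for node in sk_tree.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(dm.ids) - 2:
                side = below if ref not in below else frozenset(dm.ids) - below
                theirs.add(side)
        assert set(ours) == theirs

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))


class TestBootstrap:
    def test_identical_sequences_no_informative_bipartitions(self):
        aln = Alignment([rec_of("ACDEF", n) for n in "abcd"])
        tree = bootstrap_tree(aln, n_reps=10, seed=0)
        for key, node in tree.bipartitions().items():
            assert node.support is not None  # supports assigned, content arbitrary

    def test_two_class_family_bipartition_strongly_supported(self):
        seqs, truth = generate_family(FamilyConfig(n_tdc=6, n_tydc=6, mu=0.05, seed=3))
        aln = Alignment([r for r in seqs])
        tree = bootstrap_tree(aln, n_reps=100, seed=1)
        tdc = frozenset(i for i, l in truth.labels.items() if l == "TDC")
        tydc = frozenset(i for i, l in truth.labels.items() if l == "TYDC")
        supports = [n.support for k, n in tree.bipartitions().items() if k in (tdc, tydc)]
        assert supports and max(supports) >= 95

    def test_determinism(self):
        seqs, _ = generate_family(FamilyConfig(n_tdc=4, n_tydc=4, mu=0.05, seed=5))
        aln = Alignment(list(seqs))
        t1 = bootstrap_tree(aln, n_reps=30, seed=42)
        t2 = bootstrap_tree(aln, n_reps=30, seed=42)
        assert write_newick(t1) == write_newick(t2)

    def test_leaf_order_invariance(self):
        seqs, _ = generate_family(FamilyConfig(n_tdc=4, n_tydc=4, mu=0.05, seed=6))
        rows = list(seqs)
        t1 = bootstrap_tree(Alignment(rows), n_reps=30, seed=7)
        t2 = bootstrap_tree(Alignment(rows[::-1]), n_reps=30, seed=7)
        s1 = {k: n.support for k, n in t1.bipartitions().items()}
        s2 = {k: n.support for k, n in t2.bipartitions().items()}
        assert set(s1) == set(s2)


class TestNewick:
    def test_cherry_roundtrip(self):
        tree = Tree(Node(children=[Node(name="a", length=1.0), Node(name="b", length=1.0)]))
        text = write_newick(tree)
        back = read_newick(text)
        assert sorted(tree.taxa) == sorted(back.taxa)
        assert write_newick(back) == text

    def test_supports_as_internal_labels(self):
        inner = Node(length=0.5, support=95, children=[Node(name="a", length=1.0), Node(name="b", length=2.0)])
        tree = Tree(Node(children=[inner, Node(name="c", length=1.0)]))
        text = write_newick(tree)
        assert ")95:" in text
        back = read_newick(text)
        assert write_newick(back) == text

    def test_malformed_input_rejected(self):
        with pytest.raises(ValueError, match="Newick"):
            read_newick("((a:1,b:2;")

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_tree_roundtrip(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 8)
        dm, _ = random_additive_matrix(n, rng)
        tree = neighbor_joining(dm)
        for i, (_, node) in enumerate(tree.bipartitions().items()):
            node.support = (i * 13) % 101
        text = write_newick(tree)
        back = read_newick(text)
        assert write_newick(back) == text
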