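"""p-distance, neighbor joining vs additivity/exhaustive-search oracles,
bootstrap supports and group assignment."""

import numpy as np
import pytest

from _oracles import best_topology_splits, random_additive_matrix
from famsurvey.io_formats import TreeNode, ValidationError
from famsurvey.phylogeny import (
    DistanceMatrix,
    assign_groups,
    bootstrap_support,
    ensure_alignment,
    nj_tree,
    p_distance,
    star_align,
    tree_path_lengths,
)
from famsurvey.phylogeny import _bipartitions


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance([("a", "AAAA"), ("b", "AAAA")])
        assert dm.value("a", "b") == 0

    def test_single_mismatch(self):
        dm = p_distance([("a", "AAAA"), ("b", "AAAT")])
        assert dm.value("a", "b") == 0.25

    def test_gap_columns_excluded_pairwise(self):
        msa = [("a", "AA-A"), ("b", "AATA"), ("c", "TTTA")]
        dm = p_distance(msa)
        assert dm.value("a", "b") == 0  # 3 comparable columns, all equal
        assert dm.value("b", "c") == 0.5  # full 4 columns, 2 mismatches

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValidationError, match="comparable"):
            p_distance([("a", "A-"), ("b", "-A")])

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValidationError):
            p_distance([("a", "AAA"), ("b", "AAAA")])


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) — additive distances
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ], dtype=float)
        d[2, 3] = d[3, 2] = 7.0
        dm = DistanceMatrix(labels, d)
        tree = nj_tree(dm)
        fitted = tree_path_lengths(tree)
        assert np.allclose(fitted.d, dm.d)
        assert _bipartitions(tree) == {frozenset({"C", "D"})}

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([
            [0, 2, 3], [2, 0, 3], [3, 3, 0]
        ], dtype=float))
        tree = nj_tree(dm)
        lengths = {leaf.label: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_random_additive_matrices_reconstructed(self):
        rng = np.random.default_rng(12)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(20):
            d, true_splits = random_additive_matrix(labels, rng)
            tree = nj_tree(DistanceMatrix(labels, d))
            fitted = tree_path_lengths(tree)
            assert np.allclose(fitted.d, d, atol=1e-9)
            assert _bipartitions(tree) == true_splits

    @pytest.mark.parametrize("n", [5, 6])
    def test_topology_matches_exhaustive_least_squares(self, n):
        rng = np.random.default_rng(13 + n)
        labels = [f"t{i}" for i in range(n)]
        for _ in range(3):
            d, _true = random_additive_matrix(labels, rng)
            tree = nj_tree(DistanceMatrix(labels, d))
            assert _bipartitions(tree) == best_topology_splits(labels, d)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValidationError):
            nj_tree(dm)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(["A", "B", "C"], np.array([
                [0, 1, 2], [1.5, 0, 1], [2, 1, 0]
            ]))

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            n = 6
            d = rng.uniform(0.1, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], d))
            for node in tree.walk():
                if node.length is not None:
                    assert node.length >= 0


def _two_clade_msa(rng, n_per_clade=4, length=120, divergence=0.4):
    """Sequences from two well-separated clades."""
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    root_a = alphabet[rng.integers(0, 20, size=length)]
    root_b = root_a.copy()
    flip = rng.random(length) < divergence
    root_b[flip] = alphabet[rng.integers(0, 20, size=int(flip.sum()))]
    msa = []
    for clade, root in (("a", root_a), ("b", root_b)):
        for i in range(n_per_clade):
            seq = root.copy()
            mut = rng.random(length) < 0.03
            seq[mut] = alphabet[rng.integers(0, 20, size=int(mut.sum()))]
            msa.append((f"{clade}{i}", "".join(seq)))
    return msa


class TestBootstrap:
    def test_strong_split_gets_high_support(self):
        rng = np.random.default_rng(21)
        msa = _two_clade_msa(rng)
        tree = bootstrap_support(msa, replicates=100, seed=3)
        splits = {
            frozenset(node.leaf_labels()): node.support
            for node in tree.walk()
            if node is not tree and not node.is_leaf
        }
        clade = next(
            (s for s in splits
             if {l[0] for l in s} in ({"a"}, {"b"}) and len(s) == 4),
            None,
        )
        assert clade is not None
        assert splits[clade] >= 0.95

    def test_single_replicate_supports_are_zero_or_one(self):
        rng = np.random.default_rng(22)
        msa = _two_clade_msa(rng, n_per_clade=3)
        tree = bootstrap_support(msa, replicates=1, seed=0)
        supports = [n.support for n in tree.walk()
                    if not n.is_leaf and n is not tree and n.support is not None]
        assert supports and set(supports) <= {0.0, 1.0}

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(23)
        msa = _two_clade_msa(rng, n_per_clade=3)
        t1 = bootstrap_support(msa, replicates=25, seed=7)
        t2 = bootstrap_support(msa, replicates=25, seed=7)
        s1 = sorted((tuple(sorted(n.leaf_labels())), n.support)
                    for n in t1.walk() if not n.is_leaf)
        s2 = sorted((tuple(sorted(n.leaf_labels())), n.support)
                    for n in t2.walk() if not n.is_leaf)
        assert s1 == s2

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_support([("a", "AA"), ("b", "AA"), ("c", "AA")], 0)


class TestAssignGroups:
    def _example_tree(self):
        # ((x, exA), (y, (exB1, exB2)))
        return TreeNode(children=[
            TreeNode(children=[
                TreeNode(label="x", length=0.1),
                TreeNode(label="exA", length=0.1),
            ], length=0.2),
            TreeNode(children=[
                TreeNode(label="y", length=0.1),
                TreeNode(children=[
                    TreeNode(label="exB1", length=0.05),
                    TreeNode(label="exB2", length=0.05),
                ], length=0.1),
            ], length=0.2),
            TreeNode(label="z", length=0.9),
        ])

    def test_leaf_sister_to_exemplar_gets_its_group(self):
        groups = assign_groups(
            self._example_tree(),
            {"exA": "A", "exB1": "B", "exB2": "B"},
        )
        assert groups["x"] == "A"
        assert groups["y"] == "B"

    def test_leaf_outside_all_exemplar_clades_unassigned(self):
        groups = assign_groups(
            self._example_tree(),
            {"exA": "A", "exB1": "B", "exB2": "B"},
        )
        assert groups["z"] == "unassigned"

    def test_exemplars_keep_their_groups(self):
        groups = assign_groups(self._example_tree(), {"exA": "A"})
        assert groups["exA"] == "A"

    def test_missing_exemplar_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            assign_groups(self._example_tree(), {"ghost": "A"})


class TestAlignment:
    def test_equal_length_sequences_pass_through(self):
        seqs = [("a", "MKV"), ("b", "MRV")]
        assert ensure_alignment(seqs) == seqs

    def test_star_alignment_squares_up_with_indels(self):
        seqs = [
            ("center", "MKVLLAG"),
            ("del", "MKVAG"),
            ("same", "MKVLLAG"),
        ]
        msa = star_align(seqs)
        widths = {len(s) for _, s in msa}
        assert len(widths) == 1
        by_label = dict(msa)
        assert by_label["center"].replace("-", "") == "MKVLLAG"
        assert by_label["del"].replace("-", "") == "MKVAG"

    def test_star_alignment_preserves_identical_pairs(self):
        seqs = [("c", "MKVLLAG"), ("d", "MKVAG"), ("e", "MKVAG")]
        msa = dict(star_align(seqs))
        assert msa["d"] == msa["e"]
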