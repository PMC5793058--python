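"""Identity matrices, neighbor joining and Newick round trips."""

import numpy as np
import pytest

import corallox as cx
from corallox.errors import ContractError, FormatError
from corallox.phylo import tip_distance_matrix
from corallox.seqio import ProteinCandidate

from oracles import additive_topologies, brute_force_global_score, tree_splits


def random_additive_tree(rng, n_taxa):
    """A random binary tree with positive lengths and its distance matrix.

    Built by sequential leaf attachment; distances are accumulated path
    lengths, so the matrix is additive by construction.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency of a growing unrooted tree; nodes > n_taxa-1 are internal
    edges = {}
    next_node = n_taxa

    def add_edge(u, v, w):
        edges.setdefault(u, {})[v] = w
        edges.setdefault(v, {})[u] = w

    def lens():
        return float(rng.uniform(0.5, 5.0))

    center = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(leaf, center, lens())
    for leaf in range(3, n_taxa):
        # split a random existing edge and hang the new leaf off it
        u = int(rng.choice(list(edges)))
        v = int(rng.choice(list(edges[u])))
        w = edges[u][v]
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.2, 0.8)) * w
        del edges[u][v]
        del edges[v][u]
        add_edge(u, mid, split)
        add_edge(v, mid, w - split)
        add_edge(leaf, mid, lens())
    # all-pairs path lengths between leaves
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in edges[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    d = (d + d.T) / 2  # exact symmetry despite float summation order
    return labels, d


def matrix_from_distances(labels, d):
    return cx.IdentityMatrix(labels, 100.0 - d + np.diag(np.diag(d)))


class TestIdentityMatrix:
    def test_identical_sequences(self):
        p = [ProteinCandidate(f"s{i}", "MWLLAKHD" * 5, "as_is") for i in range(2)]
        m = cx.identity_matrix(p)
        assert m.values[0, 1] == 100.0

    def test_forced_arithmetic(self):
        p = [
            ProteinCandidate("a", "AAAA", "as_is"),
            ProteinCandidate("b", "AAAT", "as_is"),
        ]
        assert cx.identity_matrix(p).values[0, 1] == 75.0

    def test_duplicate_ids_rejected(self):
        p = [ProteinCandidate("same", "AAAA", "as_is") for _ in range(2)]
        with pytest.raises(ContractError):
            cx.identity_matrix(p)

    def test_matches_per_pair_alignment_oracle(self, rng):
        """Matrix entries equal scores/identities of independent pairwise runs."""
        seqs = [
            "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 8))))
            for _ in range(4)
        ]
        p = [ProteinCandidate(f"s{i}", s, "as_is") for i, s in enumerate(seqs)]
        m = cx.identity_matrix(p)
        for i in range(4):
            for j in range(i + 1, 4):
                aln = cx.global_align(seqs[i], seqs[j])
                assert m.values[i, j] == pytest.approx(aln.identity_pct)
                assert aln.score == pytest.approx(
                    brute_force_global_score(seqs[i], seqs[j])
                )


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0.0, 10.0, 16.0], [10.0, 0.0, 12.0], [16.0, 12.0, 0.0]])
        tree = cx.nj_tree(matrix_from_distances(labels, d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((10 + 16 - 12) / 2)
        assert lengths["B"] == pytest.approx((10 + 12 - 16) / 2)
        assert lengths["C"] == pytest.approx((16 + 12 - 10) / 2)

    def test_additive_recovery_topology_and_lengths(self, rng):
        """NJ recovers random additive trees exactly (n = 4..8)."""
        for n in range(4, 9):
            for _ in range(10):
                labels, d = random_additive_tree(rng, n)
                tree = cx.nj_tree(matrix_from_distances(labels, d))
                got = tip_distance_matrix(tree, labels)
                assert np.allclose(got, d, atol=1e-9)

    def test_five_taxon_brute_force_uniqueness(self, rng):
        """The NJ topology is the unique additive fit among all 15 topologies."""
        for _ in range(10):
            labels, d = random_additive_tree(rng, 5)
            tree = cx.nj_tree(matrix_from_distances(labels, d))
            fitting = additive_topologies(d, labels)
            assert len(fitting) == 1
            assert tree_splits(tree) == fitting[0]

    def test_planted_clades_are_separated(self):
        labels = [f"s{i}" for i in range(6)]
        v = np.full((6, 6), 35.0)
        v[:3, :3] = 85.0
        v[3:, 3:] = 85.0
        np.fill_diagonal(v, 100.0)
        tree = cx.nj_tree(cx.IdentityMatrix(labels, v))
        splits = tree_splits(tree)
        clade = frozenset({frozenset(labels[:3]), frozenset(labels[3:])})
        assert clade in splits

    def test_label_permutation_gives_isomorphic_tree(self, rng):
        labels, d = random_additive_tree(rng, 6)
        m1 = matrix_from_distances(labels, d)
        perm = rng.permutation(6)
        m2 = matrix_from_distances(
            [labels[i] for i in perm], d[np.ix_(perm, perm)]
        )
        t1, t2 = cx.nj_tree(m1), cx.nj_tree(m2)
        assert tree_splits(t1) == tree_splits(t2)
        assert np.allclose(
            tip_distance_matrix(t1, labels), tip_distance_matrix(t2, labels), atol=1e-9
        )

    def test_skbio_cross_check(self, rng):
        """Independent NJ (scikit-bio) produces the same topology."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        labels, d = random_additive_tree(rng, 7)
        ours = cx.nj_tree(matrix_from_distances(labels, d))
        theirs = skbio_nj(DistanceMatrix(d, ids=labels))
        assert tree_splits(ours) == tree_splits(theirs)

    def test_too_few_labels(self):
        m = cx.IdentityMatrix(["a", "b"], np.array([[100.0, 50.0], [50.0, 100.0]]))
        with pytest.raises(ContractError):
            cx.nj_tree(m)


class TestNewick:
    def test_three_leaf_string_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        s = cx.write_newick(cx.nj_tree(matrix_from_distances(labels, d)))
        assert s.endswith(";")
        assert set("ABC") <= set(s)

    def test_round_trip_preserves_topology_and_lengths(self, rng):
        for _ in range(25):
            labels, d = random_additive_tree(rng, int(rng.integers(4, 9)))
            tree = cx.nj_tree(matrix_from_distances(labels, d))
            back = cx.read_newick(cx.write_newick(tree))
            assert tree_splits(back) == tree_splits(tree)
            assert np.allclose(
                tip_distance_matrix(back, labels),
                tip_distance_matrix(tree, labels),
                atol=1e-6,
            )

    def test_unbalanced_parentheses_raise(self):
        with pytest.raises(FormatError):
            cx.read_newick("((A,B);")

    def test_matrix_tsv_round_trip(self, tmp_path, rng):
        labels, d = random_additive_tree(rng, 5)
        m = matrix_from_distances(labels, d)
        p = tmp_path / "idm.tsv"
        m.to_tsv(p)
        lines = p.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["label"] + labels
        assert len(lines) == 6
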