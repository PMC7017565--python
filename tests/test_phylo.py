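"""Progressive alignment, distances, neighbor-joining, bootstrap."""

import math

import numpy as np
import pytest

from sitescreen.phylo import (
    AlignParams,
    DistanceMatrix,
    MSA,
    PhyloTree,
    TreeNode,
    bootstrap,
    msa_distances,
    neighbor_joining,
    parse_newick,
    progressive_msa,
    write_newick,
)
from sitescreen.seqio import SeqRecord
from sitescreen.synthetic import diverge_family

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _prot(pid, seq):
    return SeqRecord(pid, seq, alphabet="protein")


def _additive_matrix():
    # tree ((A:2,B:3):1,(C:4,D:5)) -> unique additive distances
    d = np.array(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
    )
    return DistanceMatrix(["A", "B", "C", "D"], d)


class TestNeighborJoining:
    def test_additive_matrix_recovers_unique_topology(self):
        tree = neighbor_joining(_additive_matrix())
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_additive_matrix_path_lengths_exact(self):
        tree = neighbor_joining(_additive_matrix())
        dm = _additive_matrix()
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert tree.path_length(a, b) == pytest.approx(
                        dm.d[i, j], abs=1e-9
                    )

    def test_star_matrix_zero_internal_edge_flagged(self):
        d = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        internal = [
            n for n in _walk(tree.root) if n.children and n is not tree.root
        ]
        assert any(
            n.length == 0.0 or n.negative_length_clamped for n in internal
        )

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], d))

    def test_caterpillar_topology_recovered_from_simulation(self):
        root = _prot("root", "".join(
            AA20[i] for i in np.random.default_rng(40).integers(0, 20, 200)
        ))
        tree = _caterpillar5()
        leaves = diverge_family(root, tree, rate=0.05, seed=40)
        msa = MSA([l.id for l in leaves], [l.residues for l in leaves])
        nj = neighbor_joining(msa_distances(msa))
        assert tree.bipartitions() <= nj.bipartitions()


def _caterpillar5() -> PhyloTree:
    # (((L1,L2),L3),L4,L5) with unit branch lengths
    n12 = TreeNode(children=[TreeNode("L1", 1), TreeNode("L2", 1)], length=1)
    n123 = TreeNode(children=[n12, TreeNode("L3", 1)], length=1)
    root = TreeNode(children=[n123, TreeNode("L4", 1), TreeNode("L5", 1)])
    return PhyloTree(root)


def _walk(node):
    yield node
    for c in node.children:
        yield from _walk(c)


class TestDistances:
    def test_identical_rows_zero(self):
        msa = MSA(["a", "b"], ["MKVLA", "MKVLA"])
        # distances defined for >=2; matrix values checked directly
        assert msa_distances(msa).d[0, 1] == 0.0

    def test_p_distance_arithmetic(self):
        msa = MSA(["a", "b"], ["AAAAAAAAAA", "AAAAAAAACC"])
        assert msa_distances(msa).d[0, 1] == pytest.approx(0.2)

    def test_pairwise_deletion_of_gap_columns(self):
        msa = MSA(["a", "b"], ["AA--AAAAAA", "AACCAAAAAC"])
        # 8 compared columns, 1 mismatch
        assert msa_distances(msa).d[0, 1] == pytest.approx(1 / 8)

    def test_poisson_closed_form(self):
        msa = MSA(["a", "b"], ["AAAAAAAAAA", "AAAAAAAACC"])
        assert msa_distances(msa, "poisson").d[0, 1] == pytest.approx(
            -math.log(1 - 0.2)
        )


class TestProgressiveMSA:
    def test_identical_pair_gapless(self):
        msa = progressive_msa([_prot("a", "MKVLA"), _prot("b", "MKVLA")])
        assert msa.rows == ["MKVLA", "MKVLA"]

    def test_insertion_gapped_in_other_sequences(self):
        seqs = [
            _prot("s1", "MKVLATTGACDEFGHIKL"),
            _prot("s2", "MKVLATTGACDEFGHIKL"),
            _prot("s3", "MKVLAWWTTGACDEFGHIKL"),
        ]
        msa = progressive_msa(seqs)
        assert msa.n_cols == 20
        for label, row in zip(msa.labels, msa.rows):
            if label != "s3":
                assert "--" in row

    def test_column_count_at_least_longest_sequence(self):
        rng = np.random.default_rng(41)
        seqs = [
            _prot(f"s{i}", "".join(AA20[j] for j in rng.integers(0, 20, n)))
            for i, n in enumerate([30, 35, 40])
        ]
        msa = progressive_msa(seqs)
        assert msa.n_cols >= 40

    def test_input_order_invariance(self):
        rng = np.random.default_rng(42)
        base = "".join(AA20[i] for i in rng.integers(0, 20, 50))
        seqs = []
        for i in range(4):
            s = list(base)
            for p in rng.choice(50, size=5, replace=False):
                s[p] = AA20[int(rng.integers(0, 20))]
            seqs.append(_prot(f"s{i}", "".join(s)))
        msa1 = progressive_msa(seqs)
        msa2 = progressive_msa(list(reversed(seqs)))
        assert msa1.labels == msa2.labels
        assert msa1.rows == msa2.rows

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([_prot("a", "MKVLA")])


class TestBootstrap:
    def _clade_msa(self, seed=43, n_cols=120):
        rng = np.random.default_rng(seed)
        a = "".join(AA20[i] for i in rng.integers(0, 20, n_cols))
        b = list(a)
        for p in rng.choice(n_cols, size=n_cols // 2, replace=False):
            b[p] = AA20[int(rng.integers(0, 20))]
        b = "".join(b)

        def mutate(s, k):
            out = list(s)
            for p in rng.choice(n_cols, size=k, replace=False):
                out[p] = AA20[int(rng.integers(0, 20))]
            return "".join(out)

        rows = [a, mutate(a, 3), b, mutate(b, 3)]
        return MSA(["A1", "A2", "B1", "B2"], rows)

    def test_well_separated_clades_high_support(self):
        tree = bootstrap(self._clade_msa(), reps=100, seed=5)
        supports = [
            n.support for n in _walk(tree.root) if n.support is not None
        ]
        assert supports and all(s >= 95 for s in supports)

    def test_identical_sequences_always_sister(self):
        rng = np.random.default_rng(44)
        a = "".join(AA20[i] for i in rng.integers(0, 20, 80))
        twin = a
        others = []
        for i in range(2):
            s = list(a)
            for p in rng.choice(80, size=30, replace=False):
                s[p] = AA20[int(rng.integers(0, 20))]
            others.append("".join(s))
        msa = MSA(["T1", "T2", "X1", "X2"], [a, twin] + others)
        tree = bootstrap(msa, reps=50, seed=6)
        twins = frozenset({"X1", "X2"})  # complement side of {T1,T2}
        target = [
            n for n in _walk(tree.root)
            if n.children and frozenset(l.name for l in n.leaves()) in (
                twins, frozenset({"T1", "T2"})
            )
        ]
        assert target and all(
            n.support in (None, 100.0) for n in target
        )

    def test_supports_reproducible_under_fixed_seed(self):
        msa = self._clade_msa()
        t1 = write_newick(bootstrap(msa, reps=60, seed=9))
        t2 = write_newick(bootstrap(msa, reps=60, seed=9))
        assert t1 == t2

    def test_supports_within_0_100(self):
        tree = bootstrap(self._clade_msa(seed=45), reps=40, seed=10)
        for n in _walk(tree.root):
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0


class TestNewick:
    def test_three_leaf_shape(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        s = write_newick(tree)
        assert s.startswith("(") and s.endswith(";")
        assert all(label in s for label in "ABC")

    def test_round_trip_preserves_topology_and_supports(self):
        tree = bootstrap(
            MSA(
                ["A", "B", "C", "D"],
                ["AAAA", "AAAC", "CCCC", "CCCA"],
            ),
            reps=20,
            seed=11,
        )
        text = write_newick(tree)
        back = parse_newick(text)
        assert back.bipartitions() == tree.bipartitions()
        assert write_newick(back) == text

    def test_supports_follow_internal_closing_parens(self):
        tree = bootstrap(self._msa(), reps=20, seed=12)
        text = write_newick(tree)
        import re

        for m in re.finditer(r"\)(\d+(?:\.\d+)?):", text):
            assert 0 <= float(m.group(1)) <= 100

    def _msa(self):
        return MSA(
            ["A", "B", "C", "D"],
            ["AAAAAAAA", "AAAAAACC", "CCCCCCCC", "CCCCCCAA"],
        )
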