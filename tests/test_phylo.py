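import itertools
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from cblscreen.config import AlignConfig
from cblscreen.phylo import (
    DistanceMatrix, detect_amplification, distance_matrix, global_align,
    local_align_score, nj_tree, tree_path_lengths,
)
from cblscreen.seq_io import AMINO_ACIDS, ProteinRecord

_B62 = substitution_matrices.load("BLOSUM62")
NEG = -1e18


def gotoh_global(a: str, b: str, open_cost: float = 11.0, extend: float = 1.0) -> float:
    """Independent affine-gap global DP (gap of length k costs open + k*extend)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_cost + i * extend)
    for j in range(1, m + 1):
        Y[0][j] = -(open_cost + j * extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_cost - extend, X[i - 1][j] - extend)
            Y[i][j] = max(M[i][j - 1] - open_cost - extend, Y[i][j - 1] - extend)
    return max(M[n][m], X[n][m], Y[n][m])


def gotoh_local(a: str, b: str, open_cost: float = 11.0, extend: float = 1.0) -> float:
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], X[i - 1][j - 1],
                                   Y[i - 1][j - 1]) + s)
            X[i][j] = max(M[i - 1][j] - open_cost - extend, X[i - 1][j] - extend)
            Y[i][j] = max(M[i][j - 1] - open_cost - extend, Y[i][j - 1] - extend)
            best = max(best, M[i][j])
    return best


def random_seq(rng, lo=10, hi=40):
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(lo, hi)))


class TestGlobalAlign:
    def test_self_alignment_identity_one(self):
        _, identity = global_align("MGCF", "MGCF")
        assert identity == 1.0

    def test_hand_dp_on_three_mers(self):
        # no gap opened: s(M,M) + s(K,R) + s(V,V) = 5 + 2 + 4
        score, identity = global_align("MKV", "MRV")
        assert score == 11.0
        assert identity == pytest.approx(2 / 3)

    def test_symmetry(self, rng):
        for _ in range(100):
            a, b = random_seq(rng, 5, 25), random_seq(rng, 5, 25)
            assert global_align(a, b)[0] == global_align(b, a)[0]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MKV")

    def test_matches_gotoh_oracle(self, rng):
        for _ in range(30):
            a, b = random_seq(rng), random_seq(rng)
            score, _ = global_align(a, b)
            assert score == pytest.approx(gotoh_global(a, b))

    def test_local_matches_gotoh_oracle(self, rng):
        for _ in range(30):
            a, b = random_seq(rng), random_seq(rng)
            assert local_align_score(a, b) == pytest.approx(gotoh_local(a, b))


class TestDistanceMatrix:
    def recs(self, seqs):
        return [ProteinRecord(id=f"r{i}", sequence=s) for i, s in enumerate(seqs)]

    def test_identical_sequences_distance_zero(self):
        dm = distance_matrix(self.recs(["MGCFKV"] * 3))
        assert np.allclose(dm.d, 0.0)

    def test_matches_per_pair_recomputation(self, rng):
        records = self.recs([random_seq(rng, 15, 30) for _ in range(5)])
        dm = distance_matrix(records)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                _, ident = global_align(records[i].sequence, records[j].sequence)
                assert dm.d[i, j] == pytest.approx(1 - ident)

    def test_permutation_equivariance(self, rng):
        records = self.recs([random_seq(rng, 15, 30) for _ in range(4)])
        dm = distance_matrix(records)
        perm = [2, 0, 3, 1]
        dm2 = distance_matrix([records[i] for i in perm])
        for a, i in enumerate(perm):
            for b, j in enumerate(perm):
                assert dm2.d[a, b] == pytest.approx(dm.d[i, j])

    def test_duplicate_ids_rejected(self):
        records = [ProteinRecord(id="x", sequence="MK"),
                   ProteinRecord(id="x", sequence="MR")]
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix(records)


def random_additive_matrix(rng, n):
    """Random binary tree with random branch lengths; returns (labels, D)."""
    labels = [f"t{i}" for i in range(n)]
    nodes = {label: None for label in labels}
    # adjacency with branch lengths
    adj: dict[str, list[tuple[str, float]]] = {label: [] for label in labels}
    pool = labels[:]
    counter = 0
    while len(pool) > 2:
        a, b = rng.sample(pool, 2)
        new = f"i{counter}"
        counter += 1
        adj[new] = []
        for child in (a, b):
            w = rng.uniform(0.1, 2.0)
            adj[new].append((child, w))
            adj[child].append((new, w))
            pool.remove(child)
        pool.append(new)
    w = rng.uniform(0.1, 2.0)
    a, b = pool
    adj[a].append((b, w))
    adj[b].append((a, w))

    def path_len(src, dst):
        stack = [(src, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == dst:
                return dist
            for nxt, w in adj[node]:
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
        raise AssertionError("disconnected")

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = path_len(labels[i], labels[j])
    return labels, D


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered(self):
        labels = ("A", "B", "C", "D")
        D = np.array([[0., 3., 7., 8.],
                      [3., 0., 6., 7.],
                      [7., 6., 0., 3.],
                      [8., 7., 3., 0.]])
        tree = nj_tree(DistanceMatrix(labels=labels, d=D))
        paths = tree_path_lengths(tree)
        for i, j in itertools.combinations(range(4), 2):
            assert paths[frozenset((labels[i], labels[j]))] == pytest.approx(D[i, j])

    def test_three_leaves_closed_form(self):
        labels = ("a", "b", "c")
        D = np.array([[0., 2., 3.], [2., 0., 5.], [3., 5., 0.]])
        tree = nj_tree(DistanceMatrix(labels=labels, d=D))
        paths = tree_path_lengths(tree)
        assert paths[frozenset(("a", "b"))] == pytest.approx(2.0)
        assert paths[frozenset(("a", "c"))] == pytest.approx(3.0)
        assert paths[frozenset(("b", "c"))] == pytest.approx(5.0)

    def test_too_few_taxa_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=("a", "b"), d=D))

    def test_label_order_invariance(self, rng):
        labels, D = random_additive_matrix(rng, 6)
        base = tree_path_lengths(nj_tree(DistanceMatrix(labels=tuple(labels), d=D)))
        perm = list(range(6))
        rng.shuffle(perm)
        D2 = D[np.ix_(perm, perm)]
        labels2 = tuple(labels[i] for i in perm)
        permuted = tree_path_lengths(nj_tree(DistanceMatrix(labels=labels2, d=D2)))
        assert base.keys() == permuted.keys()
        for key in base:
            assert permuted[key] == pytest.approx(base[key])

    def test_exact_on_random_additive_matrices(self, rng):
        """NJ reconstructs path lengths of 100 random additive matrices."""
        for _ in range(100):
            n = rng.randint(4, 8)
            labels, D = random_additive_matrix(rng, n)
            tree = nj_tree(DistanceMatrix(labels=tuple(labels), d=D))
            paths = tree_path_lengths(tree)
            for i, j in itertools.combinations(range(n), 2):
                assert abs(paths[frozenset((labels[i], labels[j]))] - D[i, j]) < 1e-9


def oracle_amplification(tree, species_of):
    """All-edges bipartition scan, coded independently."""
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    sides = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.append(below)
        sides.append(frozenset(leaves) - below)
    flagged = []
    species_leaves = {}
    for leaf in leaves:
        species_leaves.setdefault(species_of[leaf], set()).add(leaf)
    for sp in sorted(species_leaves):
        mine = frozenset(species_leaves[sp])
        if len(mine) >= 2 and any(side == mine for side in sides):
            flagged.append(sp)
    return flagged


class TestAmplification:
    def build_tree(self, newick):
        import dendropy
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_paralog_clade_flagged(self):
        tree = self.build_tree(
            "((p1:1,(p2:1,(p3:1,p4:1):1):1):2,(q1:1,q2:5):1,r1:3);")
        species = {f"p{i}": "tvag" for i in range(1, 5)}
        species.update({"q1": "ngru", "q2": "acan", "r1": "atha"})
        flagged = detect_amplification(tree, species)
        assert flagged == [("tvag", ("p1", "p2", "p3", "p4"))]

    def test_singletons_not_flagged(self):
        tree = self.build_tree("(a:1,b:1,c:1);")
        assert detect_amplification(tree, {"a": "s1", "b": "s2", "c": "s3"}) == []

    def test_interleaved_species_not_flagged(self):
        tree = self.build_tree("((a1:1,b1:1):1,(a2:1,b2:1):1,c:1);")
        species = {"a1": "sa", "a2": "sa", "b1": "sb", "b2": "sb", "c": "sc"}
        assert detect_amplification(tree, species) == []

    def test_unmapped_leaf_rejected(self):
        tree = self.build_tree("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="without species"):
            detect_amplification(tree, {"a": "s1", "b": "s2"})

    def test_matches_bipartition_oracle(self, rng):
        for _ in range(25):
            n = rng.randint(4, 9)
            labels, D = random_additive_matrix(rng, n)
            tree = nj_tree(DistanceMatrix(labels=tuple(labels), d=D))
            species = {label: f"sp{rng.randint(0, 2)}" for label in labels}
            got = [sp for sp, _ in detect_amplification(tree, species)]
            assert got == oracle_amplification(tree, species)
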