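"""Distance-based grouping of candidate sensors and paralog-expansion flags.

Pairwise global alignment identity supplies a bounded distance in [0, 1];
neighbor joining (exact on additive matrices) supplies the grouping; a
species whose paralogs form a monospecific clade on the unrooted tree -- an
edge whose removal isolates exactly that species' leaves -- is flagged as an
intraspecific gene amplification, the pattern reported for the multi-CBL
genomes (e.g. the four-gene Trichomonas vaginalis case).  This distance/NJ
grouping is a deliberately lightweight stand-in for full Bayesian tree
inference, which is out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .config import AlignConfig
from .seq_io import ProteinRecord


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix entries must be finite")


def _make_aligner(config: AlignConfig, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    # a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def global_align(a: str, b: str, config: AlignConfig | None = None
                 ) -> tuple[float, float]:
    """Needleman-Wunsch with affine gaps; returns (score, identity fraction).

    Identity counts matches over all alignment columns, so gap columns count
    as non-matches: length heterogeneity lowers identity, which is the
    desired behaviour for loop-insertion variants.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    config = config or AlignConfig()
    aligner = _make_aligner(config, "global")
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    identity = counts.identities / alignment.length
    return float(alignment.score), float(identity)


def local_align_score(a: str, b: str, config: AlignConfig | None = None) -> float:
    """Best Smith-Waterman local-alignment score with the same parameters."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    config = config or AlignConfig()
    return float(_make_aligner(config, "local").score(a, b))


def distance_matrix(records: Sequence[ProteinRecord],
                    config: AlignConfig | None = None) -> DistanceMatrix:
    """Pairwise distance d = 1 - identity (each pair aligned once).

    With ``poisson_correction`` enabled the distance is -ln(identity)
    instead (unbounded; off by default).
    """
    config = config or AlignConfig()
    labels = tuple(r.id for r in records)
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate record ids in distance matrix input")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, identity = global_align(records[i].sequence, records[j].sequence, config)
            if config.poisson_correction:
                dist = -math.log(max(identity, 1e-9))
            else:
                dist = 1.0 - identity
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, d=d)


def _three_leaf_lengths(d: np.ndarray) -> tuple[float, float, float]:
    """Closed-form star lengths for three taxa, clamped at zero."""
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    return max(la, 0.0), max(lb, 0.0), max(lc, 0.0)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Negative limb lengths are clamped to zero with the deficit transferred to
    the sibling limb (then clamped as well).  Ties in the Q criterion are
    broken by the lexicographically smallest (representative label) pair,
    where a cluster is represented by its smallest leaf label, so the result
    is independent of input label order.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    reps: dict[str, str] = {}
    for label in dm.labels:
        taxon = taxa.new_taxon(label)
        node = dendropy.Node(taxon=taxon)
        nodes[label] = node
        reps[label] = label
    # work on a label-keyed distance dict for clarity at these problem sizes
    dist: dict[frozenset, float] = {}
    active = list(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.labels[i], dm.labels[j]))] = float(dm.d[i, j])

    def d_of(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    counter = 0
    while len(active) > 3:
        m = len(active)
        totals = {a: sum(d_of(a, b) for b in active if b != a) for a in active}
        best = None
        for ia in range(m):
            for ib in range(ia + 1, m):
                a, b = active[ia], active[ib]
                q = (m - 2) * d_of(a, b) - totals[a] - totals[b]
                key = tuple(sorted((reps[a], reps[b])))
                cand = (q, key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        dab = d_of(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        new_label = f"__internal_{counter}"
        counter += 1
        nodes[new_label] = parent
        reps[new_label] = min(reps[a], reps[b])
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_label, c))] = 0.5 * (d_of(a, c) + d_of(b, c) - dab)
        active = [c for c in active if c not in (a, b)]
        active.append(new_label)

    a, b, c = sorted(active, key=lambda x: reps[x])
    sub = np.array([[0.0, d_of(a, b), d_of(a, c)],
                    [d_of(a, b), 0.0, d_of(b, c)],
                    [d_of(a, c), d_of(b, c), 0.0]])
    la, lb, lc = _three_leaf_lengths(sub)
    root = dendropy.Node()
    for label, length in ((a, la), (b, lb), (c, lc)):
        nodes[label].edge.length = length
        root.add_child(nodes[label])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_path_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Leaf-to-leaf patristic distances, keyed by frozenset of leaf labels."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = [leaf.taxon for leaf in tree.leaf_node_iter()]
    out = {}
    for i, t1 in enumerate(leaves):
        for t2 in leaves[i + 1:]:
            out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


def detect_amplification(tree: dendropy.Tree, species_of: Mapping[str, str]
                         ) -> list[tuple[str, tuple[str, ...]]]:
    """Species whose paralogs form a monospecific clade on the unrooted tree.

    For each species with at least two leaves, reports the species iff some
    edge's removal isolates exactly that species' leaves.  Output sorted by
    species name.
    """
    leaf_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unmapped = [l for l in leaf_labels if l not in species_of]
    if unmapped:
        raise ValueError(f"leaves without species mapping: {unmapped}")
    all_leaves = frozenset(leaf_labels)
    by_species: dict[str, set[str]] = {}
    for label in leaf_labels:
        by_species.setdefault(species_of[label], set()).add(label)

    clades: set[frozenset] = set()
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        clades.add(below)
        clades.add(all_leaves - below)

    flagged = []
    for species in sorted(by_species):
        leaves = frozenset(by_species[species])
        if len(leaves) >= 2 and leaves in clades:
            flagged.append((species, tuple(sorted(leaves))))
    return flagged
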