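"""Distance-based phylogenetics for duplicated gene families.

Kimura 2-parameter (K2P) distances with pairwise deletion, neighbor-joining
(NJ) tree construction, nonparametric bootstrap supports, and a
within/between-species distance statistic that formalizes the concerted
evolution signal: paralogs homogenized by interlocus gene conversion are
more similar within a species than to their orthologs in another species
(W/B ratio < 1 and per-species monophyly on the NJ tree).

K2P separates transition (P) and transversion (Q) proportions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Pairwise deletion drops, for each sequence pair independently, every site
where either member carries a gap or an ambiguity code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import dendropy
import numpy as np

from .io_formats import MultipleAlignment

__all__ = [
    "DistanceSaturationError",
    "K2PResult",
    "DistanceMatrix",
    "ConcertedStat",
    "k2p_distance",
    "p_distance_matrix",
    "distance_matrix",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
    "concerted_stat",
]

logger = logging.getLogger(__name__)

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class DistanceSaturationError(ValueError):
    """Observed divergence too high for the K2P correction (log of a
    non-positive number)."""


class K2PResult(NamedTuple):
    d: float
    P: float
    Q: float
    sites_used: int


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with per-pair usable-site counts."""

    labels: list[str]
    d: np.ndarray
    sites_used: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


def _encode(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and every gap or ambiguity code to -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, code in _ENCODE.items():
        out[arr == ord(base)] = code
    return out


def _k2p_from_encoded(a: np.ndarray, b: np.ndarray) -> K2PResult:
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise DistanceSaturationError("no comparable (ungapped, unambiguous) sites")
    av, bv = a[valid], b[valid]
    diff = av != bv
    # purines (A=0, G=2) are even, pyrimidines (C=1, T=3) odd: a substitution
    # within a parity class is a transition, across classes a transversion
    transitions = int((diff & ((av & 1) == (bv & 1))).sum())
    transversions = int((diff & ((av & 1) != (bv & 1))).sum())
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise DistanceSaturationError(
            f"saturated pair (P={P:.4f}, Q={Q:.4f}): K2P distance undefined"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(d=d, P=P, Q=Q, sites_used=n)


def k2p_distance(seq1: str, seq2: str) -> K2PResult:
    """K2P distance between two aligned nucleotide sequences with pairwise
    deletion of gapped/ambiguous sites."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    return _k2p_from_encoded(_encode(seq1), _encode(seq2))


def _encoded_alignment(alignment: MultipleAlignment) -> np.ndarray:
    return np.stack([_encode(rec.sequence) for rec in alignment.records])


def _matrix_from_encoded(encoded: np.ndarray, labels: list[str]) -> DistanceMatrix:
    n = encoded.shape[0]
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        sites[i, i] = encoded.shape[1]
        for j in range(i + 1, n):
            try:
                res = _k2p_from_encoded(encoded[i], encoded[j])
            except DistanceSaturationError:
                saturated.append((labels[i], labels[j]))
                continue
            d[i, j] = d[j, i] = res.d
            sites[i, j] = sites[j, i] = res.sites_used
    if saturated:
        raise DistanceSaturationError(f"saturated pairs: {saturated}")
    return DistanceMatrix(labels, d, sites)


def distance_matrix(alignment: MultipleAlignment) -> DistanceMatrix:
    """All-pairs K2P distances for an alignment of >= 3 sequences."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    return _matrix_from_encoded(_encoded_alignment(alignment), alignment.labels)


def p_distance_matrix(alignment: MultipleAlignment) -> DistanceMatrix:
    """Uncorrected proportion-different distances (pairwise deletion over
    gap characters); the fallback for protein alignments, where the K2P
    nucleotide model does not apply."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    rows = [
        np.frombuffer(rec.sequence.upper().encode("ascii"), dtype=np.uint8)
        for rec in alignment.records
    ]
    arr = np.stack(rows)
    invalid = (arr == ord("-")) | (arr == ord("X")) | (arr == ord("?"))
    n = arr.shape[0]
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        sites[i, i] = arr.shape[1]
        for j in range(i + 1, n):
            valid = ~(invalid[i] | invalid[j])
            m = int(valid.sum())
            if m == 0:
                raise DistanceSaturationError("no comparable sites")
            d[i, j] = d[j, i] = float((arr[i, valid] != arr[j, valid]).sum()) / m
            sites[i, j] = sites[j, i] = m
    return DistanceMatrix(alignment.labels, d, sites)


# ---------------------------------------------------------------------------
# Neighbor-joining

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining on the Q-criterion.

    Deterministic across platforms: ties in the Q-criterion are broken by
    the lexicographically smallest pair of cluster representative labels
    (a cluster is represented by its smallest leaf label). Negative branch
    length estimates are clamped to zero with the length transferred to the
    sibling branch, so pairwise path lengths through each join are
    preserved. Exact on additive matrices.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
    reps = list(dm.labels)
    D = dm.d.astype(float).copy()

    def join(i: int, j: int, li: float, lj: float) -> None:
        # clamp negatives, transferring length to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        del nodes[j], reps[j]

    while D.shape[0] > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        # (r_i + r_j) summed first keeps Q exactly symmetric in floating point
        Q = (m - 2) * D - (r[:, None] + r[None, :])
        iu = np.triu_indices(m, 1)
        qmin = Q[iu].min()
        candidates = [
            tuple(sorted((reps[i], reps[j]))) + (int(i), int(j))
            for i, j in zip(*iu)
            if Q[i, j] == qmin
        ]
        _, _, i, j = min(candidates)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        join(i, j, li, lj)
        # row/col i becomes the merged cluster; drop j
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)

    # resolve the final three clusters around a central node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    center = dendropy.Node()
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = max(0.0, length)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits of an unrooted tree, each normalized to the side
    not containing the lexicographically smallest leaf label."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(leaves)
    n = len(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = below if ref not in below else leaves - below
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def bootstrap_support(
    alignment: MultipleAlignment, n_replicates: int = 500, seed: int = 0
) -> dendropy.Tree:
    """NJ tree of the full alignment with internal nodes labeled by the
    percentage of column-resampled replicates containing each split.

    Replicates in which some pair saturates are skipped (counted in the
    returned tree's ``bootstrap_skipped`` attribute, with a warning);
    supports are percentages of the completed replicates.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    encoded = _encoded_alignment(alignment)
    labels = alignment.labels
    tree = nj_tree(_matrix_from_encoded(encoded, labels))
    # only splits on internal branches of positive length are resolved;
    # an alignment of identical sequences yields no supports at all
    leaves_all = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref_label = min(leaves_all)
    n_leaves = len(leaves_all)
    reference_splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        if not node.edge.length or node.edge.length <= 0:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = frozenset(below if ref_label not in below else leaves_all - below)
        if 2 <= len(side) <= n_leaves - 2:
            reference_splits.add(side)
    counts = {split: 0 for split in reference_splits}
    rng = np.random.default_rng(seed)
    n_sites = encoded.shape[1]
    skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        try:
            rep_dm = _matrix_from_encoded(encoded[:, cols], labels)
        except DistanceSaturationError:
            skipped += 1
            continue
        rep_splits = tree_bipartitions(nj_tree(rep_dm))
        for split in reference_splits & rep_splits:
            counts[split] += 1
    completed = n_replicates - skipped
    if skipped:
        logger.warning("bootstrap: %d of %d replicates skipped (saturation)", skipped, n_replicates)
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(leaves)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = frozenset(below if ref not in below else leaves - below)
        if side in counts and completed > 0:
            node.label = str(round(100.0 * counts[side] / completed))
    tree.bootstrap_skipped = skipped
    tree.bootstrap_completed = completed
    return tree


# ---------------------------------------------------------------------------
# Concerted evolution statistic

@dataclass
class ConcertedStat:
    """Mean within-species (W) vs between-species (B) pairwise distance.

    ``ratio = W/B < 1`` together with per-species monophyly on the NJ tree
    is the signature of concerted evolution: gene conversion homogenizes
    paralogs within each lineage, so copies cluster by species instead of
    by orthology.
    """

    W: float
    B: float
    ratio: float
    within_species_monophyly: dict[str, bool]


def concerted_stat(
    dm: DistanceMatrix,
    species_labels: Sequence[str],
    paralog_labels: Sequence[str] | None = None,
) -> ConcertedStat:
    n = len(dm.labels)
    if len(species_labels) != n:
        raise ValueError("one species label per matrix row required")
    species = list(species_labels)
    if len(set(species)) < 2:
        raise ValueError("need at least two species")
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if species[i] == species[j] else between).append(dm.d[i, j])
    if not within:
        raise ValueError("no within-species pairs (every species has a single copy)")
    W = float(np.mean(within))
    B = float(np.mean(between)) if between else 0.0
    ratio = W / B if B > 0 else float("nan")

    splits = tree_bipartitions(nj_tree(dm))
    leaves = set(dm.labels)
    monophyly = {}
    for sp in sorted(set(species)):
        members = frozenset(l for l, s in zip(dm.labels, species) if s == sp)
        if len(members) == 1 or len(members) == n - 1:
            monophyly[sp] = True
        else:
            monophyly[sp] = members in splits or frozenset(leaves - members) in splits
    return ConcertedStat(W=W, B=B, ratio=ratio, within_species_monophyly=monophyly)
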