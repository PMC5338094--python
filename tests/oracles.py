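"""Independent brute-force oracles used only by the tests.

Kept deliberately naive: exhaustive topology enumeration with least-squares
branch fitting, exhaustive enumeration of affine-gap alignments, and a regex
PAM scan. None of these share code with the implementations they check.
"""

from __future__ import annotations

import math
import re
from itertools import combinations

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Unrooted topology enumeration + least-squares identification

def enumerate_unrooted_topologies(labels):
    """Yield every unrooted binary topology on the labels as an edge list.

    Nodes are the leaf labels plus integer internal nodes.
    """
    if len(labels) < 3:
        raise ValueError("need >= 3 leaves")
    base = [(labels[0], 0), (labels[1], 0), (labels[2], 0)]

    def insert(edges, next_internal, remaining):
        if not remaining:
            yield edges
            return
        leaf, rest = remaining[0], remaining[1:]
        for k, (u, v) in enumerate(edges):
            mid = next_internal
            new_edges = edges[:k] + edges[k + 1 :] + [(u, mid), (mid, v), (leaf, mid)]
            yield from insert(new_edges, next_internal + 1, rest)

    yield from insert(base, 1, list(labels[3:]))


def topology_splits(edges, labels):
    """Non-trivial splits of an edge-list topology, normalized to the side
    without the lexicographically smallest label."""
    adjacency: dict = {}
    for u, v in edges:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)
    ref = min(labels)
    n = len(labels)
    splits = set()
    for u, v in edges:
        seen = {u}
        stack = [u]
        while stack:
            node = stack.pop()
            for nbr in adjacency[node]:
                if node == u and nbr == v:
                    continue
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        side = {x for x in seen if x in set(labels)}
        if ref in side:
            side = set(labels) - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def lstsq_residual(edges, labels, D):
    """Least-squares residual of fitting branch lengths of a topology to a
    distance matrix; ~0 iff the matrix is additive on that topology."""
    adjacency: dict = {}
    for idx, (u, v) in enumerate(edges):
        adjacency.setdefault(u, []).append((v, idx))
        adjacency.setdefault(v, []).append((u, idx))

    def path_edges(a, b):
        stack = [(a, [])]
        seen = {a}
        while stack:
            node, path = stack.pop()
            if node == b:
                return path
            for nbr, idx in adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append((nbr, path + [idx]))
        raise RuntimeError("disconnected topology")

    pairs = list(combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for idx in path_edges(labels[i], labels[j]):
            A[row, idx] = 1.0
        y[row] = D[i, j]
    _, residuals, _, _ = np.linalg.lstsq(A, y, rcond=None)
    if residuals.size:
        return float(residuals[0])
    fit = A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(((fit - y) ** 2).sum())


def best_topology_splits(labels, D):
    """Splits of the unique topology on which D is additive (enumeration)."""
    best = None
    best_res = math.inf
    for edges in enumerate_unrooted_topologies(labels):
        res = lstsq_residual(edges, labels, D)
        if res < best_res:
            best_res = res
            best = edges
    assert best_res < 1e-8, "matrix not additive on any enumerated topology"
    return topology_splits(best, labels)


# ---------------------------------------------------------------------------
# Exhaustive affine-gap global alignment

def exhaustive_alignment_score(ref, read, match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0):
    """Best global alignment score by enumerating every alignment path.

    A gap of length L costs gap_open + L * gap_extend. Exponential; only
    for sequences of length <= ~7.
    """
    best = -math.inf

    def rec(i, j, prev, score):
        nonlocal best
        if i == len(ref) and j == len(read):
            best = max(best, score)
            return
        if i < len(ref) and j < len(read):
            s = match if ref[i] == read[j] else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(ref):
            cost = gap_extend if prev == "D" else gap_open + gap_extend
            rec(i + 1, j, "D", score + cost)
        if j < len(read):
            cost = gap_extend if prev == "I" else gap_open + gap_extend
            rec(i, j + 1, "I", score + cost)

    rec(0, 0, None, 0.0)
    return best


# ---------------------------------------------------------------------------
# Regex spacer scan

def regex_spacer_scan(seq, spacer_length=19, pam="NGG"):
    """All (position, strand) spacer+PAM hits via regex lookahead."""
    pam_re = pam.replace("N", "[ACGT]")
    pattern = re.compile(rf"(?=([ACGT]{{{spacer_length}}}){pam_re})")
    seq = seq.upper()
    L = len(seq)
    hits = []
    for m in pattern.finditer(seq):
        hits.append((m.start(), "+", m.group(1)))
    rc = seq.translate(_COMPLEMENT)[::-1]
    for m in pattern.finditer(rc):
        hits.append((L - m.start() - spacer_length, "-", m.group(1)))
    return sorted(hits)
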