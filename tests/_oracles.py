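"""Independent brute-force oracles used to validate the library implementations.

These are deliberately naive re-derivations (exhaustive dynamic programming,
subset enumeration, direct vector geometry) kept separate from the package so
that each check compares two independent routes to the same quantity.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def gotoh_global_score(a: str, b: str, open_cost: float = 11.0,
                       extend_cost: float = 1.0) -> float:
    """Optimal global affine-gap alignment score by explicit Gotoh DP.

    A gap of length k costs open + (k-1)*extend; insertions and deletions
    may be adjacent (all-state transitions), matching the aligner under test.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, m + 1):
        Y[0][j] = -open_cost - (j - 1) * extend_cost
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = float(_BLOSUM62[a[i - 1], b[j - 1]])
                M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if i > 0:
                X[i][j] = max(
                    X[i][j],
                    M[i - 1][j] - open_cost,
                    X[i - 1][j] - extend_cost,
                    Y[i - 1][j] - open_cost,
                )
            if j > 0:
                Y[i][j] = max(
                    Y[i][j],
                    M[i][j - 1] - open_cost,
                    X[i][j - 1] - open_cost,
                    Y[i][j - 1] - extend_cost,
                )
    return max(M[n][m], X[n][m], Y[n][m])


def dollo_min_losses(tree, present: set[str]) -> int:
    """Minimum subtree deletions below the MRCA explaining all absences.

    Brute force: enumerate subsets of entirely-absent nodes by increasing
    size until one covers exactly the absence leaves under the MRCA.
    Only suitable for small trees (<= ~12 leaves).
    """
    tree.is_rooted = True
    leaves = [l for l in tree.leaf_node_iter()]
    taxa = [l.taxon for l in leaves if l.label in present]
    if len(taxa) == 1:
        return 0
    mrca = tree.mrca(taxa=taxa)

    def leafset(node) -> frozenset:
        return frozenset(l.label for l in node.leaf_iter())

    absent_under = leafset(mrca) - present
    if not absent_under:
        return 0
    candidates = [
        node
        for node in mrca.preorder_iter()
        if node is not mrca and leafset(node) <= absent_under
    ]
    for k in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            covered = frozenset().union(*(leafset(n) for n in combo))
            if covered == absent_under:
                return k
    raise AssertionError("no cover found; tree inconsistent")


def hbond_decision(
    donor: np.ndarray,
    hydrogens: list[np.ndarray],
    acceptor: np.ndarray,
    da_max: float = 3.0,
    max_deviation: float = 20.0,
) -> bool:
    """Direct geometric hydrogen-bond decision (distance + linearity)."""
    d = math.dist(donor, acceptor)
    if d >= da_max:
        return False
    for h in hydrogens:
        v1 = np.asarray(donor) - np.asarray(h)
        v2 = np.asarray(acceptor) - np.asarray(h)
        cosang = float(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        )
        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if 180.0 - angle <= max_deviation:
            return True
    return False


def all_pairs_min_distance(xyz_a: np.ndarray, xyz_b: np.ndarray) -> float:
    """Exhaustive minimum pairwise distance (no vectorisation shortcuts)."""
    best = float("inf")
    for p in xyz_a:
        for q in xyz_b:
            best = min(best, math.dist(p, q))
    return best
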