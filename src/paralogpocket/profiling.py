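"""Phyletic profiles, Dollo birth-node inference and distance trees.

A phyletic profile records, for each ortholog family, its copy count in
every genome at the leaves of a genome tree.  Under the single-gain (Dollo)
assumption — a family arises once and can only be lost — the family's birth
node is the most recent common ancestor (MRCA) of the genomes that carry it,
and the minimum number of loss events is the number of maximal all-absent
subtrees below that node.  Violations of the single-gain assumption surface
as implausibly high implied-loss counts and are left to the caller to judge.

``nj_tree`` provides a neighbor-joining tree (midpoint-rooted) from a
distance matrix, for guide/cluster trees; protein distances can be corrected
for multiple hits with the 20-state Jukes–Cantor-style formula
d = -19/20 * ln(1 - 20 p / 19).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .seqsim import label_tree


@dataclass
class BirthEvent:
    """Inferred single-gain origin of a family."""

    family: str
    node: str
    implied_losses: int


def build_profile(
    ortholog_families: dict[str, set[str]], tree: dendropy.Tree
) -> pd.DataFrame:
    """Presence/copy-count matrix (families x tree leaves).

    ``ortholog_families`` maps family -> genomes carrying it; a genome may
    appear once per copy if counts are wanted, so values may be passed as
    either sets (presence) or lists (with multiplicity).
    """
    leaves = [leaf.label for leaf in tree.leaf_node_iter()]
    leaf_set = set(leaves)
    offenders = sorted(
        {g for members in ortholog_families.values() for g in members} - leaf_set
    )
    if offenders:
        raise ValueError(f"genomes not in tree: {offenders}")
    profile = pd.DataFrame(
        0, index=sorted(ortholog_families), columns=leaves, dtype=int
    )
    for family, members in ortholog_families.items():
        for genome in members:
            profile.loc[family, genome] += 1
    return profile


def profile_from_counts(
    counts: dict[str, dict[str, int]], tree: dendropy.Tree
) -> pd.DataFrame:
    """Profile from per-genome {family: count} maps (e.g. simulator truth)."""
    members: dict[str, list[str]] = {}
    for genome, fams in counts.items():
        for family, k in fams.items():
            members.setdefault(family, []).extend([genome] * k)
    return build_profile(members, tree)


def _absent_subtree_count(node: dendropy.Node, present: set[str]) -> tuple[bool, int]:
    """(subtree entirely absent?, number of maximal all-absent subtrees)."""
    if node.is_leaf():
        absent = node.label not in present
        return absent, 0
    child_states = [_absent_subtree_count(c, present) for c in node.child_nodes()]
    if all(a for a, _ in child_states):
        return True, 0
    losses = 0
    for (absent, sub_losses), _child in zip(child_states, node.child_nodes()):
        losses += 1 if absent else sub_losses
    return False, losses


def infer_birth_node(
    profile_row: pd.Series, tree: dendropy.Tree, family: str | None = None
) -> BirthEvent:
    """Single-gain (Dollo) birth node and minimal implied losses for one family.

    The birth node is the MRCA of all presence leaves; the implied losses are
    the minimum number of subtree deletions below it that explain every
    absence leaf under it.
    """
    present = {g for g, count in profile_row.items() if count > 0}
    if not present:
        raise ValueError("family has no presence leaves")
    tree.is_rooted = True
    label_tree(tree)
    if len(present) == 1:
        node = next(l for l in tree.leaf_node_iter() if l.label in present)
    else:
        taxa = [l.taxon for l in tree.leaf_node_iter() if l.label in present]
        node = tree.mrca(taxa=taxa)
    _, losses = _absent_subtree_count(node, present)
    return BirthEvent(
        family=family or str(profile_row.name), node=node.label, implied_losses=losses
    )


def count_events(profile: pd.DataFrame, tree: dendropy.Tree) -> pd.DataFrame:
    """Per-family event summary plus the fraction of paralog-bearing genomes.

    Duplications are attributed leaf-wise as sum(max(0, count - 1)); births
    are 1 per present family (single-gain); losses come from
    :func:`infer_birth_node`.  The returned frame carries an attribute
    ``fraction_paralogous``: the fraction of genomes whose total copy count
    across families is >= 2.
    """
    rows = []
    for family in profile.index:
        row = profile.loc[family]
        if (row > 0).any():
            birth = infer_birth_node(row, tree, family)
            births, losses, node = 1, birth.implied_losses, birth.node
        else:
            births, losses, node = 0, 0, ""
        duplications = int((row - 1).clip(lower=0).sum())
        rows.append(
            {
                "family": family,
                "birth_node": node,
                "births": births,
                "losses": losses,
                "duplications": duplications,
            }
        )
    out = pd.DataFrame(rows).set_index("family")
    totals = profile.sum(axis=0)
    out.attrs["fraction_paralogous"] = float((totals >= 2).mean())
    return out


def jukes_cantor_protein(p: float) -> float:
    """Multiple-hit corrected distance for the 20-state uniform model."""
    if not 0 <= p < 19 / 20:
        raise ValueError("observed difference fraction must lie in [0, 0.95)")
    return -19.0 / 20.0 * np.log(1.0 - 20.0 * p / 19.0)


def nj_tree(distance_matrix: np.ndarray | pd.DataFrame, labels=None) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix, midpoint-rooted.

    Additive matrices are recovered exactly (standard NJ guarantee).
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        matrix = distance_matrix.to_numpy(dtype=float)
    else:
        matrix = np.asarray(distance_matrix, dtype=float)
        if labels is None:
            labels = [f"T{i}" for i in range(matrix.shape[0])]
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T) or not np.allclose(np.diag(matrix), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for label, row in zip(labels, matrix):
        buf.write(label + "," + ",".join(f"{v:.12g}" for v in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    tree.reroot_at_midpoint(update_bipartitions=True)
    for leaf in tree.leaf_node_iter():
        leaf.label = leaf.taxon.label
    return tree
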