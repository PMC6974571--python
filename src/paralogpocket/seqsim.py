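"""Simulate a gene family evolving on a genome tree.

The generator emulates the evolutionary regime of tandem chemoreceptor
paralogs: a family expanding and contracting by whole-gene duplication, loss
and pseudogenization along a genome tree, with strong rate heterogeneity
between a fast-evolving "sensory" segment and a conserved "signaling"
segment, and a near-invariant ligand-binding motif planted inside the
sensory segment.

Substitutions follow a uniform replacement model among the 20 residues with
per-segment rate scaling; duplications copy the entire gene into the same
genome (tandem arrangement); losses remove a copy and its descendants;
pseudogenization flags a copy (heritably) without removing it.  Every event
is logged against the branch on which it occurred, and the truth tables
(birth nodes, redundancy clusters, copy counts) emitted alongside the
sequences let downstream inference be validated exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

from .homology import AssemblyLevel, SequenceRecord

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

SEGMENT_NAMES = ("sensory", "signaling", "other")


def segments_from_intervals(
    length: int, sensory: tuple[int, int], signaling: tuple[int, int]
) -> dict[str, list[int]]:
    """Build a segment map from 1-based inclusive sensory/signaling intervals.

    Positions outside both intervals fall into ``other``.
    """
    seg = {name: [] for name in SEGMENT_NAMES}
    for pos in range(1, length + 1):
        if sensory[0] <= pos <= sensory[1]:
            seg["sensory"].append(pos)
        elif signaling[0] <= pos <= signaling[1]:
            seg["signaling"].append(pos)
        else:
            seg["other"].append(pos)
    return seg


@dataclass
class EvolutionParams:
    """Parameters of the family simulator.

    ``genome_tree`` is a rooted newick string or dendropy Tree with branch
    lengths in substitutions/site.  ``base_rate`` scales branch lengths;
    the sensory segment evolves ``sensory_rate_multiplier`` times faster
    than the signaling/other segments, except at ``motif_positions`` whose
    rate is divided by ``motif_rate_reduction`` (default 100x: the motif is
    held near-invariant, as a key functional determinant would be).
    """

    genome_tree: str | dendropy.Tree
    segment_map: dict[str, list[int]]
    base_rate: float = 1.0
    sensory_rate_multiplier: float = 8.0
    motif_positions: tuple[int, ...] = ()
    motif_residues: str = ""
    motif_rate_reduction: float = 100.0
    duplication_rate: float = 0.15
    loss_rate: float = 0.08
    pseudogenization_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("base_rate", self.base_rate),
            ("sensory_rate_multiplier", self.sensory_rate_multiplier),
            ("duplication_rate", self.duplication_rate),
            ("loss_rate", self.loss_rate),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.pseudogenization_prob <= 1:
            raise ValueError("pseudogenization_prob must be a probability")
        if self.motif_rate_reduction < 10:
            raise ValueError("motif_rate_reduction must be >= 10")
        covered = sorted(
            pos for name in SEGMENT_NAMES for pos in self.segment_map.get(name, [])
        )
        length = self.length
        if covered != list(range(1, length + 1)):
            raise ValueError("segment_map must partition 1..L exactly once")
        if len(self.motif_positions) != len(self.motif_residues):
            raise ValueError("motif_positions and motif_residues differ in length")
        sensory = set(self.segment_map.get("sensory", []))
        outside = [p for p in self.motif_positions if p not in sensory]
        if outside:
            raise ValueError(
                f"motif positions {outside} fall outside the sensory segment"
            )

    @property
    def length(self) -> int:
        return sum(len(v) for v in self.segment_map.values())


@dataclass(frozen=True)
class Event:
    """One recorded evolutionary event on a tree branch.

    ``branch`` is the label of the node at the *head* (child end) of the
    branch on which the event occurred.
    """

    branch: str
    event: str  # duplication | loss | pseudogenization
    family: str
    new_family: str | None = None  # for duplications: the family born


@dataclass
class FamilySimulation:
    """Simulated sequences plus the ground-truth event log."""

    sequences: list[SequenceRecord]
    event_log: list[Event]
    true_birth_node: dict[str, str]
    true_clusters: dict[str, str]
    tree: dendropy.Tree
    params: EvolutionParams

    def copy_counts(self, include_pseudogenes: bool = False) -> dict[str, dict[str, int]]:
        """Per-genome, per-family copy counts from the emitted sequences."""
        counts: dict[str, dict[str, int]] = {}
        for rec in self.sequences:
            if rec.pseudogene and not include_pseudogenes:
                continue
            family = rec.seq_id.split("|")[1]
            counts.setdefault(rec.genome_id, {}).setdefault(family, 0)
            counts[rec.genome_id][family] += 1
        return counts

    def ortholog_families(self) -> dict[str, set[str]]:
        """family -> set of genomes carrying at least one intact copy."""
        fams: dict[str, set[str]] = {}
        for rec in self.sequences:
            if rec.pseudogene:
                continue
            family = rec.seq_id.split("|")[1]
            fams.setdefault(family, set()).add(rec.genome_id)
        return fams


def label_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign stable labels N0, N1, ... to unlabeled internal nodes (preorder)."""
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label if node.taxon else node.label
        elif not node.label:
            node.label = f"N{counter}"
            counter += 1
    return tree


def _as_tree(genome_tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(genome_tree, dendropy.Tree):
        tree = genome_tree
    else:
        tree = dendropy.Tree.get(
            data=genome_tree, schema="newick", preserve_underscores=True
        )
    tree.is_rooted = True
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if n_leaves < 2:
        raise ValueError("genome tree must have at least 2 leaves")
    return label_tree(tree)


@dataclass
class _Copy:
    family: str
    seq: np.ndarray  # integer-coded residues
    pseudogene: bool


def _evolve_branch(
    seq: np.ndarray, p_sub: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Apply uniform replacement among the other 19 residues at rate ``p_sub``."""
    out = seq.copy()
    hit = rng.random(seq.shape[0]) < p_sub
    if hit.any():
        idx = np.flatnonzero(hit)
        # uniform over the 19 non-identical residues: draw an offset 1..19
        offsets = rng.integers(1, 20, size=idx.shape[0])
        out[idx] = (out[idx] + offsets) % 20
    return out


def simulate_family_evolution(params: EvolutionParams) -> FamilySimulation:
    """Run the duplication/loss/substitution process down the genome tree.

    Returns the leaf sequences together with the event log, the true birth
    node of every family (the head node of the branch on which it arose;
    the root for the founding family) and the true redundancy clusters
    (genomes whose intact homolog sets are sequence-identical multisets).
    """
    if params.length < 50:
        raise ValueError("sequence length must be >= 50")
    tree = _as_tree(params.genome_tree)
    rng = np.random.default_rng(params.seed)

    # per-position rate multipliers
    mult = np.ones(params.length)
    for pos in params.segment_map.get("sensory", []):
        mult[pos - 1] = params.sensory_rate_multiplier
    for pos in params.motif_positions:
        mult[pos - 1] /= params.motif_rate_reduction

    ancestor = rng.integers(0, 20, size=params.length)
    for pos, res in zip(params.motif_positions, params.motif_residues):
        ancestor[pos - 1] = _AA_INDEX[res]

    root_family = "F0"
    root = tree.seed_node
    birth_node: dict[str, str] = {root_family: root.label}
    event_log: list[Event] = []
    fam_counter = 1

    node_state: dict[int, list[_Copy]] = {
        id(root): [_Copy(root_family, ancestor, False)]
    }
    leaf_copies: dict[str, list[_Copy]] = {}

    for node in tree.preorder_node_iter():
        copies = node_state.pop(id(node))
        if node.is_leaf():
            leaf_copies[node.label] = copies
            continue
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            p_sub = 1.0 - np.exp(-params.base_rate * t * mult)
            survivors: list[_Copy] = []
            for copy in copies:
                # loss: at least one loss event on this branch removes the copy
                if rng.random() < 1.0 - np.exp(-params.loss_rate * t):
                    event_log.append(Event(child.label, "loss", copy.family))
                    continue
                born = [copy]
                n_dup = rng.poisson(params.duplication_rate * t)
                for _ in range(n_dup):
                    new_family = f"F{fam_counter}"
                    fam_counter += 1
                    birth_node[new_family] = child.label
                    event_log.append(
                        Event(child.label, "duplication", copy.family, new_family)
                    )
                    born.append(_Copy(new_family, copy.seq, copy.pseudogene))
                for b in born:
                    pseudo = b.pseudogene
                    if not pseudo and rng.random() < params.pseudogenization_prob:
                        event_log.append(Event(child.label, "pseudogenization", b.family))
                        pseudo = True
                    survivors.append(
                        _Copy(b.family, _evolve_branch(b.seq, p_sub, rng), pseudo)
                    )
            node_state[id(child)] = survivors

    # assembly levels per genome, drawn once
    levels = list(AssemblyLevel)
    genome_level = {
        leaf: levels[rng.integers(0, len(levels))] for leaf in sorted(leaf_copies)
    }

    sequences: list[SequenceRecord] = []
    for genome in sorted(leaf_copies):
        for k, copy in enumerate(leaf_copies[genome]):
            sequences.append(
                SequenceRecord(
                    seq_id=f"{genome}|{copy.family}|c{k}",
                    genome_id=genome,
                    residues="".join(AMINO_ACIDS[copy.seq]),
                    assembly_level=genome_level[genome],
                    pseudogene=copy.pseudogene,
                )
            )

    # truth clusters: identical intact-homolog multisets
    signature: dict[str, tuple[str, ...]] = {}
    for genome in leaf_copies:
        intact = sorted(
            "".join(AMINO_ACIDS[c.seq]) for c in leaf_copies[genome] if not c.pseudogene
        )
        signature[genome] = tuple(intact)
    cluster_of: dict[tuple[str, ...], str] = {}
    true_clusters: dict[str, str] = {}
    for genome in sorted(signature):
        sig = signature[genome]
        if sig not in cluster_of:
            cluster_of[sig] = f"C{len(cluster_of)}"
        true_clusters[genome] = cluster_of[sig]

    return FamilySimulation(
        sequences=sequences,
        event_log=event_log,
        true_birth_node=birth_node,
        true_clusters=true_clusters,
        tree=tree,
        params=params,
    )


def replay_event_log(
    tree: dendropy.Tree, event_log: list[Event], root_family: str = "F0"
) -> dict[str, dict[str, int]]:
    """Replay an event log down the tree and return per-genome family counts.

    Pseudogenized copies are excluded from the counts, mirroring presence
    calls downstream.  Used to verify that the log is consistent with the
    emitted sequences.
    """
    by_branch: dict[str, list[Event]] = {}
    for ev in event_log:
        by_branch.setdefault(ev.branch, []).append(ev)

    state: dict[int, list[tuple[str, bool]]] = {
        id(tree.seed_node): [(root_family, False)]
    }
    counts: dict[str, dict[str, int]] = {}
    for node in tree.preorder_node_iter():
        copies = state.pop(id(node))
        if node.is_leaf():
            counts[node.label] = {}
            for fam, pseudo in copies:
                if not pseudo:
                    counts[node.label][fam] = counts[node.label].get(fam, 0) + 1
            continue
        for child in node.child_nodes():
            events = list(by_branch.get(child.label, []))
            child_copies = [list(c) for c in copies]
            for ev in events:
                if ev.event == "loss":
                    for c in child_copies:
                        if c[0] == ev.family:
                            child_copies.remove(c)
                            break
                elif ev.event == "duplication":
                    child_copies.append([ev.new_family, False])
                elif ev.event == "pseudogenization":
                    for c in child_copies:
                        if c[0] == ev.family and not c[1]:
                            c[1] = True
                            break
            state[id(child)] = [tuple(c) for c in child_copies]
    return counts


def write_fasta(sequences: list[SequenceRecord]) -> str:
    """Render sequence records as FASTA text."""
    buf = io.StringIO()
    for rec in sequences:
        buf.write(f">{rec.seq_id}\n")
        for i in range(0, len(rec.residues), 60):
            buf.write(rec.residues[i : i + 60] + "\n")
    return buf.getvalue()


def write_metadata_tsv(sequences: list[SequenceRecord]) -> str:
    """Genome metadata table: genome_id, assembly_level, plus per-sequence flags."""
    lines = ["seq_id\tgenome_id\tassembly_level\tpseudogene"]
    for rec in sequences:
        lines.append(
            f"{rec.seq_id}\t{rec.genome_id}\t{rec.assembly_level.name}\t"
            f"{int(rec.pseudogene)}"
        )
    return "\n".join(lines) + "\n"
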