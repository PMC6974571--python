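"""Redundancy reduction: cluster sequence-identical genomes, keep one representative.

Genome databases are heavily skewed toward resequenced strains; before any
comparative statistics the homolog corpus is collapsed so that each group of
effectively identical genomes contributes once.  Two genomes are merged iff

  (a) they carry the same number of homologs,
  (b) every matched homolog pair aligns at 100% query coverage
      (both directions), and
  (c) every matched homolog pair is 100% identical,

evaluated on a one-to-one matching of their homolog sets (greedy by
alignment score); clusters are the transitive closure of this pairwise
relation.  From each cluster the representative is the genome with the
highest assembly level (ties: lexicographically smallest genome id).
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import AssemblyLevel, Hit, HitTable, SequenceRecord


@dataclass
class GenomeHomologSet:
    """All homologs found in one genome."""

    genome_id: str
    homolog_ids: list[str]
    assembly_level: AssemblyLevel

    @property
    def homolog_count(self) -> int:
        return len(self.homolog_ids)


@dataclass
class RedundancyCluster:
    """A set of effectively identical genomes and its chosen representative."""

    member_genomes: set[str]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.member_genomes:
            raise ValueError("representative must be a cluster member")


def genome_sets_from_sequences(seqs: list[SequenceRecord]) -> list[GenomeHomologSet]:
    """Group sequences into per-genome homolog sets (pseudogenes excluded)."""
    by_genome: dict[str, GenomeHomologSet] = {}
    for rec in seqs:
        if rec.pseudogene:
            continue
        entry = by_genome.get(rec.genome_id)
        if entry is None:
            by_genome[rec.genome_id] = GenomeHomologSet(
                rec.genome_id, [rec.seq_id], rec.assembly_level
            )
        else:
            entry.homolog_ids.append(rec.seq_id)
    return [by_genome[g] for g in sorted(by_genome)]


def _identical_pair(hits: HitTable, id_a: str, id_b: str) -> tuple[bool, float]:
    """Whether two homologs are 100%-identity / 100%-coverage in both directions.

    Missing hits are treated as non-identical.  Returns (flag, score).
    """
    fwd = hits.get(id_a, id_b)
    rev = hits.get(id_b, id_a)
    if fwd is None or rev is None:
        return False, float("-inf")
    ok = (
        fwd.identity >= 100.0
        and rev.identity >= 100.0
        and fwd.coverage >= 100.0
        and rev.coverage >= 100.0
    )
    return ok, fwd.score


def _genomes_mergeable(
    a: GenomeHomologSet, b: GenomeHomologSet, hits: HitTable
) -> bool:
    """Conditions (a)-(c) on a greedy one-to-one matching of the homolog sets."""
    if a.homolog_count != b.homolog_count:
        return False
    candidates: list[tuple[float, str, str]] = []
    for x in a.homolog_ids:
        for y in b.homolog_ids:
            ok, score = _identical_pair(hits, x, y)
            if ok:
                candidates.append((score, x, y))
    # greedy maximum matching by score, deterministic tie-break on ids
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    matched = 0
    for _, x, y in candidates:
        if x in used_a or y in used_b:
            continue
        used_a.add(x)
        used_b.add(y)
        matched += 1
    return matched == a.homolog_count


class _UnionFind:
    def __init__(self, items: list[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            # anchor on the smaller id for order-independence
            lo, hi = sorted((rx, ry))
            self.parent[hi] = lo


def cluster_genomes(
    genome_sets: list[GenomeHomologSet], hits: HitTable
) -> list[RedundancyCluster]:
    """Partition genomes into redundancy clusters (transitive closure of merges)."""
    for gs in genome_sets:
        if gs.homolog_count < 1:
            raise ValueError(f"genome {gs.genome_id} has no homologs")
    by_id = {gs.genome_id: gs for gs in genome_sets}
    ids = sorted(by_id)
    uf = _UnionFind(ids)
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            if _genomes_mergeable(by_id[ga], by_id[gb], hits):
                uf.union(ga, gb)
    members: dict[str, set[str]] = {}
    for g in ids:
        members.setdefault(uf.find(g), set()).add(g)
    clusters = []
    for root in sorted(members):
        cluster = RedundancyCluster(member_genomes=members[root], representative=root)
        cluster.representative = select_representative(cluster, genome_sets)
        clusters.append(cluster)
    return clusters


def select_representative(
    cluster: RedundancyCluster, genome_sets: list[GenomeHomologSet]
) -> str:
    """Pick the member genome with the highest assembly level.

    Ties are broken toward the lexicographically smallest genome id.
    """
    if not cluster.member_genomes:
        raise ValueError("empty cluster")
    level = {gs.genome_id: gs.assembly_level for gs in genome_sets}
    best = max(level[g] for g in cluster.member_genomes)
    return min(g for g in cluster.member_genomes if level[g] == best)


def reduce(
    seqs: list[SequenceRecord], hits: HitTable
) -> tuple[list[SequenceRecord], list[RedundancyCluster]]:
    """Collapse the corpus to the homologs of each cluster representative.

    Idempotent: reducing the reduced set changes nothing.
    """
    genome_sets = genome_sets_from_sequences(seqs)
    clusters = cluster_genomes(genome_sets, hits)
    keep_genomes = {c.representative for c in clusters}
    kept = [
        rec for rec in seqs if rec.genome_id in keep_genomes and not rec.pseudogene
    ]
    return kept, clusters
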