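"""Pairwise sequence comparison, homolog filtering and best-hit orthology.

The search layer mirrors the classical workflow used to collect chemoreceptor
homologs: score every pair of proteins, keep hits passing coverage/identity
thresholds (defaults 90% / 30%), take the best hit per genome, and call
orthologs by the bidirectional-best-hit (BBH) rule.

Alignments are full-length global (Needleman–Wunsch) with affine gaps and
BLOSUM62 scores — appropriate for full-length receptor homologs in the
coverage ≥ 90% regime — rather than local HSPs; a ``mode="local"`` switch is
provided for comparison.  Identity is computed over residue–residue columns
only (gap columns excluded), and coverage is the fraction of query residues
aligned against a subject residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Iterator

from Bio import Align
from Bio.Align import substitution_matrices

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: affine gap scheme: a gap of length k scores -(GAP_OPEN + (k-1) * GAP_EXTEND)
GAP_OPEN = 11.0
GAP_EXTEND = 1.0


class AssemblyLevel(IntEnum):
    """Ordinal genome assembly quality, ``contig`` lowest."""

    contig = 0
    scaffold = 1
    chromosome = 2
    complete = 3


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence tied to its source genome."""

    seq_id: str
    genome_id: str
    residues: str
    assembly_level: AssemblyLevel = AssemblyLevel.contig
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.seq_id}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment; degapping recovers the inputs exactly."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    def residue_pair_columns(self) -> Iterator[tuple[str, str]]:
        """Yield columns where both rows carry a residue (no gap)."""
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-" and cb != "-":
                yield ca, cb


@dataclass(frozen=True)
class Hit:
    """One retained similarity record between a query and a subject."""

    query_id: str
    subject_id: str
    query_genome: str
    subject_genome: str
    identity: float  # % of residue-residue columns that match
    coverage: float  # % of query residues aligned to a subject residue
    score: float


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNERS = {"global": _make_aligner("global"), "local": _make_aligner("local")}


def align_pair(
    a: SequenceRecord, b: SequenceRecord, mode: str = "global"
) -> PairwiseAlignment:
    """Optimally align two protein sequences.

    Global mode is the default (full-length homologs); ``mode="local"``
    gives Smith–Waterman behaviour.  Deterministic: of co-optimal
    alignments the aligner's first traceback is taken.
    """
    if mode not in _ALIGNERS:
        raise ValueError(f"unknown alignment mode {mode!r}")
    aln = _ALIGNERS[mode].align(a.residues, b.residues)[0]
    return PairwiseAlignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=aln.score)


def make_hit(alignment: PairwiseAlignment, a: SequenceRecord, b: SequenceRecord) -> Hit:
    """Summarise an alignment of ``a`` (query) vs ``b`` (subject) as a hit.

    identity = matching residue–residue columns / residue–residue columns;
    coverage = residue–residue columns holding a query residue / query length.
    """
    pairs = list(alignment.residue_pair_columns())
    n_cols = len(pairs)
    matches = sum(1 for ca, cb in pairs if ca == cb)
    identity = 100.0 * matches / n_cols if n_cols else 0.0
    coverage = 100.0 * n_cols / len(a)
    return Hit(
        query_id=a.seq_id,
        subject_id=b.seq_id,
        query_genome=a.genome_id,
        subject_genome=b.genome_id,
        identity=identity,
        coverage=coverage,
        score=alignment.score,
    )


class HitTable:
    """Best-scoring hits keyed by ordered (query, subject) pair."""

    def __init__(self, hits: Iterable[Hit] = ()) -> None:
        self._hits: dict[tuple[str, str], Hit] = {}
        for hit in hits:
            self.add(hit)

    def add(self, hit: Hit) -> None:
        key = (hit.query_id, hit.subject_id)
        old = self._hits.get(key)
        if old is None or hit.score > old.score:
            self._hits[key] = hit

    def __len__(self) -> int:
        return len(self._hits)

    def __iter__(self) -> Iterator[Hit]:
        return iter(self._hits.values())

    def get(self, query_id: str, subject_id: str) -> Hit | None:
        return self._hits.get((query_id, subject_id))

    def hits_from(self, query_id: str) -> list[Hit]:
        return [h for h in self._hits.values() if h.query_id == query_id]

    def genomes(self) -> set[str]:
        out: set[str] = set()
        for h in self._hits.values():
            out.add(h.query_genome)
            out.add(h.subject_genome)
        return out


def filter_homologs(
    hits: HitTable, min_coverage: float = 90.0, min_identity: float = 30.0
) -> HitTable:
    """Keep hits with coverage ≥ ``min_coverage`` and identity ≥ ``min_identity`` (%)."""
    for thr in (min_coverage, min_identity):
        if not 0.0 <= thr <= 100.0:
            raise ValueError("thresholds must lie in [0, 100]")
    return HitTable(
        h for h in hits if h.coverage >= min_coverage and h.identity >= min_identity
    )


def all_vs_all_search(
    seqs: list[SequenceRecord], mode: str = "global"
) -> HitTable:
    """All-versus-all pairwise search over a sequence set.

    Every ordered non-self pair yields a hit (alignments are computed once
    per unordered pair; scores are symmetric, coverage is per-query).
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    table = HitTable()
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            aln = align_pair(a, b, mode=mode)
            table.add(make_hit(aln, a, b))
            flipped = PairwiseAlignment(aln.aligned_b, aln.aligned_a, aln.score)
            table.add(make_hit(flipped, b, a))
    return table


def best_hits_per_genome(hits: HitTable, query: SequenceRecord | str) -> dict[str, Hit]:
    """For one query, the single best-scoring hit in each subject genome.

    Ties are broken toward the lexicographically smaller subject id.
    """
    query_id = query if isinstance(query, str) else query.seq_id
    best: dict[str, Hit] = {}
    for hit in hits.hits_from(query_id):
        cur = best.get(hit.subject_genome)
        if (
            cur is None
            or hit.score > cur.score
            or (hit.score == cur.score and hit.subject_id < cur.subject_id)
        ):
            best[hit.subject_genome] = hit
    return best


def bidirectional_best_hits(
    hits: HitTable, genome_a: str, genome_b: str
) -> list[tuple[str, str]]:
    """Ortholog pairs between two genomes by the bidirectional-best-hit rule.

    ``(x, y)`` is returned iff y is x's best hit in ``genome_b`` and x is
    y's best hit in ``genome_a``.  Pairs are reported sorted, with x from
    ``genome_a``.
    """
    present = hits.genomes()
    for g in (genome_a, genome_b):
        if g not in present:
            raise ValueError(f"genome {g!r} absent from hit table")
    queries_a = sorted({h.query_id for h in hits if h.query_genome == genome_a})
    pairs: list[tuple[str, str]] = []
    for x in queries_a:
        fwd = best_hits_per_genome(hits, x).get(genome_b)
        if fwd is None:
            continue
        y = fwd.subject_id
        back = best_hits_per_genome(hits, y).get(genome_a)
        if back is not None and back.subject_id == x:
            pairs.append((x, y))
    return pairs
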