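"""Map binding-pocket residues between paralogs and scan for the binding motif.

Residues lining the pocket of one paralog are projected onto the others
through a shared multiple sequence alignment ("homologous positions"), so
that conservation of the ligand-binding site can be counted across paralogs
(e.g. how many of a reference receptor's contact residues survive in each
sister paralog, and which positions are common to all).  A positional motif
scanner checks sequences for the amino-acid-binding signature — by default
Tyr121, Asp122, Arg124, Arg126, Trp128 in PctA numbering — whose presence
separates amino-acid sensors from receptors with other ligand repertoires.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices

GAP = "-"

#: the amino-acid-binding motif in PctA numbering: (position, allowed residues)
DEFAULT_MOTIF: tuple[tuple[int, str], ...] = (
    (121, "Y"),
    (122, "D"),
    (124, "R"),
    (126, "R"),
    (128, "W"),
)


@dataclass
class PositionMap:
    """Residue-position correspondence between two rows of one alignment.

    ``pairs`` are (position in A, position in B), 1-based, strictly
    increasing in both coordinates; ``residues`` holds the letter pair of
    each entry.
    """

    pairs: list[tuple[int, int]]
    residues: list[tuple[str, str]]

    def to_b(self, pos_a: int) -> int | None:
        for (pa, pb) in self.pairs:
            if pa == pos_a:
                return pb
        return None

    def residue_pair(self, pos_a: int) -> tuple[str, str] | None:
        for (pa, _pb), res in zip(self.pairs, self.residues):
            if pa == pos_a:
                return res
        return None


def map_positions(row_a: str, row_b: str) -> PositionMap:
    """Positional map induced by two rows of one alignment.

    Every residue–residue column yields one pair; columns with a gap in
    either row yield none.
    """
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    pairs: list[tuple[int, int]] = []
    residues: list[tuple[str, str]] = []
    pos_a = pos_b = 0
    for ca, cb in zip(row_a, row_b):
        if ca != GAP:
            pos_a += 1
        if cb != GAP:
            pos_b += 1
        if ca != GAP and cb != GAP:
            pairs.append((pos_a, pos_b))
            residues.append((ca, cb))
    return PositionMap(pairs=pairs, residues=residues)


@dataclass
class ContactConservationSummary:
    """Conservation of a reference contact-residue set across paralogs."""

    reference: str
    ref_contacts: list[int]
    conserved: dict[str, list[int]]  # paralog -> conserved ref positions
    substituted: dict[str, list[tuple[int, str, str]]]  # (ref pos, ref aa, aa)
    unmapped: dict[str, list[int]]
    common_to_all: list[int]

    def conserved_count(self, paralog: str) -> int:
        return len(self.conserved[paralog])


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _similar(a: str, b: str) -> bool:
    try:
        return _BLOSUM62[a, b] > 0
    except KeyError:
        return False


def conserved_contacts(
    ref_contacts: list[int],
    ref_row: str,
    paralog_rows: dict[str, str],
    mode: str = "identity",
) -> ContactConservationSummary:
    """Count reference contact residues conserved in each paralog.

    ``ref_contacts`` are 1-based positions on the (ungapped) reference
    sequence; paralog rows come from the same alignment as ``ref_row``.
    ``mode="identity"`` (default) requires the identical residue letter at
    the mapped position; ``mode="similarity"`` accepts any positive
    BLOSUM62 pair.  conserved + substituted + unmapped partitions the
    reference set exactly.
    """
    if mode not in ("identity", "similarity"):
        raise ValueError("mode must be 'identity' or 'similarity'")
    conserved: dict[str, list[int]] = {}
    substituted: dict[str, list[tuple[int, str, str]]] = {}
    unmapped: dict[str, list[int]] = {}
    for name, row in paralog_rows.items():
        pmap = map_positions(ref_row, row)
        conserved[name] = []
        substituted[name] = []
        unmapped[name] = []
        for pos in ref_contacts:
            pair = pmap.residue_pair(pos)
            if pair is None:
                unmapped[name].append(pos)
                continue
            ra, rb = pair
            same = ra == rb if mode == "identity" else (ra == rb or _similar(ra, rb))
            if same:
                conserved[name].append(pos)
            else:
                substituted[name].append((pos, ra, rb))
    common = [
        pos
        for pos in ref_contacts
        if all(pos in conserved[name] for name in paralog_rows)
    ]
    return ContactConservationSummary(
        reference="reference",
        ref_contacts=list(ref_contacts),
        conserved=conserved,
        substituted=substituted,
        unmapped=unmapped,
        common_to_all=common,
    )


def homologous_contact_positions(
    contact_sets: dict[str, list[int]], alignment_rows: dict[str, str]
) -> tuple[int, list[int], dict[str, list[int]]]:
    """Project per-structure contact residues onto master-alignment columns.

    ``contact_sets`` maps structure name -> 1-based contact positions on
    its own sequence; ``alignment_rows`` maps the same names -> their row
    in the master alignment.  Returns (number of distinct columns, sorted
    0-based column list, per-structure positions that fell outside the
    aligned region and were excluded).
    """
    columns: set[int] = set()
    excluded: dict[str, list[int]] = {}
    for name, positions in contact_sets.items():
        row = alignment_rows[name]
        pos_to_col: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(row):
            if ch != GAP:
                pos += 1
                pos_to_col[pos] = col
        excluded[name] = []
        for p in positions:
            if p in pos_to_col:
                columns.add(pos_to_col[p])
            else:
                excluded[name].append(p)
    return len(columns), sorted(columns), excluded


@dataclass
class MotifMatch:
    """One window satisfying all positional constraints of a motif."""

    start: int  # 1-based position aligned with the first constraint
    satisfied: list[tuple[int, str]]  # (sequence position, residue)


def motif_scan(
    sequence: str,
    motif: tuple[tuple[int, str], ...] = DEFAULT_MOTIF,
) -> list[MotifMatch]:
    """All placements of a positional motif in an ungapped sequence.

    ``motif`` lists (position, allowed residues) in a common numbering; the
    scan slides the whole constraint set along the sequence, so a match at
    offset 0 means the sequence follows the reference numbering exactly.
    """
    if not motif:
        return []
    base = motif[0][0]
    offsets = [(pos - base, allowed) for pos, allowed in motif]
    span = max(off for off, _ in offsets)
    matches: list[MotifMatch] = []
    for start in range(0, len(sequence) - span):
        satisfied = []
        for off, allowed in offsets:
            residue = sequence[start + off]
            if residue not in allowed:
                break
            satisfied.append((start + off + 1, residue))
        else:
            matches.append(MotifMatch(start=start + 1, satisfied=satisfied))
    return matches
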