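"""Conservation statistics: domain-partitioned identity, logos, conserved motifs.

The signature of paralog subfunctionalization in chemoreceptors is extreme
rate contrast between domains: near-identity in the cytosolic signaling
domain against deep divergence in the periplasmic sensor (dCache_1) domain,
with a short amino-acid-binding motif held invariant inside the otherwise
fast-evolving sensor.  This module quantifies that contrast:

* :func:`domain_partition_identity` — mean pairwise identity per annotated
  domain, with domains given in reference-sequence coordinates;
* :func:`column_statistics` — per-column residue frequencies and information
  content (IC = log2 20 - Shannon entropy, bits), the basis of sequence logos;
* :func:`detect_hcr` — highly conserved regions shared by (almost) all
  paralog clusters, allowing a configurable number of exception clusters;
* :func:`cluster_specific_positions` — columns conserved *within* every
  cluster but differing *between* clusters, the residues that retarget
  ligand specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MAX_IC_BITS = math.log2(20)


@dataclass
class DomainAnnotation:
    """Named, non-overlapping intervals in 1-based reference coordinates."""

    intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.intervals.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("domain intervals overlap")
        for name, (a, b) in self.intervals.items():
            if a < 1 or b < a:
                raise ValueError(f"bad interval for domain {name!r}")


@dataclass
class AlignmentMatrix:
    """A multiple sequence alignment as an ids + character-matrix pair."""

    seq_ids: list[str]
    rows: np.ndarray  # (n_seqs, n_cols) of single characters

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows)
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.seq_ids):
            raise ValueError("row/ids shape mismatch")

    @classmethod
    def from_strings(cls, records: dict[str, str]) -> "AlignmentMatrix":
        ids = list(records)
        lengths = {len(s) for s in records.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        rows = np.array([list(records[i]) for i in ids])
        return cls(seq_ids=ids, rows=rows)

    @property
    def n_cols(self) -> int:
        return self.rows.shape[1]

    def row(self, seq_id: str) -> str:
        return "".join(self.rows[self.seq_ids.index(seq_id)])

    def reference_column_map(self, ref_id: str) -> dict[int, int]:
        """1-based reference residue number -> 0-based alignment column."""
        ref = self.rows[self.seq_ids.index(ref_id)]
        mapping: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(ref):
            if ch != GAP:
                pos += 1
                mapping[pos] = col
        return mapping


@dataclass
class SequenceLogo:
    """Per-column residue frequencies, gap fractions and information content."""

    frequencies: np.ndarray  # (n_cols, 20), gap-excluded, rows sum to 1
    gap_fraction: np.ndarray  # (n_cols,)
    information: np.ndarray  # (n_cols,) bits; NaN for all-gap columns
    all_gap: np.ndarray  # (n_cols,) bool
    n_seqs: int

    @property
    def n_cols(self) -> int:
        return self.frequencies.shape[0]

    def consensus(self) -> list[str]:
        """Most frequent residue per column (gap for all-gap columns)."""
        out = []
        for col in range(self.n_cols):
            if self.all_gap[col]:
                out.append(GAP)
            else:
                out.append(AA_ALPHABET[int(np.argmax(self.frequencies[col]))])
        return out


@dataclass
class HCRRegion:
    """A highly conserved column interval, with the clusters that carry it."""

    start: int  # 0-based, inclusive
    end: int  # 0-based, inclusive
    mean_ic: float
    clusters_present: set[str]
    clusters_absent: set[str]


def _pairwise_identity(rows: np.ndarray, cols: np.ndarray) -> float:
    """Mean over all sequence pairs of % identity on residue-residue columns."""
    sub = rows[:, cols]
    n = sub.shape[0]
    idents = []
    for i in range(n):
        for j in range(i + 1, n):
            both = (sub[i] != GAP) & (sub[j] != GAP)
            total = int(both.sum())
            if total == 0:
                continue
            matches = int(((sub[i] == sub[j]) & both).sum())
            idents.append(100.0 * matches / total)
    return float(np.mean(idents)) if idents else float("nan")


def domain_partition_identity(
    alignment: AlignmentMatrix, domains: DomainAnnotation, ref_id: str
) -> dict[str, float]:
    """Average pairwise identity (%) per domain, in reference coordinates."""
    colmap = alignment.reference_column_map(ref_id)
    out: dict[str, float] = {}
    for name, (a, b) in domains.intervals.items():
        cols = np.array([colmap[p] for p in range(a, b + 1) if p in colmap])
        if cols.size == 0:
            raise ValueError(f"domain {name!r} maps to no alignment columns")
        out[name] = _pairwise_identity(alignment.rows, cols)
    return out


def column_statistics(
    alignment: AlignmentMatrix, small_sample_correction: bool = False
) -> SequenceLogo:
    """Residue frequencies and information content for every alignment column.

    IC = log2(20) - H where H is the Shannon entropy (bits) of the gap-excluded
    residue frequencies.  With ``small_sample_correction`` the Miller–Madow
    bias correction (m-1)/(2 N ln 2) is added to the entropy estimate and the
    IC clipped into [0, log2 20].
    """
    if alignment.rows.shape[0] < 2:
        raise ValueError("need at least 2 sequences")
    n_cols = alignment.n_cols
    freqs = np.zeros((n_cols, 20))
    gap_frac = np.zeros(n_cols)
    info = np.full(n_cols, np.nan)
    all_gap = np.zeros(n_cols, dtype=bool)
    aa_index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    for col in range(n_cols):
        column = alignment.rows[:, col]
        residues = [c for c in column if c != GAP and c in aa_index]
        gap_frac[col] = 1.0 - len(residues) / len(column)
        if not residues:
            all_gap[col] = True
            continue
        counts = np.zeros(20)
        for c in residues:
            counts[aa_index[c]] += 1
        p = counts / counts.sum()
        freqs[col] = p
        nonzero = p[p > 0]
        entropy = float(-(nonzero * np.log2(nonzero)).sum())
        if small_sample_correction:
            entropy += (len(nonzero) - 1) / (2.0 * len(residues) * math.log(2))
        info[col] = min(max(MAX_IC_BITS - entropy, 0.0), MAX_IC_BITS)
    return SequenceLogo(
        frequencies=freqs,
        gap_fraction=gap_frac,
        information=info,
        all_gap=all_gap,
        n_seqs=alignment.rows.shape[0],
    )


def slice_logo(logo: SequenceLogo, start: int, end: int) -> SequenceLogo:
    """Restrict a logo to columns [start, end) (0-based), e.g. one domain."""
    return SequenceLogo(
        frequencies=logo.frequencies[start:end],
        gap_fraction=logo.gap_fraction[start:end],
        information=logo.information[start:end],
        all_gap=logo.all_gap[start:end],
        n_seqs=logo.n_seqs,
    )


def detect_hcr(
    cluster_logos: dict[str, SequenceLogo],
    window: int = 10,
    ic_threshold: float = 2.5,
    max_exceptions: int = 1,
    max_gap_fraction: float = 0.5,
) -> list[HCRRegion]:
    """Find highly conserved regions shared by (almost) all clusters.

    A window of ``window`` columns qualifies when its mean IC is at least
    ``ic_threshold`` bits in at least ``n_clusters - max_exceptions``
    clusters; overlapping qualifying windows are merged into maximal
    regions.  Columns gapped in more than ``max_gap_fraction`` of any
    cluster's sequences are excluded from windows.  For each region the
    clusters whose mean IC over the region falls short are reported in
    ``clusters_absent`` (the "exception" clusters).
    """
    names = sorted(cluster_logos)
    if not names:
        raise ValueError("no cluster logos supplied")
    n_cols = cluster_logos[names[0]].n_cols
    if any(cluster_logos[n].n_cols != n_cols for n in names):
        raise ValueError("cluster logos are not on a common column coordinate")
    if window > n_cols:
        raise ValueError("window exceeds alignment length")

    usable = np.ones(n_cols, dtype=bool)
    for name in names:
        logo = cluster_logos[name]
        usable &= (logo.gap_fraction <= max_gap_fraction) & ~logo.all_gap

    ic = np.array(
        [np.where(np.isnan(cluster_logos[n].information), 0.0,
                  cluster_logos[n].information) for n in names]
    )  # (n_clusters, n_cols)

    qualifying = np.zeros(n_cols, dtype=bool)
    need = max(len(names) - max_exceptions, 1)
    for start in range(0, n_cols - window + 1):
        cols = slice(start, start + window)
        if not usable[cols].all():
            continue
        passing = (ic[:, cols].mean(axis=1) >= ic_threshold).sum()
        if passing >= need:
            qualifying[cols] = True

    regions: list[HCRRegion] = []
    col = 0
    while col < n_cols:
        if not qualifying[col]:
            col += 1
            continue
        start = col
        while col < n_cols and qualifying[col]:
            col += 1
        end = col - 1
        region_ic = ic[:, start : end + 1].mean(axis=1)
        present = {n for n, v in zip(names, region_ic) if v >= ic_threshold}
        regions.append(
            HCRRegion(
                start=start,
                end=end,
                mean_ic=float(region_ic[[names.index(n) for n in present]].mean())
                if present
                else 0.0,
                clusters_present=present,
                clusters_absent=set(names) - present,
            )
        )
    return regions


def cluster_specific_positions(
    cluster_logos: dict[str, SequenceLogo],
    within_ic_threshold: float = 3.0,
) -> list[dict]:
    """Columns conserved within every cluster but divergent between clusters.

    Returns, per qualifying column, the per-cluster consensus residues, the
    minimum within-cluster IC, and the between-cluster divergence (fraction
    of cluster pairs whose consensus residues differ).
    """
    names = sorted(cluster_logos)
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    n_cols = cluster_logos[names[0]].n_cols
    consensus = {n: cluster_logos[n].consensus() for n in names}
    out = []
    for col in range(n_cols):
        ics = [cluster_logos[n].information[col] for n in names]
        if any(np.isnan(v) or v < within_ic_threshold for v in ics):
            continue
        residues = {n: consensus[n][col] for n in names}
        distinct = set(residues.values())
        if len(distinct) < 2:
            continue
        n_pairs = len(names) * (len(names) - 1) // 2
        diff_pairs = sum(
            1
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if residues[names[i]] != residues[names[j]]
        )
        out.append(
            {
                "column": col,
                "consensus": residues,
                "min_within_ic": float(min(ics)),
                "between_divergence": diff_pairs / n_pairs,
            }
        )
    return out
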