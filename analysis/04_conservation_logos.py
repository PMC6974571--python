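#!/usr/bin/env python
"""Domain-partitioned divergence, per-family logos and HCR detection.

Quantifies the signature of sensory-domain subfunctionalization: pairwise
identity split by domain, per-family sequence logos on the common
coordinate, and detection of the highly conserved region (HCR) shared by
motif-carrying families with the motif-free family flagged as the
exception.
"""

from pathlib import Path

from paralogpocket.conservation import (
    AlignmentMatrix,
    DomainAnnotation,
    column_statistics,
    detect_hcr,
    domain_partition_identity,
    slice_logo,
)
from paralogpocket.pipeline import default_simulation_params
from paralogpocket.seqsim import simulate_family_evolution

OUT = Path("results/analysis")
SEED = 1
SENSORY = (31, 110)
SIGNALING = (111, 170)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # rate contrast, measured on a loss-free replicate (one row per genome)
    sim = simulate_family_evolution(default_simulation_params(
        seed=SEED, duplication_rate=0.0, loss_rate=0.0,
        pseudogenization_prob=0.0,
    ))
    aln = AlignmentMatrix.from_strings({s.seq_id: s.residues for s in sim.sequences})
    domains = DomainAnnotation({"sensory": SENSORY, "signaling": SIGNALING})
    ident = domain_partition_identity(aln, domains, aln.seq_ids[0])
    print(f"mean pairwise identity: sensory {ident['sensory']:.1f}%, "
          f"signaling {ident['signaling']:.1f}% "
          f"(the sensory segment evolves ~8x faster)")

    # five-cluster HCR experiment: motif planted in four, absent from one
    logos = {}
    for c in range(4):
        rep = simulate_family_evolution(default_simulation_params(
            seed=SEED + 10 + c, duplication_rate=0.0, loss_rate=0.0,
            pseudogenization_prob=0.0,
        ))
        a = AlignmentMatrix.from_strings({s.seq_id: s.residues for s in rep.sequences})
        logos[f"cluster{c + 1}"] = slice_logo(
            column_statistics(a), SENSORY[0] - 1, SENSORY[1]
        )
    rep = simulate_family_evolution(default_simulation_params(
        seed=SEED + 20, duplication_rate=0.0, loss_rate=0.0,
        pseudogenization_prob=0.0, motif_positions=(), motif_residues="",
    ))
    a = AlignmentMatrix.from_strings({s.seq_id: s.residues for s in rep.sequences})
    logos["cluster5_nomotif"] = slice_logo(
        column_statistics(a), SENSORY[0] - 1, SENSORY[1]
    )

    regions = detect_hcr(logos, window=10, ic_threshold=2.5, max_exceptions=1)
    lines = ["start\tend\tmean_ic\tclusters_present\tclusters_absent"]
    for r in regions:
        lines.append(f"{r.start + SENSORY[0] - 1}\t{r.end + SENSORY[0] - 1}\t"
                     f"{r.mean_ic:.3f}\t{','.join(sorted(r.clusters_present))}\t"
                     f"{','.join(sorted(r.clusters_absent))}")
    (OUT / "hcr_report.tsv").write_text("\n".join(lines) + "\n")

    motif_cols = {p - 1 for p in (61, 62, 64, 66, 68)}
    for r in regions:
        span = set(range(r.start + SENSORY[0] - 1, r.end + SENSORY[0]))
        overlap = len(span & motif_cols) / len(motif_cols)
        print(f"HCR at alignment columns {r.start + SENSORY[0] - 1}-"
              f"{r.end + SENSORY[0] - 1}: covers {overlap:.0%} of the planted "
              f"motif, absent from {sorted(r.clusters_absent)}")
    print(f"outputs -> {OUT}/hcr_report.tsv")


if __name__ == "__main__":
    main()
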