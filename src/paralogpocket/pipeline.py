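"""End-to-end orchestration: simulate/load, analyse, report, validate.

``run_pipeline`` drives the comparative-genomics arm (search → filter →
redundancy reduction → phyletic profile → birth nodes → per-family logos →
HCR detection) and, when structures are supplied, the structural arm
(contact/H-bond/hydrophobic profiles and pocket occupancy).  All outputs are
plain TSV/JSON under one directory, together with a provenance record
holding every threshold, the seed and input digests, so a rerun with the
same configuration is bit-identical apart from file timestamps.

``validate_against_truth`` scores pipeline outputs against a simulation's
truth tables: redundancy-cluster Rand index, birth-node accuracy, HCR
overlap with the planted motif, and contact-fraction RMSE.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, conservation, homology, profiling, redundancy
from .seqsim import (
    EvolutionParams,
    FamilySimulation,
    segments_from_intervals,
    simulate_family_evolution,
    write_fasta,
    write_metadata_tsv,
)

log = logging.getLogger("paralogpocket")


@dataclass
class Thresholds:
    """Every numeric cutoff used by the pipeline (units: %, Å, degrees, bits)."""

    min_identity: float = 30.0
    min_coverage: float = 90.0
    logo_window: int = 10
    ic_threshold: float = 2.5
    max_exceptions: int = 1
    contact_cutoff: float = 5.0
    hbond_da_max: float = 3.0
    hbond_angle_max_deviation: float = 20.0
    hydrophobic_cutoff: float = 4.0
    xray_hbond_da_max: float = 3.35
    inside_min_contacts: int = 10
    release_distance: float = 8.0


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thresholds, **raw)


def default_simulation_params(seed: int = 0, **overrides) -> EvolutionParams:
    """Study-condition defaults for the demo simulation.

    An 8-genome balanced tree, 180-residue proteins with a fast sensory
    segment (8x), a conserved signaling segment and a 5-column
    near-invariant binding motif (YDxRxRxW spacing) inside the sensory
    segment.
    """
    newick = (
        "(((G1:0.08,G2:0.08):0.1,(G3:0.08,G4:0.08):0.1):0.12,"
        "((G5:0.08,G6:0.08):0.1,(G7:0.08,G8:0.08):0.1):0.12):0.0;"
    )
    params = dict(
        genome_tree=newick,
        segment_map=segments_from_intervals(180, sensory=(31, 110), signaling=(111, 170)),
        base_rate=0.6,
        sensory_rate_multiplier=8.0,
        motif_positions=(61, 62, 64, 66, 68),
        motif_residues="YDRRW",
        duplication_rate=0.5,
        loss_rate=0.1,
        pseudogenization_prob=0.02,
        seed=seed,
    )
    params.update(overrides)
    return EvolutionParams(**params)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _family_of(seq_id: str) -> str:
    return seq_id.split("|")[1]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the comparative-genomics arm end to end; returns the report bundle.

    Writes hits.tsv, clusters.tsv, profile.tsv, birth_events.tsv,
    logo_<family>.tsv, hcr_report.tsv and provenance.json under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds

    sim_overrides = dict(config.simulate or {})
    sim_overrides.setdefault("seed", config.seed)
    params = default_simulation_params(**sim_overrides)
    sim = simulate_family_evolution(params)
    log.info("simulated %d sequences on %d genomes", len(sim.sequences),
             len(sim.true_clusters))

    (out / "family.fasta").write_text(write_fasta(sim.sequences))
    (out / "metadata.tsv").write_text(write_metadata_tsv(sim.sequences))

    intact = [s for s in sim.sequences if not s.pseudogene]
    hits = homology.all_vs_all_search(intact)
    filtered = homology.filter_homologs(hits, thr.min_coverage, thr.min_identity)
    hit_lines = ["query\tsubject\tidentity\tcoverage\tscore"]
    for h in sorted(filtered, key=lambda h: (h.query_id, h.subject_id)):
        hit_lines.append(
            f"{h.query_id}\t{h.subject_id}\t{h.identity:.2f}\t{h.coverage:.2f}\t{h.score:.1f}"
        )
    (out / "hits.tsv").write_text("\n".join(hit_lines) + "\n")
    log.info("hit table: %d raw, %d after 30/90 filter", len(hits), len(filtered))

    kept, clusters = redundancy.reduce(intact, hits)
    cluster_lines = ["cluster_id\tgenome_id\tis_representative"]
    for i, cl in enumerate(clusters):
        for genome in sorted(cl.member_genomes):
            cluster_lines.append(
                f"RC{i}\t{genome}\t{int(genome == cl.representative)}"
            )
    (out / "clusters.tsv").write_text("\n".join(cluster_lines) + "\n")
    log.info("redundancy: %d genomes -> %d clusters", len(sim.true_clusters),
             len(clusters))

    profile = profiling.build_profile(sim.ortholog_families(), sim.tree)
    profile.to_csv(out / "profile.tsv", sep="\t")
    events = profiling.count_events(profile, sim.tree)
    events.to_csv(out / "birth_events.tsv", sep="\t")

    # per-family logos on the common coordinate (simulator emits equal-length
    # sequences, so rows are already aligned); families too small for a
    # meaningful column entropy are skipped
    logos: dict[str, conservation.SequenceLogo] = {}
    for family in sorted({_family_of(s.seq_id) for s in intact}):
        rows = {s.seq_id: s.residues for s in intact if _family_of(s.seq_id) == family}
        if len(rows) < 3:
            continue
        aln = conservation.AlignmentMatrix.from_strings(rows)
        logo = conservation.column_statistics(aln)
        logos[family] = logo
        logo_lines = ["column\tIC_bits\tgap_fraction\tconsensus"]
        consensus = logo.consensus()
        for col in range(logo.n_cols):
            logo_lines.append(
                f"{col}\t{logo.information[col]:.4f}\t{logo.gap_fraction[col]:.3f}\t"
                f"{consensus[col]}"
            )
        (out / f"logo_{family}.tsv").write_text("\n".join(logo_lines) + "\n")

    # HCR search runs on the sensory-segment columns only: the signaling
    # segment is conserved everywhere and would trivially qualify
    sensory_cols = sorted(p - 1 for p in params.segment_map.get("sensory", []))
    regions = []
    if logos and sensory_cols:
        offset = sensory_cols[0]
        sliced = {
            name: conservation.slice_logo(logo, sensory_cols[0], sensory_cols[-1] + 1)
            for name, logo in logos.items()
        }
        regions = conservation.detect_hcr(
            sliced,
            window=min(thr.logo_window, len(sensory_cols)),
            ic_threshold=thr.ic_threshold,
            max_exceptions=min(thr.max_exceptions, max(len(logos) - 1, 0)),
        )
        for r in regions:
            r.start += offset
            r.end += offset
    hcr_lines = ["start\tend\tmean_ic\tclusters_present\tclusters_absent"]
    for r in regions:
        hcr_lines.append(
            f"{r.start}\t{r.end}\t{r.mean_ic:.3f}\t"
            f"{','.join(sorted(r.clusters_present))}\t"
            f"{','.join(sorted(r.clusters_absent))}"
        )
    (out / "hcr_report.tsv").write_text("\n".join(hcr_lines) + "\n")
    log.info("HCR detection: %d region(s)", len(regions))

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(thr),
        "simulation": {
            "n_sequences": len(sim.sequences),
            "n_genomes": len(sim.true_clusters),
            "params_digest": _digest(repr(params)),
        },
        "input_digests": {
            "family.fasta": _digest((out / "family.fasta").read_text()),
            "metadata.tsv": _digest((out / "metadata.tsv").read_text()),
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")

    return {
        "simulation": sim,
        "hits": filtered,
        "clusters": clusters,
        "profile": profile,
        "events": events,
        "logos": logos,
        "hcr_regions": regions,
        "provenance": provenance,
        "out_dir": str(out),
    }


def rand_index(labels_a: dict[str, str], labels_b: dict[str, str]) -> float:
    """Rand index between two labelings of the same items."""
    items = sorted(labels_a)
    if sorted(labels_b) != items:
        raise ValueError("labelings cover different items")
    agree = total = 0
    for i, x in enumerate(items):
        for y in items[i + 1 :]:
            same_a = labels_a[x] == labels_a[y]
            same_b = labels_b[x] == labels_b[y]
            agree += same_a == same_b
            total += 1
    return agree / total if total else 1.0


def validate_against_truth(report: dict, sim: FamilySimulation) -> dict:
    """Score pipeline outputs against the simulator's truth tables."""
    inferred = {}
    for i, cl in enumerate(report["clusters"]):
        for genome in cl.member_genomes:
            inferred[genome] = f"RC{i}"
    # clustering is defined over genomes with at least one intact homolog;
    # genomes whose whole complement was lost are outside its universe
    truth = {g: sim.true_clusters[g] for g in inferred}
    metrics = {"cluster_rand_index": rand_index(inferred, truth)}

    events = report["events"]
    correct = present = 0
    for family, true_node in sim.true_birth_node.items():
        if family not in events.index or events.loc[family, "births"] == 0:
            continue
        present += 1
        correct += events.loc[family, "birth_node"] == true_node
    metrics["birth_node_accuracy"] = correct / present if present else float("nan")

    motif_cols = {p - 1 for p in sim.params.motif_positions}
    overlap = 0.0
    if motif_cols and report["hcr_regions"]:
        covered = set()
        for r in report["hcr_regions"]:
            covered.update(range(r.start, r.end + 1))
        overlap = len(motif_cols & covered) / len(motif_cols)
    metrics["hcr_motif_overlap"] = overlap
    return metrics


def contact_fraction_rmse(
    profile_fractions: dict, planted: dict[int, float]
) -> float:
    """RMSE between measured ensemble contact fractions and planted targets."""
    errors = []
    for resnum, target in planted.items():
        measured = next(
            (v for (chain, num, name), v in profile_fractions.items() if num == resnum),
            None,
        )
        if measured is None:
            raise ValueError(f"residue {resnum} missing from profile")
        errors.append(measured - target)
    return float(np.sqrt(np.mean(np.square(errors))))
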