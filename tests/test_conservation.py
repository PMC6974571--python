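"""Logos, information content, domain identity, HCR and cluster-specific sites."""

import math
import random

import numpy as np
import pytest

from paralogpocket.conservation import (
    AlignmentMatrix,
    DomainAnnotation,
    cluster_specific_positions,
    column_statistics,
    detect_hcr,
    domain_partition_identity,
    slice_logo,
)
from paralogpocket.pipeline import default_simulation_params
from paralogpocket.seqsim import simulate_family_evolution

AAS = "ACDEFGHIKLMNPQRSTVWY"
LOG2_20 = math.log2(20)


def aln_from(rows):
    return AlignmentMatrix.from_strings(
        {f"s{i}": row for i, row in enumerate(rows)}
    )


class TestColumnStatistics:
    def test_invariant_column_has_maximal_information(self):
        logo = column_statistics(aln_from(["R", "R", "R", "R"]))
        assert logo.information[0] == pytest.approx(LOG2_20, abs=1e-9)

    def test_uniform_column_has_zero_information(self):
        logo = column_statistics(aln_from(list(AAS)))
        assert logo.information[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_state_column_loses_exactly_one_bit(self):
        logo = column_statistics(aln_from(["D", "D", "E", "E"]))
        assert logo.information[0] == pytest.approx(LOG2_20 - 1.0, abs=1e-9)

    def test_all_gap_column_flagged(self):
        logo = column_statistics(aln_from(["A-", "C-"]))
        assert logo.all_gap[1]
        assert np.isnan(logo.information[1])

    def test_ic_bounds_hold_on_random_alignments(self):
        rng = random.Random(3)
        rows = [
            "".join(rng.choice(AAS + "-") for _ in range(50)) for _ in range(12)
        ]
        logo = column_statistics(aln_from(rows))
        valid = ~logo.all_gap
        assert (logo.information[valid] >= 0).all()
        assert (logo.information[valid] <= LOG2_20 + 1e-12).all()

    def test_row_order_invariance(self):
        rng = random.Random(5)
        rows = ["".join(rng.choice(AAS) for _ in range(30)) for _ in range(8)]
        a = column_statistics(aln_from(rows))
        b = column_statistics(aln_from(list(reversed(rows))))
        np.testing.assert_allclose(a.information, b.information)
        np.testing.assert_allclose(a.frequencies, b.frequencies)

    def test_frequencies_sum_to_one_after_gap_exclusion(self):
        logo = column_statistics(aln_from(["A-C", "AAC", "A-C"]))
        for col in range(3):
            if not logo.all_gap[col]:
                assert logo.frequencies[col].sum() == pytest.approx(1.0, abs=1e-9)


class TestDomainIdentity:
    def test_identical_sequences_full_identity_everywhere(self):
        rows = {"r": "A" * 40, "s": "A" * 40}
        aln = AlignmentMatrix.from_strings(rows)
        domains = DomainAnnotation({"sensory": (1, 20), "signaling": (21, 40)})
        ident = domain_partition_identity(aln, domains, "r")
        assert ident == {"sensory": 100.0, "signaling": 100.0}

    def test_half_divergent_sensory_counts_fifty_percent(self):
        a = "A" * 20 + "W" * 20
        b = "A" * 10 + "C" * 10 + "W" * 20
        aln = AlignmentMatrix.from_strings({"a": a, "b": b})
        domains = DomainAnnotation({"sensory": (1, 20), "signaling": (21, 40)})
        ident = domain_partition_identity(aln, domains, "a")
        assert ident["sensory"] == pytest.approx(50.0)
        assert ident["signaling"] == pytest.approx(100.0)

    def test_empty_domain_rejected(self):
        aln = AlignmentMatrix.from_strings({"a": "AAAA", "b": "AAAA"})
        domains = DomainAnnotation({"tail": (10, 20)})
        with pytest.raises(ValueError, match="no alignment columns"):
            domain_partition_identity(aln, domains, "a")


class TestDetectHCR:
    def _conserved_cluster(self, rng, n_cols, motif_cols, n_rows=20):
        rows = []
        consensus = [rng.choice(AAS) for _ in range(n_cols)]
        for _ in range(n_rows):
            row = [
                consensus[c] if c in motif_cols else rng.choice(AAS)
                for c in range(n_cols)
            ]
            rows.append("".join(row))
        return column_statistics(aln_from(rows))

    def test_single_fully_conserved_cluster_spans_everything(self):
        logo = column_statistics(aln_from(["ACDEFGHIKLMN"] * 5))
        regions = detect_hcr({"c1": logo}, window=4, ic_threshold=2.5,
                             max_exceptions=0)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 11)

    def test_planted_motif_found_with_single_exception_cluster(self):
        """Four clusters share a 10-column motif; the fifth lacks it and is
        reported as the exception."""
        rng = random.Random(17)
        motif = set(range(20, 30))
        logos = {
            f"c{i}": self._conserved_cluster(rng, 60, motif) for i in range(1, 5)
        }
        logos["c5"] = self._conserved_cluster(rng, 60, set())
        regions = detect_hcr(logos, window=10, ic_threshold=2.5, max_exceptions=1)
        assert len(regions) == 1
        region = regions[0]
        # the region must cover the motif; window smearing may widen it by
        # at most window - 1 columns on either side
        assert region.start <= 20 and region.end >= 29
        assert region.start > 20 - 10 and region.end < 29 + 10
        assert region.clusters_absent == {"c5"}

    def test_unattainable_threshold_finds_nothing(self):
        logo = column_statistics(aln_from(["ACDEFGHIKLMN"] * 5))
        assert detect_hcr({"c1": logo}, window=4, ic_threshold=LOG2_20 + 0.1) == []

    def test_oversized_window_rejected(self):
        logo = column_statistics(aln_from(["ACDE"] * 3))
        with pytest.raises(ValueError, match="window"):
            detect_hcr({"c1": logo}, window=10)

    def test_simulated_families_localize_planted_motif(self):
        """On simulator output the HCR detector localizes the planted binding
        motif (>=80% column overlap) and flags the motif-free cluster in
        >=95/100 seeded replicates."""
        sensory_first, sensory_last = 31, 110
        motif_cols = {p - sensory_first for p in (61, 62, 64, 66, 68)}
        hits = 0
        for seed in range(100):
            logos = {}
            for c in range(4):
                sim = simulate_family_evolution(
                    default_simulation_params(
                        seed=1000 * seed + c, duplication_rate=0.0,
                        loss_rate=0.0, pseudogenization_prob=0.0,
                    )
                )
                aln = AlignmentMatrix.from_strings(
                    {s.seq_id: s.residues for s in sim.sequences}
                )
                logos[f"m{c}"] = slice_logo(
                    column_statistics(aln), sensory_first - 1, sensory_last
                )
            sim = simulate_family_evolution(
                default_simulation_params(
                    seed=1000 * seed + 7, duplication_rate=0.0, loss_rate=0.0,
                    pseudogenization_prob=0.0, motif_positions=(),
                    motif_residues="",
                )
            )
            aln = AlignmentMatrix.from_strings(
                {s.seq_id: s.residues for s in sim.sequences}
            )
            logos["nomotif"] = slice_logo(
                column_statistics(aln), sensory_first - 1, sensory_last
            )
            regions = detect_hcr(logos, window=10, ic_threshold=2.5,
                                 max_exceptions=1)
            best = None
            for r in regions:
                covered = set(range(r.start, r.end + 1)) & motif_cols
                if best is None or len(covered) > len(best[0]):
                    best = (covered, r)
            if best is None:
                continue
            covered, region = best
            if (
                len(covered) >= 0.8 * len(motif_cols)
                and region.clusters_absent == {"nomotif"}
            ):
                hits += 1
        assert hits >= 95


class TestClusterSpecificPositions:
    def test_identical_clusters_yield_nothing(self):
        logo = column_statistics(aln_from(["ACDE"] * 6))
        assert cluster_specific_positions({"a": logo, "b": logo}) == []

    def test_planted_divergent_conserved_column_reported(self):
        a = column_statistics(aln_from(["AQ" + "A" * 8] * 6))
        b = column_statistics(aln_from(["AE" + "A" * 8] * 6))
        out = cluster_specific_positions({"a": a, "b": b})
        assert [entry["column"] for entry in out] == [1]
        assert out[0]["consensus"] == {"a": "Q", "b": "E"}
        assert out[0]["between_divergence"] == 1.0

    def test_variable_column_not_reported(self):
        rng = random.Random(11)
        variable = ["A" + rng.choice(AAS) for _ in range(12)]
        a = column_statistics(aln_from(["AQ"] * 12))
        b = column_statistics(aln_from(variable))
        assert cluster_specific_positions({"a": a, "b": b}) == []
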