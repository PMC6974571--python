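"""Synthetic pocket/trajectory generator: planted geometry round-trips."""

import math

import numpy as np
import pytest

from paralogpocket.pocketsim import (
    GenerationError,
    PocketSpec,
    TrajectorySpec,
    generate_pocket_structure,
    generate_trajectory,
)
from paralogpocket.structures import (
    InteractionCriteria,
    classify_pocket_occupancy,
    contact_residues,
    detect_hbonds,
    detect_hydrophobic,
    ensemble_profile,
    find_ligand,
    parse_structure,
)


class TestPocketSpecValidation:
    def test_clashing_distance_rejected(self):
        with pytest.raises(ValueError, match="1.5"):
            PocketSpec(contact_distances=[1.2])

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="angle"):
            PocketSpec(hbond_geometries=[(2.8, 200.0, "ligand-carboxyl")])

    def test_unknown_partner_rejected(self):
        with pytest.raises(ValueError, match="partner"):
            PocketSpec(hbond_geometries=[(2.8, 5.0, "ligand-backbone")])


class TestGeneratedGeometry:
    def test_planted_distances_reproduced_within_hundredth_angstrom(self):
        spec = PocketSpec(contact_distances=[3.7, 4.4, 5.6, 7.2])
        model = parse_structure(generate_pocket_structure(spec))[0]
        ligand = find_ligand(model, resname="LIG")
        dists = contact_residues(model, ligand, InteractionCriteria(contact_cutoff=1e6))
        measured = [dists[("A", i + 1, "ALA")] for i in range(4)]
        assert measured == pytest.approx(spec.contact_distances, abs=0.01)

    def test_far_ligand_means_no_contacts(self):
        spec = PocketSpec(contact_distances=[10.0, 12.0])
        model = parse_structure(generate_pocket_structure(spec))[0]
        ligand = find_ligand(model, resname="LIG")
        assert contact_residues(model, ligand) == {}

    def test_single_planted_hbond_detected_exactly_once(self):
        spec = PocketSpec(hbond_geometries=[(2.8, 5.0, "ligand-carboxyl")])
        model = parse_structure(generate_pocket_structure(spec))[0]
        ligand = find_ligand(model, resname="LIG")
        bonds = detect_hbonds(model, ligand, mode="md")
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.8, abs=0.01)
        assert bonds[0].angle_deviation == pytest.approx(5.0, abs=0.5)

    def test_ligand_amino_partner_plants_protein_acceptor(self):
        spec = PocketSpec(hbond_geometries=[(2.7, 10.0, "ligand-amino")])
        model = parse_structure(generate_pocket_structure(spec))[0]
        ligand = find_ligand(model, resname="LIG")
        bonds = detect_hbonds(model, ligand, mode="md")
        assert len(bonds) == 1
        assert bonds[0].donor_residue == ligand.residue.key
        assert bonds[0].distance == pytest.approx(2.7, abs=0.01)

    def test_planted_hydrophobic_pair_reproduced(self):
        spec = PocketSpec(hydrophobic_pairs=[3.2])
        model = parse_structure(generate_pocket_structure(spec))[0]
        ligand = find_ligand(model, resname="LIG")
        pairs = detect_hydrophobic(model, ligand)
        assert len(pairs) == 1
        assert pairs[0][3] == pytest.approx(3.2, abs=0.01)

    def test_byte_identical_for_same_spec(self):
        spec = PocketSpec(contact_distances=[4.0, 5.0], seed=7)
        assert generate_pocket_structure(spec) == generate_pocket_structure(spec)


class TestTrajectory:
    def test_degenerate_fraction_one_gives_exact_unity(self, pocket_pdb_text):
        traj = generate_trajectory(
            pocket_pdb_text,
            TrajectorySpec(n_frames=20, per_residue_contact_fraction={1: 1.0},
                           seed=5),
        )
        profile = ensemble_profile(parse_structure(traj), "LIG")
        assert profile.contact_fraction[("A", 1, "ALA")] == 1.0

    def test_fraction_estimate_within_binomial_bound(self, pocket_pdb_text):
        frac, n = 0.6, 50
        traj = generate_trajectory(
            pocket_pdb_text,
            TrajectorySpec(n_frames=n, per_residue_contact_fraction={1: frac},
                           seed=42),
        )
        profile = ensemble_profile(parse_structure(traj), "LIG")
        bound = 3 * math.sqrt(frac * (1 - frac) / n)
        assert abs(profile.contact_fraction[("A", 1, "ALA")] - frac) <= bound

    def test_fraction_recovery_across_many_seeds(self, pocket_pdb_text):
        """Ensemble contact fractions land within the binomial 3-sigma band
        in >= 99/100 seeded 50-frame trajectories."""
        frac, n = 0.6, 50
        bound = 3 * math.sqrt(frac * (1 - frac) / n)
        ok = 0
        for seed in range(100):
            traj = generate_trajectory(
                pocket_pdb_text,
                TrajectorySpec(n_frames=n,
                               per_residue_contact_fraction={1: frac},
                               seed=seed),
            )
            models = parse_structure(traj)
            in_contact = 0
            for m in models:
                lig = find_ligand(m, resname="LIG")
                if ("A", 1, "ALA") in contact_residues(m, lig):
                    in_contact += 1
            ok += abs(in_contact / n - frac) <= bound
        assert ok >= 99

    def test_rate_one_and_a_half_gives_150_percent_occupancy(self, pocket_pdb_text):
        """An H-bond rate of 1.5 (two bonds in half the frames, one in the
        rest) shows up as ~150% occupancy frequency."""
        n = 50
        traj = generate_trajectory(
            pocket_pdb_text,
            TrajectorySpec(n_frames=n, per_residue_hbond_rate={4: 1.5}, seed=3),
        )
        profile = ensemble_profile(parse_structure(traj), "LIG")
        freq = profile.hbond_frequency[("A", 4, "DNR")]
        sigma = 100 * math.sqrt(0.25 / n)
        assert abs(freq - 150.0) <= 3 * sigma

    def test_unknown_residue_rejected(self, pocket_pdb_text):
        with pytest.raises(ValueError, match="not present"):
            generate_trajectory(
                pocket_pdb_text,
                TrajectorySpec(per_residue_contact_fraction={99: 0.5}),
            )

    def test_rate_beyond_donor_arms_rejected(self, pocket_pdb_text):
        with pytest.raises(ValueError, match="donor arms"):
            generate_trajectory(
                pocket_pdb_text, TrajectorySpec(per_residue_hbond_rate={4: 2.5})
            )

    def test_release_places_ligand_beyond_twelve_angstroms(self, pocket_pdb_text):
        traj = generate_trajectory(
            pocket_pdb_text, TrajectorySpec(n_frames=8, release_frame=4, seed=1)
        )
        models = parse_structure(traj)
        for m in models[4:]:
            lig = find_ligand(m, resname="LIG")
            contacts = contact_residues(
                m, lig, InteractionCriteria(contact_cutoff=12.0)
            )
            assert contacts == {}


def _merge_units(unit_texts):
    """Combine single-chain pocket units into one multi-chain model.

    Each unit is shifted along x and its chains/residue numbers relabelled
    so het groups stay associated with their own protein chain by distance.
    """
    lines = []
    serial = 1
    for i, text in enumerate(unit_texts):
        chain = chr(ord("A") + i)
        for line in text.splitlines():
            if not line.startswith(("ATOM", "HETATM")):
                continue
            x = float(line[30:38]) + 200.0 * i
            resnum = int(line[22:26])
            if line.startswith("HETATM"):
                resnum = 900 + i
            new = (
                f"{line[:6]}{serial:5d}{line[11:21]}{chain}{resnum:4d}"
                f"    {x:8.3f}{line[38:]}"
            )
            lines.append(new)
            serial += 1
    return "\n".join(lines + ["END"]) + "\n"


class TestAsymmetricUnitScenario:
    def test_seven_chain_occupancy_classification(self):
        """A seven-chain assembly with two ligand-inside chains, three
        at-entrance, one acetate-occupied and one empty classifies exactly."""
        inside = PocketSpec(contact_distances=[4.0] * 12, ligand_name="ABU")
        entrance = PocketSpec(
            contact_distances=[4.5, 4.8] + [6.5] * 10, ligand_name="ABU"
        )
        acetate = PocketSpec(contact_distances=[4.0] * 12, ligand_name="ACT")
        empty = PocketSpec(contact_distances=[8.0] * 12, ligand_name="ABU")
        units = [
            generate_pocket_structure(inside),
            generate_pocket_structure(inside),
            generate_pocket_structure(entrance),
            generate_pocket_structure(entrance),
            generate_pocket_structure(entrance),
            generate_pocket_structure(acetate),
            generate_pocket_structure(empty),
        ]
        model = parse_structure(_merge_units(units))[0]
        occ = classify_pocket_occupancy(model, set(range(1, 13)), "ABU")
        classes = sorted(occ.classes.values())
        assert classes.count("ligand-inside") == 2
        assert classes.count("ligand-at-entrance") == 3
        assert classes.count("other-molecule") == 1
        assert classes.count("empty") == 1
        assert len(occ.classes) == 7
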