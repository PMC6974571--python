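"""Structure parsing and interaction geometry: contacts, H-bonds, hydrophobics."""

import numpy as np
import pytest

from paralogpocket.structures import (
    AtomRecord,
    HBond,
    InteractionCriteria,
    ResidueRecord,
    StructureModel,
    classify_pocket_occupancy,
    contact_residues,
    detect_hbonds,
    detect_hydrophobic,
    detect_ligand_release,
    ensemble_profile,
    find_ligand,
    parse_structure,
)

from _oracles import all_pairs_min_distance, hbond_decision


def residue(chain, num, name, atoms, het=False):
    return ResidueRecord(
        chain_id=chain, resname=name, resnum=num, icode="", het=het,
        atoms=[AtomRecord(n, e, tuple(c)) for n, e, c in atoms],
    )


class TestParsing:
    def test_round_trip_atom_count(self, pocket_pdb_text):
        n_records = sum(
            1 for line in pocket_pdb_text.splitlines()
            if line.startswith(("ATOM", "HETATM"))
        )
        model = parse_structure(pocket_pdb_text)[0]
        assert model.n_atoms == n_records

    def test_altloc_b_dropped(self):
        text = (
            "ATOM      1  CA AALA A   1      11.000  12.000  13.000  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1      11.500  12.000  13.000  0.50  0.00           C\n"
            "ATOM      3  CB  ALA A   1      12.000  13.000  14.000  1.00  0.00           C\n"
            "END\n"
        )
        model = parse_structure(text)[0]
        names = [a.name for r in model.residues for a in r.atoms]
        assert names == ["CA", "CB"]

    def test_malformed_record_reports_line_number(self):
        text = (
            "ATOM      1  CA  ALA A   1      11.000  12.000  13.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1      xx.000  12.000  13.000  1.00  0.00           C\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            parse_structure(text)

    def test_multi_model_order_preserved(self, pocket_pdb_text):
        from paralogpocket.pocketsim import TrajectorySpec, generate_trajectory

        traj = generate_trajectory(pocket_pdb_text, TrajectorySpec(n_frames=3))
        models = parse_structure(traj)
        assert [m.model_id for m in models] == sorted(m.model_id for m in models)
        assert len(models) == 3

    def test_agreement_with_independent_pdb_reader(self, pocket_pdb_text):
        gemmi = pytest.importorskip("gemmi")
        st = gemmi.read_pdb_string(pocket_pdb_text)
        n_gemmi = sum(
            1 for mdl in st for ch in mdl for res in ch for at in res
        )
        model = parse_structure(pocket_pdb_text)[0]
        assert model.n_atoms == n_gemmi


class TestContacts:
    def test_far_ligand_yields_empty_set(self):
        protein = residue("A", 1, "ALA", [("CB", "C", (0, 0, 0))])
        lig = residue("L", 9, "LIG", [("C", "C", (10, 0, 0))], het=True)
        model = StructureModel([protein, lig])
        ligand = find_ligand(model, resname="LIG")
        assert contact_residues(model, ligand) == {}

    def test_planted_shell_two_of_three_within_cutoff(self, pocket_pdb_text):
        model = parse_structure(pocket_pdb_text)[0]
        ligand = find_ligand(model, resname="LIG")
        contacts = contact_residues(model, ligand)
        shell = {k: v for k, v in contacts.items() if k[2] == "ALA" and k[1] <= 3}
        assert len(shell) == 2
        assert contacts[("A", 1, "ALA")] == pytest.approx(4.0, abs=0.01)
        assert contacts[("A", 2, "ALA")] == pytest.approx(4.9, abs=0.01)

    def test_min_distances_match_exhaustive_oracle(self, pocket_pdb_text):
        model = parse_structure(pocket_pdb_text)[0]
        ligand = find_ligand(model, resname="LIG")
        contacts = contact_residues(model, ligand, InteractionCriteria(contact_cutoff=1e6))
        lig_xyz = ligand.heavy_coords()
        for res in model.polymer_residues():
            expected = all_pairs_min_distance(res.heavy_coords(), lig_xyz)
            assert contacts[res.key] == pytest.approx(expected, abs=1e-9)

    def test_cutoff_monotonicity(self, pocket_pdb_text):
        model = parse_structure(pocket_pdb_text)[0]
        ligand = find_ligand(model, resname="LIG")
        sizes = [
            len(contact_residues(model, ligand, InteractionCriteria(contact_cutoff=c)))
            for c in (3.0, 4.0, 5.0, 6.0, 8.0)
        ]
        assert sizes == sorted(sizes)


class TestHBonds:
    def _pair_model(self, donor_xyz, h_xyz, acceptor_xyz):
        protein = residue(
            "A", 1, "SER",
            [("OG", "O", donor_xyz), ("HG", "H", h_xyz)],
        )
        lig = residue("L", 9, "LIG", [("O1", "O", acceptor_xyz)], het=True)
        return StructureModel([protein, lig])

    def test_distance_failure_rejected(self):
        model = self._pair_model((0, 0, 0), (1.0, 0, 0), (3.2, 0, 0))
        ligand = find_ligand(model, resname="LIG")
        assert detect_hbonds(model, ligand, mode="md") == []

    def test_md_mode_without_hydrogens_directs_to_xray(self):
        protein = residue("A", 1, "SER", [("OG", "O", (0, 0, 0))])
        lig = residue("L", 9, "LIG", [("O1", "O", (2.8, 0, 0))], het=True)
        model = StructureModel([protein, lig])
        ligand = find_ligand(model, resname="LIG")
        with pytest.raises(ValueError, match="xray"):
            detect_hbonds(model, ligand, mode="md")
        assert len(detect_hbonds(model, ligand, mode="xray")) == 1

    def test_xray_mode_distance_cutoff(self):
        protein = residue("A", 1, "SER", [("OG", "O", (0, 0, 0))])
        model_near = StructureModel(
            [protein, residue("L", 9, "LIG", [("O1", "O", (3.3, 0, 0))], het=True)]
        )
        model_far = StructureModel(
            [protein, residue("L", 9, "LIG", [("O1", "O", (3.4, 0, 0))], het=True)]
        )
        assert len(detect_hbonds(model_near, find_ligand(model_near, "LIG"),
                                 mode="xray")) == 1
        assert detect_hbonds(model_far, find_ligand(model_far, "LIG"),
                             mode="xray") == []

    def test_decisions_match_geometric_oracle_on_random_configurations(self):
        """1,000 random donor/hydrogen/acceptor placements: the detector
        agrees with a direct re-derivation of the distance+angle rule."""
        rng = np.random.default_rng(2024)
        agreements = 0
        for _ in range(1000):
            donor = rng.uniform(-1, 1, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            h = donor + 1.0 * direction
            acceptor = donor + rng.uniform(1.6, 4.0) * _random_unit(rng)
            model = self._pair_model(tuple(donor), tuple(h), tuple(acceptor))
            ligand = find_ligand(model, resname="LIG")
            got = len(detect_hbonds(model, ligand, mode="md")) > 0
            expected = hbond_decision(donor, [h], acceptor)
            assert got == expected
            agreements += 1
        assert agreements == 1000


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestHydrophobic:
    def _model(self, lig_atoms, prot_atoms):
        protein = residue("A", 1, "ALA", prot_atoms)
        lig = residue("L", 9, "LIG", lig_atoms, het=True)
        return StructureModel([protein, lig])

    def test_apolar_carbon_pair_within_cutoff(self):
        model = self._model([("CB", "C", (0, 0, 0))], [("CB", "C", (3.5, 0, 0))])
        pairs = detect_hydrophobic(model, find_ligand(model, "LIG"))
        assert len(pairs) == 1
        assert pairs[0][3] == pytest.approx(3.5)

    def test_carbon_oxygen_pair_not_hydrophobic(self):
        model = self._model([("O1", "O", (0, 0, 0))], [("CB", "C", (3.5, 0, 0))])
        assert detect_hydrophobic(model, find_ligand(model, "LIG")) == []

    def test_pair_beyond_cutoff_rejected(self):
        model = self._model([("CB", "C", (0, 0, 0))], [("CB", "C", (4.5, 0, 0))])
        assert detect_hydrophobic(model, find_ligand(model, "LIG")) == []

    def test_carbon_bonded_to_polar_atom_excluded(self):
        # protein carbon 1.5 Å from its own oxygen: polar-adjacent, excluded
        model = self._model(
            [("CB", "C", (0, 0, 0))],
            [("C", "C", (3.5, 0, 0)), ("O", "O", (3.5, 1.5, 0))],
        )
        assert detect_hydrophobic(model, find_ligand(model, "LIG")) == []


class TestEnsembleProfile:
    def test_contact_fraction_is_plain_arithmetic(self, pocket_pdb_text):
        from paralogpocket.pocketsim import TrajectorySpec, generate_trajectory

        traj = generate_trajectory(
            pocket_pdb_text, TrajectorySpec(n_frames=10, seed=1)
        )
        models = parse_structure(traj)
        profile = ensemble_profile(models, "LIG")
        assert profile.n_frames == 10
        # static shell residues: always or never in contact
        assert profile.contact_fraction[("A", 1, "ALA")] == 1.0
        assert profile.contact_fraction[("A", 3, "ALA")] == 0.0

    def test_double_bond_every_frame_gives_200_percent(self, pocket_pdb_text):
        from paralogpocket.pocketsim import TrajectorySpec, generate_trajectory

        traj = generate_trajectory(
            pocket_pdb_text,
            TrajectorySpec(n_frames=5, per_residue_hbond_rate={4: 2.0}, seed=0),
        )
        profile = ensemble_profile(parse_structure(traj), "LIG")
        assert profile.hbond_frequency[("A", 4, "DNR")] == pytest.approx(200.0)

    def test_missing_residue_names_offending_frame(self, pocket_pdb_text):
        models = parse_structure(pocket_pdb_text) * 2
        broken = StructureModel(models[1].residues[1:], model_id=1)
        with pytest.raises(ValueError, match="frame 1"):
            ensemble_profile([models[0], broken], "LIG")


class TestOccupancyAndRelease:
    def test_empty_pocket_classified_empty(self):
        shell = [
            residue("A", i, "ALA", [("CB", "C", (float(i), 20.0, 0.0))])
            for i in range(1, 13)
        ]
        lig = residue("L", 900, "ABU", [("C", "C", (0, 0, 0))], het=True)
        model = StructureModel(shell + [lig])
        occ = classify_pocket_occupancy(model, set(range(1, 13)), "ABU")
        assert occ.classes == {"A": "empty"}

    def test_ligand_with_many_pocket_contacts_is_inside(self):
        from paralogpocket.pocketsim import PocketSpec, generate_pocket_structure

        text = generate_pocket_structure(
            PocketSpec(contact_distances=[4.0] * 12, ligand_name="ABU")
        )
        model = parse_structure(text)[0]
        occ = classify_pocket_occupancy(model, set(range(1, 13)), "ABU")
        assert occ.classes == {"A": "ligand-inside"}

    def test_static_ligand_never_released(self, pocket_pdb_text):
        from paralogpocket.pocketsim import TrajectorySpec, generate_trajectory

        traj = generate_trajectory(pocket_pdb_text, TrajectorySpec(n_frames=6))
        models = parse_structure(traj)
        assert detect_ligand_release(models, "LIG", {1, 2, 3}) is None

    def test_planted_release_frame_recovered(self, pocket_pdb_text):
        from paralogpocket.pocketsim import TrajectorySpec, generate_trajectory

        traj = generate_trajectory(
            pocket_pdb_text, TrajectorySpec(n_frames=20, release_frame=13, seed=2)
        )
        models = parse_structure(traj)
        assert detect_ligand_release(models, "LIG", {1, 2, 3}) == 13

    def test_transient_excursion_is_not_release(self):
        def frame(x):
            prot = residue("A", 1, "ALA", [("CB", "C", (0.0, 0.0, 0.0))])
            lig = residue("L", 9, "LIG", [("C", "C", (x, 0.0, 0.0))], het=True)
            return StructureModel([prot, lig])

        models = [frame(4.0), frame(12.0), frame(4.0), frame(4.5)]
        assert detect_ligand_release(models, "LIG", {1}) is None
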