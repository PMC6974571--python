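"""Ligand-contact, hydrogen-bond and hydrophobic-interaction analysis of structures.

Operates on ligand-bound sensor-domain structures in PDB format, either a
single crystallographic model or an ordered multi-model ensemble standing in
for trajectory snapshots.  Interaction criteria follow the conventions used
for chemoreceptor ligand-binding domains:

* contact: any residue heavy atom within 5 Å of a ligand heavy atom;
* hydrogen bond (``md`` mode, explicit hydrogens): donor–acceptor distance
  < 3 Å and donor–hydrogen···acceptor deviation from linearity <= 20°;
* hydrogen bond (``xray`` mode, hydrogen-free models): chemical donor/
  acceptor typing with donor–acceptor distance <= 3.35 Å and no angle term;
* hydrophobic: apolar carbon pairs (carbons covalently bonded to no N/O/S)
  within 4 Å.

Ensemble profiles report per-residue contact fractions and hydrogen-bond
occupancy as a percentage of frames; occupancies above 100% indicate that a
residue forms more than one simultaneous bond.  Pocket-occupancy
classification assigns each chain one of {ligand-inside, ligand-at-entrance,
other-molecule, empty} from contact counts against a reference pocket
residue set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

WATER_NAMES = {"HOH", "WAT", "DOD"}
_COVALENT_H_MAX = 1.25  # Å, hydrogen to its bonded heavy atom
_COVALENT_HEAVY_MAX = 1.9  # Å, heavy-heavy covalent bond inference

#: atom names acting as H-bond donors in hydrogen-free (X-ray) mode
XRAY_DONORS = {
    "N", "ND1", "ND2", "NE", "NE1", "NE2", "NH1", "NH2", "NZ",
    "OG", "OG1", "OH", "SG", "OXT",
}
#: atom names acting as H-bond acceptors in hydrogen-free (X-ray) mode
XRAY_ACCEPTORS = {
    "O", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "OXT",
    "ND1", "NE2", "SD", "O1", "O2", "O3", "O4",
}

CARBOXYL_ATOMS = {"C", "O", "OXT", "O1", "O2", "OT1", "OT2", "C1"}
AMINO_ATOMS = {"N", "N1"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure model."""

    name: str
    element: str
    coord: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class ResidueRecord:
    """One residue (polymer or hetero) of a structure model."""

    chain_id: str
    resname: str
    resnum: int
    icode: str
    het: bool
    atoms: list[AtomRecord]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.resname)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.resname}{self.resnum}{self.icode}".strip()

    def heavy_coords(self) -> np.ndarray:
        pts = [a.xyz for a in self.atoms if not a.is_hydrogen]
        return np.array(pts) if pts else np.empty((0, 3))

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """A single model: residues grouped by chain, in file order."""

    residues: list[ResidueRecord]
    model_id: int = 0

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def protein_chains(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if not res.het and res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def polymer_residues(self) -> list[ResidueRecord]:
        return [r for r in self.residues if not r.het]

    def het_residues(self, include_water: bool = False) -> list[ResidueRecord]:
        out = [r for r in self.residues if r.het]
        if not include_water:
            out = [r for r in out if r.resname not in WATER_NAMES]
        return out

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass
class InteractionCriteria:
    """Distance/angle cutoffs for interaction calls (Å, degrees)."""

    contact_cutoff: float = 5.0
    hbond_da_max: float = 3.0
    hbond_angle_max_deviation: float = 20.0
    hydrophobic_cutoff: float = 4.0
    xray_hbond_da_max: float = 3.35

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class HBond:
    """A detected hydrogen bond (donor heavy atom to acceptor)."""

    donor_residue: tuple[str, int, str]
    donor_atom: str
    acceptor_residue: tuple[str, int, str]
    acceptor_atom: str
    distance: float
    angle_deviation: float | None  # None in X-ray mode


def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"line {lineno}: truncated coordinate record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: malformed coordinates in record"
                ) from exc


def parse_structure(pdb_text: str) -> list[StructureModel]:
    """Parse PDB-format text into an ordered list of models.

    Single-model files yield a one-element list.  Alternate locations other
    than blank/'A' are dropped (standard altloc policy); coordinates must be
    finite.  Malformed ATOM/HETATM records raise with their line number.
    """
    _validate_pdb_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", io.StringIO(pdb_text))
    models: list[StructureModel] = []
    for model in structure:
        residues: list[ResidueRecord] = []
        for chain in model:
            for residue in chain:
                hetflag, resnum, icode = residue.id
                atoms: list[AtomRecord] = []
                for atom in residue.get_unpacked_list():
                    if atom.get_altloc() not in (" ", "A", ""):
                        continue
                    coord = atom.get_coord()
                    if not np.isfinite(coord).all():
                        raise ValueError(
                            f"non-finite coordinates at atom {atom.get_full_id()}"
                        )
                    element = (atom.element or "").strip().upper()
                    atoms.append(
                        AtomRecord(
                            name=atom.get_name().strip(),
                            element=element,
                            coord=tuple(float(x) for x in coord),
                            altloc=atom.get_altloc().strip(),
                            occupancy=float(atom.get_occupancy() or 1.0),
                        )
                    )
                if atoms:
                    residues.append(
                        ResidueRecord(
                            chain_id=chain.id,
                            resname=residue.get_resname().strip(),
                            resnum=int(resnum),
                            icode=str(icode).strip(),
                            het=hetflag.strip() != "",
                            atoms=atoms,
                        )
                    )
        models.append(StructureModel(residues=residues, model_id=model.id))
    if not models:
        raise ValueError("no models found in PDB text")
    return models


@dataclass
class LigandInstance:
    """A bound small molecule with functional-group atom sets."""

    residue: ResidueRecord
    carboxyl: list[AtomRecord] = field(default_factory=list)
    amino: list[AtomRecord] = field(default_factory=list)
    sidechain: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.carboxyl and not self.amino and not self.sidechain:
            for atom in self.residue.atoms:
                if atom.is_hydrogen:
                    continue
                if atom.name in CARBOXYL_ATOMS:
                    self.carboxyl.append(atom)
                elif atom.name in AMINO_ATOMS:
                    self.amino.append(atom)
                else:
                    self.sidechain.append(atom)
        if not self.heavy_atoms:
            raise ValueError(f"ligand {self.residue.label} has no heavy atoms")

    @property
    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.residue.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.heavy_atoms])


def find_ligand(
    model: StructureModel,
    resname: str | None = None,
    chain: str | None = None,
    resnum: int | None = None,
) -> LigandInstance:
    """Select a bound ligand by residue name and/or explicit (chain, resnum)."""
    candidates = [
        r
        for r in model.het_residues()
        if (resname is None or r.resname == resname)
        and (chain is None or r.chain_id == chain)
        and (resnum is None or r.resnum == resnum)
    ]
    if not candidates:
        raise ValueError(
            f"no ligand matching resname={resname} chain={chain} resnum={resnum}"
        )
    return LigandInstance(residue=candidates[0])


def contact_residues(
    model: StructureModel,
    ligand: LigandInstance,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> dict[tuple[str, int, str], float]:
    """Residues with any heavy atom within the contact cutoff of the ligand.

    Returns {residue key: minimum heavy-atom distance} for residues passing
    the cutoff.
    """
    lig_xyz = ligand.heavy_coords()
    out: dict[tuple[str, int, str], float] = {}
    for res in model.polymer_residues():
        xyz = res.heavy_coords()
        if xyz.size == 0:
            continue
        dmin = float(cdist(xyz, lig_xyz).min())
        if dmin < criteria.contact_cutoff:
            out[res.key] = dmin
    return out


def _bonded_hydrogens(residue: ResidueRecord, heavy: AtomRecord) -> list[AtomRecord]:
    return [
        a
        for a in residue.atoms
        if a.is_hydrogen
        and float(np.linalg.norm(a.xyz - heavy.xyz)) <= _COVALENT_H_MAX
    ]


def _angle_deviation(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Deviation of the D-H...A angle from linearity (degrees)."""
    v1 = d - h
    v2 = a - h
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - angle


def _has_hydrogens(model: StructureModel) -> bool:
    return any(a.is_hydrogen for r in model.residues for a in r.atoms)


def _donor_candidates_md(residue: ResidueRecord):
    for atom in residue.atoms:
        if atom.element in ("N", "O", "S"):
            hydrogens = _bonded_hydrogens(residue, atom)
            if hydrogens:
                yield atom, hydrogens


def _acceptor_candidates_md(residue: ResidueRecord):
    for atom in residue.atoms:
        if atom.element in ("N", "O"):
            yield atom


def detect_hbonds(
    model: StructureModel,
    ligand: LigandInstance,
    criteria: InteractionCriteria = InteractionCriteria(),
    mode: str = "md",
) -> list[HBond]:
    """Hydrogen bonds between the ligand and the protein.

    ``md`` mode requires explicit hydrogens and applies the geometric
    criterion (D-A < 3 Å, deviation from linearity <= 20°); ``xray`` mode
    works on hydrogen-free models via donor/acceptor atom typing and a
    relaxed D-A <= 3.35 Å cutoff.  Water-mediated bonds are never counted
    (waters are excluded outright).
    """
    if mode not in ("md", "xray"):
        raise ValueError("mode must be 'md' or 'xray'")
    lig_res = ligand.residue
    protein = model.polymer_residues()
    bonds: list[HBond] = []

    if mode == "md":
        if not _has_hydrogens(model):
            raise ValueError(
                "md mode needs explicit hydrogens; use mode='xray' for "
                "hydrogen-free crystallographic models"
            )
        # protein donor -> ligand acceptor
        for res in protein:
            for donor, hydrogens in _donor_candidates_md(res):
                for acceptor in _acceptor_candidates_md(lig_res):
                    dist = float(np.linalg.norm(donor.xyz - acceptor.xyz))
                    if dist >= criteria.hbond_da_max:
                        continue
                    dev = min(
                        _angle_deviation(donor.xyz, h.xyz, acceptor.xyz)
                        for h in hydrogens
                    )
                    if dev <= criteria.hbond_angle_max_deviation:
                        bonds.append(
                            HBond(res.key, donor.name, lig_res.key, acceptor.name,
                                  dist, dev)
                        )
        # ligand donor -> protein acceptor
        for donor, hydrogens in _donor_candidates_md(lig_res):
            for res in protein:
                for acceptor in _acceptor_candidates_md(res):
                    dist = float(np.linalg.norm(donor.xyz - acceptor.xyz))
                    if dist >= criteria.hbond_da_max:
                        continue
                    dev = min(
                        _angle_deviation(donor.xyz, h.xyz, acceptor.xyz)
                        for h in hydrogens
                    )
                    if dev <= criteria.hbond_angle_max_deviation:
                        bonds.append(
                            HBond(lig_res.key, donor.name, res.key, acceptor.name,
                                  dist, dev)
                        )
        return bonds

    # X-ray mode: typed donors/acceptors, distance-only criterion.  Without
    # hydrogens the donation direction of an O...O / O...N pair is ambiguous,
    # so each physical atom pair is reported once (protein side listed as
    # donor when its atom is donor-typed).
    lig_polar = [a for a in ligand.heavy_atoms if a.element in ("N", "O")]
    seen: set[tuple] = set()
    for res in protein:
        for prot_atom in res.atoms:
            donor_typed = prot_atom.name in XRAY_DONORS
            acceptor_typed = prot_atom.name in XRAY_ACCEPTORS
            if not donor_typed and not acceptor_typed:
                continue
            for lig_atom in lig_polar:
                dist = float(np.linalg.norm(prot_atom.xyz - lig_atom.xyz))
                if dist > criteria.xray_hbond_da_max:
                    continue
                pair = (res.key, prot_atom.name, lig_atom.name)
                if pair in seen:
                    continue
                seen.add(pair)
                if donor_typed:
                    bonds.append(
                        HBond(res.key, prot_atom.name, lig_res.key,
                              lig_atom.name, dist, None)
                    )
                else:
                    bonds.append(
                        HBond(lig_res.key, lig_atom.name, res.key,
                              prot_atom.name, dist, None)
                    )
    return bonds


def _apolar_carbons(residue: ResidueRecord) -> list[AtomRecord]:
    """Carbons covalently bonded (distance-inferred) to no N/O/S in the residue."""
    heteroatoms = [a for a in residue.atoms if a.element in ("N", "O", "S")]
    out = []
    for atom in residue.atoms:
        if atom.element != "C":
            continue
        bonded_polar = any(
            float(np.linalg.norm(atom.xyz - h.xyz)) <= _COVALENT_HEAVY_MAX
            for h in heteroatoms
        )
        if not bonded_polar:
            out.append(atom)
    return out


def detect_hydrophobic(
    model: StructureModel,
    ligand: LigandInstance,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[tuple[tuple[str, int, str], str, str, float]]:
    """Apolar carbon pairs (protein residue, protein atom, ligand atom, distance)."""
    lig_apolar = _apolar_carbons(ligand.residue)
    pairs = []
    for res in model.polymer_residues():
        for pa in _apolar_carbons(res):
            for la in lig_apolar:
                dist = float(np.linalg.norm(pa.xyz - la.xyz))
                if dist < criteria.hydrophobic_cutoff:
                    pairs.append((res.key, pa.name, la.name, dist))
    return pairs


@dataclass
class ContactProfile:
    """Per-residue interaction statistics over an ensemble of models."""

    n_frames: int
    contact_fraction: dict[tuple[str, int, str], float]
    hbond_frequency: dict[tuple[str, int, str], float]  # %, may exceed 100
    hydrophobic_fraction: dict[tuple[str, int, str], float]
    hbond_partners: set[tuple[str, int, str]]
    hydrophobic_partners: set[tuple[str, int, str]]


def ensemble_profile(
    models: list[StructureModel],
    ligand_resname: str,
    criteria: InteractionCriteria = InteractionCriteria(),
    hbond_mode: str = "md",
) -> ContactProfile:
    """Aggregate contact/H-bond/hydrophobic statistics across ordered models.

    contact_fraction = frames with the residue within the contact cutoff /
    total frames; hbond_frequency = 100 x (total bonds formed by the
    residue across frames) / frames, which exceeds 100% when a residue
    maintains more than one simultaneous bond.
    """
    if not models:
        raise ValueError("need at least one model")
    keys = [r.key for r in models[0].polymer_residues()]
    key_set = set(keys)
    for i, model in enumerate(models[1:], start=1):
        frame_keys = {r.key for r in model.polymer_residues()}
        if frame_keys != key_set:
            missing = sorted(key_set ^ frame_keys)
            raise ValueError(f"frame {i}: residue set differs ({missing[:3]} ...)")

    contact = {k: 0 for k in keys}
    hbonds = {k: 0 for k in keys}
    hydro = {k: 0 for k in keys}
    for model in models:
        ligand = find_ligand(model, resname=ligand_resname)
        for key in contact_residues(model, ligand, criteria):
            contact[key] += 1
        for bond in detect_hbonds(model, ligand, criteria, mode=hbond_mode):
            res_key = (
                bond.donor_residue
                if bond.donor_residue != ligand.residue.key
                else bond.acceptor_residue
            )
            if res_key in hbonds:
                hbonds[res_key] += 1
        seen_hydro = {pair[0] for pair in detect_hydrophobic(model, ligand, criteria)}
        for key in seen_hydro:
            hydro[key] += 1

    n = len(models)
    return ContactProfile(
        n_frames=n,
        contact_fraction={k: contact[k] / n for k in keys},
        hbond_frequency={k: 100.0 * hbonds[k] / n for k in keys},
        hydrophobic_fraction={k: hydro[k] / n for k in keys},
        hbond_partners={k for k in keys if hbonds[k] > 0},
        hydrophobic_partners={k for k in keys if hydro[k] > 0},
    )


@dataclass
class PocketOccupancy:
    """Per-chain pocket occupancy classification."""

    classes: dict[str, str]  # chain -> class
    evidence: dict[str, dict]  # chain -> contact counts per het group


def classify_pocket_occupancy(
    model: StructureModel,
    pocket_residues: set[int],
    target_resname: str,
    criteria: InteractionCriteria = InteractionCriteria(),
    inside_min_contacts: int = 10,
) -> PocketOccupancy:
    """Classify each protein chain's pocket as one of four occupancy classes.

    ``pocket_residues`` are author residue numbers on the reference chain,
    mapped to every chain by shared numbering.  A chain is ``ligand-inside``
    when the target ligand contacts at least ``inside_min_contacts`` pocket
    residues within the contact cutoff; ``ligand-at-entrance`` when it
    contacts at least one but fewer; ``other-molecule`` when a different
    het group satisfies the inside rule; ``empty`` otherwise.
    """
    classes: dict[str, str] = {}
    evidence: dict[str, dict] = {}
    for chain in model.protein_chains():
        pocket = [
            r
            for r in model.polymer_residues()
            if r.chain_id == chain and r.resnum in pocket_residues
        ]
        if not pocket:
            raise ValueError(f"chain {chain}: no pocket residues mappable")
        pocket_xyz = {r.key: r.heavy_coords() for r in pocket}
        counts: dict[str, int] = {}
        target_count = 0
        for het in model.het_residues():
            het_xyz = np.array([a.xyz for a in het.atoms if not a.is_hydrogen])
            if het_xyz.size == 0:
                continue
            n_contacts = sum(
                1
                for xyz in pocket_xyz.values()
                if xyz.size and cdist(xyz, het_xyz).min() < criteria.contact_cutoff
            )
            if n_contacts == 0:
                continue
            counts[het.label] = n_contacts
            if het.resname == target_resname:
                target_count = max(target_count, n_contacts)
        other_inside = any(
            n >= inside_min_contacts
            for label, n in counts.items()
            if target_resname not in label
        )
        if target_count >= inside_min_contacts:
            classes[chain] = "ligand-inside"
        elif target_count >= 1:
            classes[chain] = "ligand-at-entrance"
        elif other_inside:
            classes[chain] = "other-molecule"
        else:
            classes[chain] = "empty"
        evidence[chain] = counts
    return PocketOccupancy(classes=classes, evidence=evidence)


def detect_ligand_release(
    models: list[StructureModel],
    ligand_resname: str,
    pocket_residues: set[int],
    release_distance: float = 8.0,
) -> int | None:
    """First frame from which the ligand stays beyond the release distance.

    Returns the index of the first frame such that in every frame from it
    onward the minimum ligand–pocket heavy-atom distance exceeds
    ``release_distance``; ``None`` if the ligand never permanently leaves.
    A transient excursion followed by a return does not count.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 frames")
    min_dists = []
    for model in models:
        ligand = find_ligand(model, resname=ligand_resname)
        lig_xyz = ligand.heavy_coords()
        pocket_pts = [
            r.heavy_coords()
            for r in model.polymer_residues()
            if r.resnum in pocket_residues
        ]
        pocket_xyz = np.vstack([p for p in pocket_pts if p.size])
        min_dists.append(float(cdist(pocket_xyz, lig_xyz).min()))
    release = None
    for i in range(len(min_dists) - 1, -1, -1):
        if min_dists[i] > release_distance:
            release = i
        else:
            break
    return release
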