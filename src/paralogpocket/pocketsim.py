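"""Generate toy ligand-bound pocket structures and trajectory-like ensembles.

The generator plants exactly specified interaction geometries around a small
amino-acid-like ligand so that every structural statistic downstream
(contacts at 5 Å, hydrogen bonds under the distance+angle criterion,
hydrophobic carbon pairs at 4 Å, per-frame occupancy frequencies, ligand
release) can be validated against construction truth:

* shell residues are placed so that their minimum heavy-atom distance to the
  ligand equals a requested value to within 0.01 Å;
* donor residues carry two hydroxyl arms (OG1/HG1, OG2/HG2) so a residue can
  form zero, one or two simultaneous hydrogen bonds — occupancy frequencies
  above 100% are therefore constructible;
* trajectories are multi-model PDB ensembles in which per-frame contact is
  Bernoulli with a planted per-residue fraction, hydrogen-bond counts follow
  floor(rate) + Bernoulli(fractional part), and an optional release frame
  moves the ligand permanently out of the pocket.

Geometries are solved numerically (bisection on the placement radius and on
the donor-hydrogen tilt) and every emitted structure is re-measured before
being returned; infeasible requests raise :class:`GenerationError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .structures import (
    InteractionCriteria,
    StructureModel,
    contact_residues,
    detect_hbonds,
    find_ligand,
    parse_structure,
)

MIN_CLEARANCE = 1.5  # Å, non-bonded inter-residue minimum


class GenerationError(ValueError):
    """Raised when a requested geometry cannot be realised without clashes."""


@dataclass
class PocketSpec:
    """Planted geometry of a synthetic binding pocket.

    ``contact_distances`` give, per shell residue, the minimum heavy-atom
    distance from the residue to the ligand.  ``hbond_geometries`` are
    (donor-acceptor distance Å, deviation-from-linearity angle °, partner)
    with partner one of ``ligand-carboxyl``, ``ligand-amino``,
    ``ligand-sidechain``.  ``hydrophobic_pairs`` are apolar carbon-carbon
    distances.
    """

    contact_distances: list[float] = field(default_factory=list)
    hbond_geometries: list[tuple[float, float, str]] = field(default_factory=list)
    hydrophobic_pairs: list[float] = field(default_factory=list)
    ligand_name: str = "LIG"
    seed: int = 0

    def __post_init__(self) -> None:
        for d in self.contact_distances:
            if d <= MIN_CLEARANCE:
                raise ValueError("contact distances must exceed 1.5 Å")
        for d, ang, partner in self.hbond_geometries:
            if d <= MIN_CLEARANCE:
                raise ValueError("H-bond distances must exceed 1.5 Å")
            if not 0.0 <= ang <= 180.0:
                raise ValueError("angles must lie in [0°, 180°]")
            if partner not in ("ligand-carboxyl", "ligand-amino", "ligand-sidechain"):
                raise ValueError(f"unknown H-bond partner {partner!r}")
        for d in self.hydrophobic_pairs:
            if d <= MIN_CLEARANCE:
                raise ValueError("hydrophobic distances must exceed 1.5 Å")

    @property
    def n_shell_residues(self) -> int:
        return len(self.contact_distances)


@dataclass
class TrajectorySpec:
    """Planted per-frame statistics for a synthetic ensemble.

    ``per_residue_contact_fraction`` maps residue number -> target fraction
    of frames within 5 Å.  ``per_residue_hbond_rate`` maps residue number ->
    expected hydrogen bonds per frame (up to 2 for donor residues; per-frame
    counts are floor(rate) + Bernoulli(rate - floor)).  Frames from
    ``release_frame`` onward place the ligand >= 12 Å from every pocket
    residue.  50 frames emulate 0.2-ns snapshots over a 10-ns run.
    """

    n_frames: int = 50
    per_residue_contact_fraction: dict[int, float] = field(default_factory=dict)
    per_residue_hbond_rate: dict[int, float] = field(default_factory=dict)
    release_frame: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for frac in self.per_residue_contact_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("contact fractions must lie in [0, 1]")
        for rate in self.per_residue_hbond_rate.values():
            if rate < 0:
                raise ValueError("hbond rates must be >= 0")
        overlap = set(self.per_residue_contact_fraction) & set(
            self.per_residue_hbond_rate
        )
        if overlap:
            raise ValueError(
                f"residues {sorted(overlap)} listed for both contact and H-bond control"
            )


# --- ligand template (heavy atoms + amino hydrogens), compact around origin ---

_LIGAND_ATOMS: list[tuple[str, str, tuple[float, float, float]]] = [
    ("C", "C", (0.00, 0.00, 0.00)),     # carboxyl carbon
    ("O1", "O", (1.25, 0.00, 0.00)),    # carboxyl oxygen
    ("O2", "O", (-0.62, -1.08, 0.00)),  # carboxyl oxygen
    ("CA", "C", (-0.76, 1.32, 0.00)),
    ("N", "N", (-2.21, 1.32, 0.00)),    # amino nitrogen
    ("H1", "H", (-2.55, 2.26, 0.00)),
    ("H2", "H", (-2.55, 0.85, 0.82)),
    ("H3", "H", (-2.55, 0.85, -0.82)),
    ("CB", "C", (-0.27, 2.08, 1.23)),   # apolar side chain
    ("CG", "C", (-0.95, 1.77, 2.55)),   # apolar side chain
    ("OG", "O", (-0.33, 2.42, 3.62)),   # polar side-chain tip
]

_LIG_COORD = {name: np.array(xyz) for name, _, xyz in _LIGAND_ATOMS}
_LIG_HEAVY = np.array(
    [xyz for name, el, xyz in _LIGAND_ATOMS if el != "H"]
)

_PARTNER_ACCEPTORS = {
    "ligand-carboxyl": ("O1", "O2"),
    "ligand-sidechain": ("OG", "OG"),
}


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _solve_shell_radius(direction: np.ndarray, target: float,
                        points: np.ndarray) -> float:
    """Radius r so that min_p |r*direction - p| = target (points near origin)."""
    reach = float(np.linalg.norm(points, axis=1).max())

    def f(r: float) -> float:
        return float(np.linalg.norm(r * direction - points, axis=1).min()) - target

    lo, hi = max(target - reach - 0.2, 1e-3), target + reach + 0.2
    if f(lo) > 0 or f(hi) < 0:
        raise GenerationError("cannot bracket shell placement radius")
    return float(brentq(f, lo, hi, xtol=1e-10))


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return v, w


#: ALA-like residue template in a local frame whose +x axis points away from
#: the ligand; the CB atom sits at the local origin (nearest to the ligand).
_SHELL_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("CB", "C", (0.00, 0.00, 0.00)),
    ("CA", "C", (1.45, 0.45, 0.00)),
    ("N", "N", (2.35, 1.55, 0.00)),
    ("C", "C", (2.50, -0.55, 0.00)),
    ("O", "O", (3.60, -1.10, 0.00)),
]


def _place_template(
    template: list[tuple[str, str, tuple[float, float, float]]],
    anchor: np.ndarray,
    u: np.ndarray,
) -> list[tuple[str, str, np.ndarray]]:
    v, w = _orthonormal_frame(u)
    placed = []
    for name, element, (a, b, c) in template:
        placed.append((name, element, anchor + a * u + b * v + c * w))
    return placed


def _tilted_hydrogen(
    donor: np.ndarray, acceptor: np.ndarray, deviation_deg: float,
    bond_length: float = 1.0,
) -> np.ndarray:
    """Hydrogen on the donor making the D-H...A angle deviate as requested."""
    e = acceptor - donor
    e /= np.linalg.norm(e)
    v, _ = _orthonormal_frame(e)

    def dev(theta: float) -> float:
        h = donor + bond_length * (np.cos(theta) * e + np.sin(theta) * v)
        v1 = donor - h
        v2 = acceptor - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return (180.0 - angle) - deviation_deg

    if deviation_deg < 1e-9:
        theta = 0.0
    else:
        theta = brentq(dev, 0.0, np.pi / 2 - 0.05, xtol=1e-12)
    return donor + bond_length * (np.cos(theta) * e + np.sin(theta) * v)


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int,
    xyz: np.ndarray, element: str, het: bool,
) -> str:
    record = "HETATM" if het else "ATOM  "
    atom_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record}{serial:5d} {atom_field}{'':1s}{resname:<3s} {chain}{resnum:4d}"
        f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


@dataclass
class _BuiltResidue:
    resname: str
    resnum: int
    atoms: list[tuple[str, str, np.ndarray]]  # (name, element, coord)
    role: str  # shell | donor | acceptor | hydrophobic


def _clashes(
    atoms: list[tuple[str, str, np.ndarray]],
    placed: list[_BuiltResidue],
    lig_heavy: np.ndarray,
) -> bool:
    from scipy.spatial.distance import cdist

    cloud = np.array([xyz for _, _, xyz in atoms])
    if cdist(cloud, lig_heavy).min() < MIN_CLEARANCE:
        return True
    for res in placed:
        other = np.array([xyz for _, _, xyz in res.atoms])
        if cdist(cloud, other).min() < MIN_CLEARANCE:
            return True
    return False


def _build_pocket(spec: PocketSpec) -> tuple[list[_BuiltResidue], list]:
    """Place all residues, retrying alternative directions on steric clashes."""
    n_total = spec.n_shell_residues + len(spec.hbond_geometries) + len(
        spec.hydrophobic_pairs
    )
    # a generous pool of well-spread candidate directions for retries
    directions = _fibonacci_directions(max(4 * n_total, 16))
    residues: list[_BuiltResidue] = []
    resnum = 1
    d_idx = 0

    def next_direction() -> np.ndarray:
        nonlocal d_idx
        u = directions[d_idx % len(directions)]
        d_idx += 1
        return u

    def place_or_raise(build, label: str, resname: str, role: str) -> None:
        nonlocal resnum
        for _attempt in range(len(directions)):
            atoms = build(next_direction())
            if not _clashes(atoms, residues, _LIG_HEAVY):
                residues.append(_BuiltResidue(resname, resnum, atoms, role))
                resnum += 1
                return
        raise GenerationError(f"cannot place {label} without a clash")

    for dist in spec.contact_distances:

        def build_shell(u: np.ndarray, dist=dist):
            r = _solve_shell_radius(u, dist, _LIG_HEAVY)
            return _place_template(_SHELL_TEMPLATE, r * u, u)

        place_or_raise(build_shell, f"shell residue at {dist} Å", "ALA", "shell")

    for dist, dev, partner in spec.hbond_geometries:
        if partner in _PARTNER_ACCEPTORS:
            acc1_name, _acc2_name = _PARTNER_ACCEPTORS[partner]
            acc1 = _LIG_COORD[acc1_name]

            def build_donor(u: np.ndarray, acc1=acc1, dist=dist, dev=dev):
                base = acc1 / np.linalg.norm(acc1) if np.linalg.norm(acc1) > 1e-6 else u
                out_dir = 0.6 * base + 0.4 * u
                out_dir /= np.linalg.norm(out_dir)
                og1 = acc1 + dist * out_dir
                hg1 = _tilted_hydrogen(og1, acc1, dev)
                # arm 2 parks radially beyond arm 1, out of bonding range of
                # every ligand polar atom
                og2 = og1 + 1.7 * out_dir
                hg2 = og2 + 1.0 * out_dir
                backbone = _place_template(
                    [("CA", "C", (1.45, 0.45, 0.0)), ("C", "C", (2.50, -0.55, 0.0))],
                    og1 + 0.3 * out_dir, out_dir,
                )
                return [
                    ("OG1", "O", og1), ("HG1", "H", hg1),
                    ("OG2", "O", og2), ("HG2", "H", hg2),
                ] + backbone

            place_or_raise(build_donor, f"donor at {dist} Å", "DNR", "donor")
        else:  # ligand-amino: ligand donates, protein provides an acceptor O
            n_pos = _LIG_COORD["N"]
            h_pos = _LIG_COORD["H1"]
            e = (h_pos - n_pos) / np.linalg.norm(h_pos - n_pos)

            def build_acceptor(u: np.ndarray, dist=dist, dev=dev):
                # rotate the tilt plane toward the candidate direction
                w = u - np.dot(u, e) * e
                if np.linalg.norm(w) < 1e-6:
                    w, _ = _orthonormal_frame(e)
                else:
                    w /= np.linalg.norm(w)

                def place(phi: float) -> np.ndarray:
                    return n_pos + dist * (np.cos(phi) * e + np.sin(phi) * w)

                def dev_of(phi: float) -> float:
                    a = place(phi)
                    v1 = n_pos - h_pos
                    v2 = a - h_pos
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    return (180.0 - angle) - dev

                phi = 0.0 if dev < 1e-9 else brentq(dev_of, 0.0, np.pi / 2,
                                                    xtol=1e-12)
                od1 = place(phi)
                out_dir = od1 - n_pos
                out_dir /= np.linalg.norm(out_dir)
                backbone = _place_template(
                    [("CA", "C", (1.45, 0.45, 0.0)), ("C", "C", (2.50, -0.55, 0.0))],
                    od1 + 0.3 * out_dir, out_dir,
                )
                return [("OD1", "O", od1)] + backbone

            place_or_raise(build_acceptor, f"acceptor at {dist} Å", "ACC",
                           "acceptor")

    lig_cb = _LIG_COORD["CB"]
    cb_out = lig_cb - np.mean(_LIG_HEAVY, axis=0)
    cb_out /= np.linalg.norm(cb_out)
    for dist in spec.hydrophobic_pairs:

        def build_hydrophobic(u: np.ndarray, dist=dist):
            out_dir = 0.7 * cb_out + 0.3 * u
            out_dir /= np.linalg.norm(out_dir)
            anchor = lig_cb + dist * out_dir
            return _place_template(_SHELL_TEMPLATE, anchor, out_dir)

        place_or_raise(build_hydrophobic, f"hydrophobic partner at {dist} Å",
                       "ALA", "hydrophobic")

    ligand_atoms = [(name, el, np.array(xyz)) for name, el, xyz in _LIGAND_ATOMS]
    return residues, ligand_atoms


def _render_model(
    residues: list[_BuiltResidue], ligand_atoms: list, ligand_name: str
) -> list[str]:
    lines = []
    serial = 1
    for res in residues:
        for name, element, xyz in res.atoms:
            lines.append(
                _pdb_atom_line(serial, name, res.resname, "A", res.resnum, xyz,
                               element, het=False)
            )
            serial += 1
    for name, element, xyz in ligand_atoms:
        lines.append(
            _pdb_atom_line(serial, name, ligand_name, "L", 900, xyz, element,
                           het=True)
        )
        serial += 1
    return lines


def generate_pocket_structure(spec: PocketSpec) -> str:
    """Build a single-model PDB text realising the planted pocket geometry.

    The emitted structure is re-parsed and re-measured before being
    returned: shell distances must match to 0.01 Å and each planted
    hydrogen bond must be recovered by the detection criterion it was
    built for.
    """
    residues, ligand_atoms = _build_pocket(spec)
    lines = _render_model(residues, ligand_atoms, spec.ligand_name)
    text = "\n".join(lines + ["END"]) + "\n"

    # self-check by re-measurement
    model = parse_structure(text)[0]
    ligand = find_ligand(model, resname=spec.ligand_name)
    dists = contact_residues(
        model, ligand, InteractionCriteria(contact_cutoff=1e6)
    )
    for res, target in zip(residues, spec.contact_distances):
        measured = dists[("A", res.resnum, res.resname)]
        if abs(measured - target) > 0.01:
            raise GenerationError(
                f"shell residue {res.resnum}: planted {target:.3f} Å, "
                f"measured {measured:.3f} Å"
            )
    wanted = [g for g in spec.hbond_geometries if g[0] < 3.0 and g[1] <= 20.0]
    if wanted:
        bonds = detect_hbonds(model, ligand, InteractionCriteria(), mode="md")
        if len(bonds) < len(wanted):
            raise GenerationError("planted hydrogen bonds not recovered")
    return text


def _residue_atom_indices(model: StructureModel) -> dict[int, "object"]:
    return {r.resnum: r for r in model.polymer_residues()}


def generate_trajectory(structure_pdb: str, spec: TrajectorySpec) -> str:
    """Emit a multi-model PDB ensemble with planted per-frame statistics.

    Contact-controlled residues are translated radially each frame: inside
    (3.6-4.6 Å) with the planted probability, outside (6.0-7.0 Å)
    otherwise.  Hydrogen-bond-controlled residues form
    floor(rate) + Bernoulli(rate - floor) bonds per frame using their
    hydroxyl arms (rates above 2 are not constructible and raise).
    Frames from ``release_frame`` onward shift the ligand 60 Å away.
    """
    base = parse_structure(structure_pdb)[0]
    by_num = {r.resnum: r for r in base.polymer_residues()}
    het = base.het_residues()
    if not het:
        raise ValueError("structure has no ligand")
    lig = het[0]
    lig_heavy = np.array([a.xyz for a in lig.atoms if not a.is_hydrogen])

    for resnum in list(spec.per_residue_contact_fraction) + list(
        spec.per_residue_hbond_rate
    ):
        if resnum not in by_num:
            raise ValueError(f"residue {resnum} not present in structure")
    for resnum, rate in spec.per_residue_hbond_rate.items():
        res = by_num[resnum]
        arms = [a for a in res.atoms if a.name in ("OG1", "OG2")]
        if rate > len(arms):
            raise ValueError(
                f"residue {resnum}: rate {rate} exceeds its {len(arms)} donor arms"
            )

    rng = np.random.default_rng(spec.seed)
    lig_names = {a.name: a.xyz for a in lig.atoms}

    # pre-solve the in-geometry position of each donor's second arm: 2.8 Å
    # from the second acceptor, perpendicular to arm 1 so it cannot bond
    # with the first acceptor as a side effect
    arm2_geometry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for resnum, rate in spec.per_residue_hbond_rate.items():
        res = by_num[resnum]
        og1, og2 = res.atom("OG1"), res.atom("OG2")
        if og1 is None or og2 is None or rate <= 1.0:
            continue
        acc1 = lig_names.get("O1", lig_names.get("OG"))
        acc2 = lig_names.get("O2", lig_names.get("OG"))
        arm1_dir = og1.xyz - acc1
        arm1_dir /= np.linalg.norm(arm1_dir)
        d2 = np.cross(arm1_dir, acc1 - acc2)
        norm = np.linalg.norm(d2)
        if norm < 1e-9:  # acceptors coincide: fall back to the arm-1 direction
            d2 = arm1_dir
        else:
            d2 /= norm
            if np.dot(d2, acc2 - lig_heavy.mean(axis=0)) < 0:
                d2 = -d2
        og2_in = acc2 + 2.8 * d2
        hg2_in = _tilted_hydrogen(og2_in, acc2, 5.0)
        arm2_geometry[resnum] = (og2_in, hg2_in)

    frames: list[str] = []
    for frame in range(spec.n_frames):
        released = spec.release_frame is not None and frame >= spec.release_frame
        lines: list[str] = [f"MODEL     {frame + 1:4d}"]
        serial = 1
        for res in base.polymer_residues():
            shift = np.zeros(3)
            coords = {a.name: a.xyz.copy() for a in res.atoms}
            if res.resnum in spec.per_residue_contact_fraction and not released:
                frac = spec.per_residue_contact_fraction[res.resnum]
                inside = rng.random() < frac
                target = (
                    rng.uniform(3.6, 4.6) if inside else rng.uniform(6.0, 7.0)
                )
                heavy = np.array([a.xyz for a in res.atoms if not a.is_hydrogen])
                from scipy.spatial.distance import cdist

                current = float(cdist(heavy, lig_heavy).min())
                centroid = heavy.mean(axis=0)
                u = centroid - lig_heavy.mean(axis=0)
                u /= np.linalg.norm(u)

                # translation along u changes the min distance only
                # approximately; solve the shift magnitude exactly
                def min_dist_at(t: float) -> float:
                    return float(cdist(heavy + t * u, lig_heavy).min())

                lo, hi = target - current - 3.0, target - current + 3.0
                if (min_dist_at(lo) - target) * (min_dist_at(hi) - target) > 0:
                    t_shift = target - current  # fall back to the linear guess
                else:
                    t_shift = float(
                        brentq(lambda t: min_dist_at(t) - target, lo, hi,
                               xtol=1e-9)
                    )
                shift = t_shift * u
            elif res.resnum in spec.per_residue_hbond_rate:
                rate = spec.per_residue_hbond_rate[res.resnum]
                k = int(rate) + (1 if rng.random() < rate - int(rate) else 0)
                if res.atom("OG1") is not None:
                    if k == 0:
                        og1 = coords["OG1"]
                        # push arm 1 out of bonding range
                        acc = lig_names.get("O1", lig_names.get("OG"))
                        direction = og1 - acc
                        direction /= np.linalg.norm(direction)
                        coords["OG1"] = og1 + 2.0 * direction
                        coords["HG1"] = coords["HG1"] + 2.0 * direction
                    if k >= 2 and res.resnum in arm2_geometry:
                        coords["OG2"], coords["HG2"] = arm2_geometry[res.resnum]
                else:  # acceptor-style residue: move the whole group
                    if k == 0:
                        od1 = coords.get("OD1")
                        direction = od1 - lig_names["N"]
                        direction /= np.linalg.norm(direction)
                        shift = 2.0 * direction
            for atom in res.atoms:
                lines.append(
                    _pdb_atom_line(
                        serial, atom.name, res.resname, res.chain_id, res.resnum,
                        coords[atom.name] + shift, atom.element, het=False,
                    )
                )
                serial += 1
        lig_shift = np.array([0.0, 0.0, 60.0]) if released else np.zeros(3)
        for atom in lig.atoms:
            lines.append(
                _pdb_atom_line(
                    serial, atom.name, lig.resname, lig.chain_id, lig.resnum,
                    atom.xyz + lig_shift, atom.element, het=True,
                )
            )
            serial += 1
        lines.append("ENDMDL")
        frames.append("\n".join(lines))
    return "\n".join(frames) + "\nEND\n"
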