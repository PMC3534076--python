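"""Synthetic structure generators with known ground truth.

Every generator is a pure function of its spec and seed, so fixtures are
reproducible and carry their own answer key:

* :func:`make_helix_bundle` — multi-helix Cα bundles with ideal α-helix
  geometry (1.5 Å rise, 100° twist, 2.3 Å radius per residue), optionally
  decorated with backbone and stub side-chain atoms.  A desk-scale stand-in
  for a transmembrane helix bundle.
* :func:`make_planted_complex` — a toy protein–ligand complex whose
  interactions (hydrogen bonds, salt bridges, π-stacks, contact patches)
  are planted with margins of at least 0.3 Å / 10° inside the detection
  thresholds, with everything unplanted kept well outside them.
* :func:`make_two_state_ensemble` — conformer ensembles split into two
  groups displaced oppositely along a normal mode, the planted partition
  for clustering tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import anm
from .fingerprint import ChecklistEntry, LigandFeature, LigandPose
from .structio import Structure

__all__ = [
    "BundleSpec",
    "PlacementError",
    "PlantedComplex",
    "make_helix_bundle",
    "make_planted_complex",
    "make_two_state_ensemble",
]


class PlacementError(Exception):
    """A planted complex cannot be constructed for the requested set."""


@dataclass(frozen=True)
class BundleSpec:
    """Helix-bundle recipe: geometry, decoration level, jitter, seed."""

    n_helices: int = 3
    n_residues: int = 20
    spacing: float = 10.0        # Å between adjacent helix axes
    all_atom: bool = False       # add N/C/O backbone + CB stub
    jitter: float = 0.0          # Å, Gaussian σ on every coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.n_residues < 1:
            raise ValueError("need at least 1 helix and 1 residue")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


# ideal α-helix Cα parameters
_HELIX_RISE = 1.5        # Å per residue
_HELIX_TWIST = 100.0     # ° per residue
_HELIX_RADIUS = 2.3      # Å

# backbone/stub offsets in the residue's local frame (CA at origin)
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.80, -0.50]),
    "C": np.array([1.20, 0.80, 0.50]),
    "O": np.array([2.05, 1.40, 1.10]),
}


def make_helix_bundle(spec: BundleSpec) -> Structure:
    """Build an idealized helix bundle.

    Helix axes run along z and sit on a circle sized so adjacent axes are
    ``spacing`` apart.  Chains are lettered per helix; residues are
    numbered continuously across the bundle.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_helices == 1:
        centers = np.zeros((1, 2))
    else:
        ring_r = spec.spacing / (2.0 * np.sin(np.pi / spec.n_helices))
        phis = 2 * np.pi * np.arange(spec.n_helices) / spec.n_helices
        centers = ring_r * np.stack([np.cos(phis), np.sin(phis)], axis=1)

    names, elems, res_ids, res_names, chains, xyz = [], [], [], [], [], []
    res_counter = 0
    for h in range(spec.n_helices):
        chain = chr(ord("A") + h)
        for r in range(spec.n_residues):
            res_counter += 1
            theta = np.radians(_HELIX_TWIST * r)
            ca = np.array([
                centers[h, 0] + _HELIX_RADIUS * np.cos(theta),
                centers[h, 1] + _HELIX_RADIUS * np.sin(theta),
                _HELIX_RISE * r,
            ])
            atoms = [("CA", "C", ca)]
            if spec.all_atom:
                rot = np.array([
                    [np.cos(theta), -np.sin(theta), 0.0],
                    [np.sin(theta), np.cos(theta), 0.0],
                    [0.0, 0.0, 1.0],
                ])
                for name, off in _BACKBONE_OFFSETS.items():
                    atoms.append((name, name[0], ca + rot @ off))
                outward = ca - np.array([centers[h, 0], centers[h, 1], ca[2]])
                outward /= np.linalg.norm(outward)
                atoms.append(("CB", "C", ca + 1.53 * outward))
            for name, elem, pos in atoms:
                names.append(name)
                elems.append(elem)
                res_ids.append(res_counter)
                res_names.append("ALA")
                chains.append(chain)
                xyz.append(pos)

    coords = np.asarray(xyz)
    if spec.jitter > 0:
        coords = coords + rng.normal(0.0, spec.jitter, coords.shape)
    return Structure(
        atom_name=names, element=elems, res_id=res_ids, res_name=res_names,
        chain_id=chains, coords=coords[None],
        provenance=f"synthetic helix bundle {spec}",
    )


# -- planted protein–ligand complexes ------------------------------------

# side-chain templates in a local frame: CA at origin, side chain along -y
_SIDECHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "ALA": [("CB", "C", (0.0, -1.53, 0.0))],
    "SER": [("CB", "C", (0.0, -1.53, 0.0)), ("OG", "O", (0.0, -2.90, 0.0))],
    "VAL": [("CB", "C", (0.0, -1.53, 0.0)), ("CG1", "C", (0.90, -2.40, 0.40)),
            ("CG2", "C", (-0.90, -2.40, 0.40))],
    "ASP": [("CB", "C", (0.0, -1.53, 0.0)), ("CG", "C", (0.0, -2.90, 0.0)),
            ("OD1", "O", (1.09, -3.55, 0.0)), ("OD2", "O", (-1.09, -3.55, 0.0))],
    "ASN": [("CB", "C", (0.0, -1.53, 0.0)), ("CG", "C", (0.0, -2.90, 0.0)),
            ("OD1", "O", (1.09, -3.55, 0.0)), ("ND2", "N", (-1.09, -3.55, 0.0))],
    "PHE": [("CB", "C", (0.0, -1.53, 0.0)), ("CG", "C", (0.0, -2.91, 0.0)),
            ("CD1", "C", (1.20, -3.60, 0.0)), ("CD2", "C", (-1.20, -3.60, 0.0)),
            ("CE1", "C", (1.20, -5.00, 0.0)), ("CE2", "C", (-1.20, -5.00, 0.0)),
            ("CZ", "C", (0.0, -5.69, 0.0))],
}
_TYPE_RESIDUE = {"hbond": "SER", "salt_bridge": "ASP",
                 "pi_stack": "PHE", "contact": "VAL"}
_MAX_PLANTED = 6  # angular capacity of the radial layout


@dataclass
class PlantedComplex:
    """A constructed complex plus its answer key."""

    protein: Structure
    pose: LigandPose
    planted: list[tuple[str, int]]          # (interaction type, residue number)
    checklist: list[ChecklistEntry]         # one entry per planted interaction


def _residue_atoms(res_name: str, origin: np.ndarray, u: np.ndarray
                   ) -> list[tuple[str, str, np.ndarray]]:
    """Instantiate a residue template at ``origin`` (CA) with its side chain
    pointing along ``-u`` (toward the complex center)."""
    # local frame: y_local -> u, z_local -> world z (or x if u ~ z)
    y = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(y @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    x = np.cross(y, ref)
    x /= np.linalg.norm(x)
    z = np.cross(x, y)
    M = np.stack([x, y, z], axis=1)  # local -> world
    atoms = [("CA", "C", origin)]
    for name, off in _BACKBONE_OFFSETS.items():
        atoms.append((name, name[0], origin + M @ off))
    for name, elem, off in _SIDECHAINS[res_name]:
        atoms.append((name, elem, origin + M @ np.asarray(off)))
    return atoms


def make_planted_complex(interactions: list[tuple[str, int]], seed: int = 0,
                         jitter: float = 0.04) -> PlantedComplex:
    """Build a toy complex that satisfies exactly the requested interactions.

    ``interactions`` is a list of (type, residue number) with type in
    {hbond, salt_bridge, pi_stack, contact}.  Residues are laid out
    radially around the ligand, one direction per interaction, so every
    planted geometry is at least 0.3 Å / 10° inside its threshold while
    all unplanted residue–feature pairs stay at least 0.3 Å outside.
    A small seeded jitter and a random global rotation are applied
    (jointly, so the planted geometry is preserved to within the margins).
    """
    for itype, _res in interactions:
        if itype not in _TYPE_RESIDUE:
            raise ValueError(f"unknown interaction type {itype!r}")
    res_nums = [r for _t, r in interactions]
    if len(set(res_nums)) != len(res_nums):
        raise PlacementError("duplicate target residue numbers")
    if len(interactions) > _MAX_PLANTED:
        raise PlacementError(
            f"cannot place more than {_MAX_PLANTED} interactions "
            "with guaranteed margins")

    rng = np.random.default_rng(seed)
    R_CA = 10.0
    n_dirs = max(len(interactions), 1)
    angles = 2 * np.pi * np.arange(n_dirs) / n_dirs

    prot_atoms: list[tuple[str, str, int, str, str, np.ndarray]] = []
    lig_names: list[str] = []
    lig_elems: list[str] = []
    lig_xyz: list[np.ndarray] = []
    features: list[LigandFeature] = []
    checklist: list[ChecklistEntry] = []

    def add_lig(name: str, elem: str, pos: np.ndarray) -> int:
        lig_names.append(name)
        lig_elems.append(elem)
        lig_xyz.append(np.asarray(pos, float))
        return len(lig_xyz) - 1

    # inert ligand core: every feature kind is represented, far from protein
    c1 = add_lig("C1", "C", (0.0, 0.0, 0.0))
    c2 = add_lig("C2", "C", (1.5, 0.0, 0.0))
    c3 = add_lig("C3", "C", (0.0, 1.5, 0.0))
    o4 = add_lig("O4", "O", (-1.2, 0.0, 0.0))
    h4 = add_lig("H4", "H", (-2.2, 0.0, 0.0))
    n5 = add_lig("N5", "N", (0.0, -1.4, 0.0))
    ring_core = []
    for j in range(6):
        a = np.radians(60.0 * j)
        ring_core.append(add_lig(f"C{6 + j}", "C",
                                 (1.39 * np.cos(a), 1.39 * np.sin(a), 2.5)))
    features += [
        LigandFeature("core_OH", "donor", (o4,), hydrogen=h4),
        LigandFeature("core_amine", "cation", (n5,)),
        LigandFeature("core_ring", "ring", tuple(ring_core)),
        LigandFeature("core", "contact", (c1, c2, c3)),
    ]

    for i, (itype, res_id) in enumerate(interactions):
        ang = angles[i]
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        res_name = _TYPE_RESIDUE[itype]
        atoms = _residue_atoms(res_name, R_CA * u, u)
        for name, elem, pos in atoms:
            prot_atoms.append((name, elem, res_id, res_name, "A", pos))
        by_name = {name: pos for name, _e, pos in atoms}
        cls = f"probe{i}"

        if itype == "hbond":
            og = by_name["OG"]
            dxyz = og - 2.8 * u              # donor heavy atom, 2.8 Å from OG
            hxyz = dxyz + 1.0 * u            # H on the D→A line: angle 180°
            d = add_lig(f"OD{i}", "O", dxyz)
            h = add_lig(f"HD{i}", "H", hxyz)
            features.append(LigandFeature(cls, "donor", (d,), hydrogen=h))
        elif itype == "salt_bridge":
            mid = 0.5 * (by_name["OD1"] + by_name["OD2"])
            nxyz = mid - 3.2 * u             # 3.38 Å to each carboxylate O
            n = add_lig(f"NS{i}", "N", nxyz)
            features.append(LigandFeature(cls, "cation", (n,)))
        elif itype == "pi_stack":
            ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
            rxyz = np.array([by_name[n] for n in ring_names])
            centroid = rxyz.mean(axis=0)
            normal = np.linalg.svd(rxyz - centroid)[2][-1]
            members = []
            basis_a = rxyz[0] - centroid
            basis_a /= np.linalg.norm(basis_a)
            basis_b = np.cross(normal, basis_a)
            for j in range(6):
                a = np.radians(60.0 * j)
                pos = (centroid + 3.8 * normal
                       + 1.39 * (np.cos(a) * basis_a + np.sin(a) * basis_b))
                members.append(add_lig(f"CR{i}_{j}", "C", pos))
            features.append(LigandFeature(cls, "ring", tuple(members)))
        elif itype == "contact":
            # one ligand atom 2.5 Å inward of each of 4 of the 7 residue atoms
            targets = ["CA", "CB", "CG1", "CG2"]
            members = []
            for j, tname in enumerate(targets):
                members.append(add_lig(f"CT{i}_{j}", "C",
                                       by_name[tname] - 2.5 * u))
            features.append(LigandFeature(cls, "contact", tuple(members)))
        checklist.append(ChecklistEntry(res_id, res_name, itype, cls))

    # inert scaffold residues, far from everything
    scaffold_base = (max(res_nums) if res_nums else 0) + 100
    for j in range(3):
        ang = 2 * np.pi * (j + 0.5) / 3
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        for name, elem, pos in _residue_atoms("ALA", 18.0 * u + [0, 0, 6.0], u):
            prot_atoms.append((name, elem, scaffold_base + j, "ALA", "A", pos))

    lig_coords = np.asarray(lig_xyz)
    prot_coords = np.asarray([p for *_x, p in prot_atoms])

    # seeded jitter (ligand only, well inside margins) + joint random rotation
    lig_coords = lig_coords + rng.uniform(-jitter, jitter, lig_coords.shape)
    from scipy.spatial.transform import Rotation
    Rm = Rotation.random(random_state=np.random.RandomState(seed % (2**32))).as_matrix()
    lig_coords = lig_coords @ Rm.T
    prot_coords = prot_coords @ Rm.T

    protein = Structure(
        atom_name=[a[0] for a in prot_atoms],
        element=[a[1] for a in prot_atoms],
        res_id=[a[2] for a in prot_atoms],
        res_name=[a[3] for a in prot_atoms],
        chain_id=[a[4] for a in prot_atoms],
        coords=prot_coords[None],
        provenance=f"synthetic planted complex seed={seed}",
    )
    pose = LigandPose(atom_name=lig_names, element=lig_elems,
                      coords=lig_coords, features=features)
    return PlantedComplex(protein=protein, pose=pose,
                          planted=[(t, r) for t, r in interactions],
                          checklist=checklist)


def make_two_state_ensemble(n_a: int, n_b: int, displacement: float = 3.0,
                            mode_index: int = 1, noise: float = 0.1,
                            seed: int = 0,
                            spec: BundleSpec | None = None,
                            ) -> tuple[list[Structure], list[int]]:
    """Planted two-cluster ensemble: bundle ± a mode-shaped displacement.

    Group A conformers sit at +displacement (Å RMSD) along the chosen
    normal mode of the base bundle, group B at −displacement, each with
    per-atom Gaussian noise of the given σ.  Returns the conformers and
    their true labels (0 for group A, 1 for group B).
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one conformer")
    if spec is None:
        spec = BundleSpec()
    base = make_helix_bundle(spec)
    net = anm.build_network(base)
    modes = anm.compute_modes(net)
    disp = displacement * np.sqrt(modes.n_nodes) * modes.mode_displacements(mode_index)

    rng = np.random.default_rng(seed)
    conformers, labels = [], []
    ca = base.calpha_indices()
    for label, n, sign in [(0, n_a, +1.0), (1, n_b, -1.0)]:
        for i in range(n):
            coords = base.coords[0].copy()
            coords[ca] += sign * disp
            if noise > 0:
                coords = coords + rng.normal(0.0, noise, coords.shape)
            conformers.append(base.with_coords(
                coords, provenance=f"two-state {'AB'[label]}{i}"))
            labels.append(label)
    return conformers, labels
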