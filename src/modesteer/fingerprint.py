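"""Geometric protein–ligand interaction detection and checklist triage.

Interactions are detected purely from geometry against explicit feature
annotations on the ligand; no chemical perception from connectivity is
attempted.  The protein side is typed from residue and atom names via a
small built-in chemistry table (carboxylate oxygens, cationic nitrogens,
aromatic ring atoms, polar donors/acceptors).

Detection criteria (all thresholds configurable in one block):

* hydrogen bond — donor–acceptor heavy-atom distance ≤ 3.5 Å; when the
  donor hydrogen is annotated, additionally D–H…A angle ≥ 120°
* salt bridge — cationic N to carboxylate O ≤ 4.0 Å
* π-stack — ring-centroid distance ≤ 5.5 Å with interplanar angle ≤ 30°
  (parallel) or ≥ 60° (T-shaped)
* contact — residue with at least half its atoms within the cutoff
  (default 3.5 Å) of any ligand atom

A checklist pairs binding-site residues with the ligand feature class
expected to engage them; a fingerprint records, per entry, whether a
matching interaction was found and its measured geometry.  Pose triage
ranks externally scored poses by score and filters them by fingerprint
fraction — the score is consumed as supplied, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structio import Structure, superpose

__all__ = [
    "LigandFeature",
    "LigandPose",
    "InteractionThresholds",
    "Interaction",
    "ChecklistEntry",
    "InteractionFingerprint",
    "UntypedLigandError",
    "detect_contacts",
    "detect_interactions",
    "evaluate_checklist",
    "triage_poses",
    "place_polar_hydrogen",
    "B2AR_AGONIST_CHECKLIST",
]


class UntypedLigandError(Exception):
    """A requested interaction type has no matching ligand feature annotation."""


@dataclass(frozen=True)
class LigandFeature:
    """Typed ligand feature: a named group of atoms with a chemical role.

    ``kind`` is one of donor | acceptor | cation | ring | contact.
    ``hydrogen`` optionally names the explicit H atom of a donor.
    """

    feature_class: str
    kind: str
    atoms: tuple[int, ...]
    hydrogen: int | None = None

    KINDS = ("donor", "acceptor", "cation", "ring", "contact")


@dataclass
class LigandPose:
    """Ligand atoms with feature annotations and an optional external score."""

    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    features: list[LigandFeature] = field(default_factory=list)
    score: float | None = None
    name: str = "LIG"

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.coords.shape[0]
        for f in self.features:
            if f.kind not in LigandFeature.KINDS:
                raise ValueError(f"unknown feature kind {f.kind!r}")
            if any(a < 0 or a >= n for a in f.atoms):
                raise ValueError(f"feature {f.feature_class}: atom index out of range")
            if f.hydrogen is not None and not 0 <= f.hydrogen < n:
                raise ValueError(f"feature {f.feature_class}: hydrogen index out of range")
            if f.kind == "ring":
                if len(f.atoms) < 5:
                    raise ValueError("ring feature needs >= 5 member atoms")
                pts = self.coords[list(f.atoms)]
                dev = _plane_deviation(pts)
                if dev > 0.3:
                    raise ValueError(
                        f"ring feature {f.feature_class} not coplanar (max dev {dev:.2f} A)")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        return replace(self, coords=self.coords @ np.asarray(rotation).T + translation)


@dataclass(frozen=True)
class InteractionThresholds:
    """Geometric cutoffs; defaults are common structural-biology practice."""

    hbond_dist: float = 3.5          # Å, donor–acceptor heavy atoms
    hbond_angle: float = 120.0       # °, D–H…A when H present
    salt_bridge_dist: float = 4.0    # Å, cationic N – carboxylate O
    stack_dist: float = 5.5          # Å, ring centroid – centroid
    stack_angle_parallel: float = 30.0   # ° interplanar, parallel stack
    stack_angle_tshaped: float = 60.0    # ° interplanar, T-shaped stack
    contact_dist: float = 3.5        # Å, contact shell


DEFAULT_THRESHOLDS = InteractionThresholds()


@dataclass(frozen=True)
class Interaction:
    """One detected protein–ligand interaction with its measured geometry."""

    itype: str                   # hbond | salt_bridge | pi_stack | contact
    chain: str
    res_id: int
    res_name: str
    feature_class: str
    distance: float              # Å
    angle: float | None = None   # ° (D–H…A or interplanar)
    subtype: str | None = None   # parallel | tshaped for pi_stack


@dataclass(frozen=True)
class ChecklistEntry:
    """Expected interaction: residue + type + ligand feature class."""

    res_id: int
    res_name: str | None
    itype: str
    feature_class: str
    note: str = ""


@dataclass
class InteractionFingerprint:
    """Per-checklist-entry satisfaction with measured geometry."""

    entries: list[ChecklistEntry]
    satisfied: list[bool]
    matches: list[Interaction | None]

    @property
    def fraction(self) -> float:
        return float(np.mean(self.satisfied)) if self.satisfied else 0.0

    def satisfied_entries(self) -> list[ChecklistEntry]:
        return [e for e, s in zip(self.entries, self.satisfied) if s]

    def violated_entries(self) -> list[ChecklistEntry]:
        return [e for e, s in zip(self.entries, self.satisfied) if not s]


# -- protein-side chemistry table ---------------------------------------

_CARBOXYLATE_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_CATION_N = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",), "TRP": ("NE1",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
}
_ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",), "HIS": ("ND1", "NE2"),
}
_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_BACKBONE_DONOR = "N"
_BACKBONE_ACCEPTOR = "O"


def _plane_deviation(points: np.ndarray) -> float:
    """Max distance of points from their best-fit plane."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    normal = vt[-1]
    return float(np.max(np.abs((points - c) @ normal)))


def _plane_normal(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    return vt[-1]


def place_polar_hydrogen(donor: np.ndarray, antecedent: np.ndarray,
                         length: float = 1.0) -> np.ndarray:
    """Idealized polar H: extend the antecedent→donor bond by ``length`` Å.

    Minimal helper for donors lacking explicit hydrogens (e.g. measuring a
    lysine H…O salt-bridge distance); heavy-atom criteria are the default
    and do not require it.
    """
    d = np.asarray(donor, float) - np.asarray(antecedent, float)
    return np.asarray(donor, float) + length * d / np.linalg.norm(d)


# -- detectors -----------------------------------------------------------


def detect_contacts(protein: Structure, pose: LigandPose,
                    cutoff: float = 3.5) -> list[tuple[str, int, str]]:
    """Residues with at least half their atoms within ``cutoff`` of the ligand.

    Returns (chain, res_id, res_name) tuples sorted by residue number.
    """
    lig = pose.coords
    out = []
    for (chain, res_id, _ins), idx in protein.residue_atom_indices().items():
        xyz = protein.coords[0][idx]
        dmin = np.min(np.linalg.norm(xyz[:, None, :] - lig[None, :, :], axis=-1),
                      axis=1)
        if np.mean(dmin <= cutoff) >= 0.5:
            out.append((chain, int(res_id), str(protein.res_name[idx[0]])))
    return sorted(out, key=lambda t: t[1])


def _residue_atom_xyz(protein: Structure, idx: np.ndarray,
                      names: tuple[str, ...]) -> list[tuple[str, np.ndarray]]:
    found = []
    for i in idx:
        if protein.atom_name[i] in names:
            found.append((str(protein.atom_name[i]), protein.coords[0][i]))
    return found


def detect_interactions(protein: Structure, pose: LigandPose,
                        thresholds: InteractionThresholds = DEFAULT_THRESHOLDS,
                        types: tuple[str, ...] = ("hbond", "salt_bridge",
                                                  "pi_stack", "contact"),
                        ) -> list[Interaction]:
    """Detect all typed interactions between a protein model and a ligand pose.

    Raises :class:`UntypedLigandError` if a requested type has no matching
    ligand feature annotation at all — a silent empty result would be
    indistinguishable from "no interaction".
    """
    th = thresholds
    kinds_present = {f.kind for f in pose.features}
    needed = {"hbond": {"donor", "acceptor"}, "salt_bridge": {"cation"},
              "pi_stack": {"ring"}, "contact": {"contact"}}
    for t in types:
        if t not in needed:
            raise ValueError(f"unknown interaction type {t!r}")
        if not (needed[t] & kinds_present):
            raise UntypedLigandError(
                f"no ligand feature of kind {sorted(needed[t])} for type {t!r}")

    found: list[Interaction] = []
    res_groups = protein.residue_atom_indices()

    for (chain, res_id, _ins), idx in res_groups.items():
        res_name = str(protein.res_name[idx[0]])
        for feat in pose.features:
            fxyz = pose.coords[list(feat.atoms)]

            if "hbond" in types and feat.kind in ("donor", "acceptor"):
                if feat.kind == "donor":
                    partner_names = _ACCEPTORS.get(res_name, ()) + (_BACKBONE_ACCEPTOR,)
                else:
                    partner_names = _DONORS.get(res_name, ()) + (_BACKBONE_DONOR,)
                for _an, axyz in _residue_atom_xyz(protein, idx, partner_names):
                    for fa in feat.atoms:
                        dxyz = pose.coords[fa]
                        dist = float(np.linalg.norm(dxyz - axyz))
                        if dist > th.hbond_dist:
                            continue
                        angle = None
                        if feat.kind == "donor" and feat.hydrogen is not None:
                            hxyz = pose.coords[feat.hydrogen]
                            angle = _angle_deg(dxyz, hxyz, axyz)
                            if angle < th.hbond_angle:
                                continue
                        found.append(Interaction("hbond", chain, int(res_id),
                                                 res_name, feat.feature_class,
                                                 dist, angle))

            if "salt_bridge" in types and feat.kind == "cation":
                onames = _CARBOXYLATE_O.get(res_name, ())
                for _an, oxyz in _residue_atom_xyz(protein, idx, onames):
                    for fa in feat.atoms:
                        dist = float(np.linalg.norm(pose.coords[fa] - oxyz))
                        if dist <= th.salt_bridge_dist:
                            found.append(Interaction("salt_bridge", chain,
                                                     int(res_id), res_name,
                                                     feat.feature_class, dist))

            if "pi_stack" in types and feat.kind == "ring":
                rnames = _RINGS.get(res_name, ())
                ratoms = _residue_atom_xyz(protein, idx, rnames)
                if rnames and len(ratoms) >= len(rnames):
                    rxyz = np.array([x for _n, x in ratoms])
                    d = float(np.linalg.norm(rxyz.mean(0) - fxyz.mean(0)))
                    if d <= th.stack_dist:
                        n1 = _plane_normal(rxyz)
                        n2 = _plane_normal(fxyz)
                        ang = np.degrees(np.arccos(
                            np.clip(abs(float(n1 @ n2)), 0.0, 1.0)))
                        subtype = None
                        if ang <= th.stack_angle_parallel:
                            subtype = "parallel"
                        elif ang >= th.stack_angle_tshaped:
                            subtype = "tshaped"
                        if subtype:
                            found.append(Interaction("pi_stack", chain,
                                                     int(res_id), res_name,
                                                     feat.feature_class, d,
                                                     float(ang), subtype))

            if "contact" in types and feat.kind == "contact":
                xyz = protein.coords[0][idx]
                dmin = np.min(np.linalg.norm(
                    xyz[:, None, :] - fxyz[None, :, :], axis=-1), axis=1)
                if np.mean(dmin <= th.contact_dist) >= 0.5:
                    found.append(Interaction("contact", chain, int(res_id),
                                             res_name, feat.feature_class,
                                             float(dmin.min())))
    return found


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def evaluate_checklist(protein: Structure, pose: LigandPose,
                       checklist: list[ChecklistEntry],
                       thresholds: InteractionThresholds = DEFAULT_THRESHOLDS,
                       ) -> InteractionFingerprint:
    """Evaluate a pose against an interaction checklist.

    An entry is satisfied iff detection yields a matching
    (residue, type, feature class) triple.  Unknown checklist residues are
    an error rather than a silent miss.
    """
    known = {int(r) for r in protein.res_id}
    for entry in checklist:
        if entry.res_id not in known:
            raise KeyError(f"checklist residue {entry.res_id} not in protein")
    types = tuple(dict.fromkeys(e.itype for e in checklist))
    hits = detect_interactions(protein, pose, thresholds, types=types)
    satisfied, matches = [], []
    for entry in checklist:
        match = next(
            (h for h in hits
             if h.res_id == entry.res_id and h.itype == entry.itype
             and h.feature_class == entry.feature_class
             and (entry.res_name is None or h.res_name == entry.res_name)),
            None)
        satisfied.append(match is not None)
        matches.append(match)
    return InteractionFingerprint(list(checklist), satisfied, matches)


@dataclass(frozen=True)
class TriageRecord:
    key: str
    score: float
    fraction: float
    fingerprint: InteractionFingerprint


@dataclass
class TriageReport:
    accepted: list[TriageRecord]
    rejected: list[TriageRecord]


def triage_poses(complexes: list[tuple[str, Structure, LigandPose]],
                 checklist: list[ChecklistEntry],
                 min_fraction: float = 0.5,
                 thresholds: InteractionThresholds = DEFAULT_THRESHOLDS,
                 ) -> TriageReport:
    """Rank scored conformer–pose complexes by the two-criteria rule.

    Primary sort is the external score (lower = better, as supplied);
    complexes whose checklist fraction falls below ``min_fraction`` are
    rejected but reported, so a score-best-but-rejected pose stays
    visible.  Ties break by higher fraction, then input order.
    """
    records = []
    for order, (key, protein, pose) in enumerate(complexes):
        if pose.score is None:
            raise ValueError(f"pose {key!r} carries no external score")
        fp = evaluate_checklist(protein, pose, checklist, thresholds)
        records.append((order, TriageRecord(key, float(pose.score),
                                            fp.fraction, fp)))
    records.sort(key=lambda r: (r[1].score, -r[1].fraction, r[0]))
    accepted = [r for _o, r in records if r.fraction >= min_fraction]
    rejected = [r for _o, r in records if r.fraction < min_fraction]
    return TriageReport(accepted=accepted, rejected=rejected)


# -- serialization -------------------------------------------------------


def checklist_to_json(entries: list[ChecklistEntry]) -> list[dict]:
    return [{"res_id": e.res_id, "res_name": e.res_name, "type": e.itype,
             "feature_class": e.feature_class, "note": e.note}
            for e in entries]


def checklist_from_json(data: list[dict]) -> list[ChecklistEntry]:
    return [ChecklistEntry(int(d["res_id"]), d.get("res_name"),
                           d["type"], d["feature_class"], d.get("note", ""))
            for d in data]


def pose_from_json(data: dict) -> LigandPose:
    """Build a pose from the feature-annotation JSON layout.

    Layout: ``{"atoms": [{"name", "element", "xyz"}], "features":
    [{"class", "kind", "atoms", "hydrogen"?}], "score"?, "name"?}``.
    """
    atoms = data["atoms"]
    return LigandPose(
        atom_name=[a["name"] for a in atoms],
        element=[a["element"] for a in atoms],
        coords=np.array([a["xyz"] for a in atoms], dtype=float),
        features=[LigandFeature(f["class"], f["kind"], tuple(f["atoms"]),
                                f.get("hydrogen"))
                  for f in data.get("features", [])],
        score=data.get("score"),
        name=data.get("name", "LIG"),
    )


def pose_to_json(pose: LigandPose) -> dict:
    return {
        "name": pose.name,
        "score": pose.score,
        "atoms": [{"name": str(n), "element": str(e), "xyz": list(map(float, x))}
                  for n, e, x in zip(pose.atom_name, pose.element, pose.coords)],
        "features": [{"class": f.feature_class, "kind": f.kind,
                      "atoms": list(f.atoms), "hydrogen": f.hydrogen}
                     for f in pose.features],
    }


#: Experimentally supported β2AR agonist-binding checklist.  Residue
#: numbers follow β2AR author numbering.  The published source table lists
#: "Try316", an evident typo for Tyr316, which is what the preset uses.
B2AR_AGONIST_CHECKLIST: list[ChecklistEntry] = [
    ChecklistEntry(113, "ASP", "hbond", "beta_OH", "H3; amine/β-OH anchor"),
    ChecklistEntry(113, "ASP", "salt_bridge", "protonated_amine", "H3"),
    ChecklistEntry(114, "VAL", "contact", "aromatic_ring", "H3"),
    ChecklistEntry(203, "SER", "hbond", "head_group_OH", "H5"),
    ChecklistEntry(204, "SER", "hbond", "head_group_OH", "H5"),
    ChecklistEntry(207, "SER", "hbond", "head_group_OH", "H5"),
    ChecklistEntry(211, "PRO", "contact", "head_group", "H5"),
    ChecklistEntry(282, "PHE", "contact", "head_group", "H6"),
    ChecklistEntry(286, "TRP", "contact", "head_group", "H6"),
    ChecklistEntry(289, "PHE", "pi_stack", "aromatic_ring", "H6"),
    ChecklistEntry(293, "ASN", "hbond", "protonated_amine", "H6"),
    ChecklistEntry(297, "ASN", "hbond", "head_group", "H6"),
    ChecklistEntry(308, "TYR", "hbond", "ethanolamine_tail", "H7"),
    ChecklistEntry(312, "ASN", "hbond", "ethanolamine_tail", "H7"),
    ChecklistEntry(316, "TYR", "hbond", "ethanolamine_tail", "H7"),
]
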