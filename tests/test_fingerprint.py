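"""Interaction detection, checklist evaluation, pose triage."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from modesteer import fingerprint as fp, synthgen
from modesteer.fingerprint import (
    ChecklistEntry,
    InteractionThresholds,
    LigandFeature,
    LigandPose,
    UntypedLigandError,
)
from modesteer.structio import Structure


def simple_protein(res_entries):
    """res_entries: list of (res_id, res_name, [(atom, element, xyz)])."""
    names, elems, rids, rnames, chains, xyz = [], [], [], [], [], []
    for rid, rname, atoms in res_entries:
        for a, e, p in atoms:
            names.append(a)
            elems.append(e)
            rids.append(rid)
            rnames.append(rname)
            chains.append("A")
            xyz.append(p)
    return Structure(atom_name=names, element=elems, res_id=rids,
                     res_name=rnames, chain_id=chains,
                     coords=np.array(xyz)[None])


class TestDetectContacts:
    def test_whole_residue_within_cutoff(self):
        prot = simple_protein([(1, "ALA", [("CA", "C", (2.0, 0, 0)),
                                           ("CB", "C", (2.0, 1, 0))])])
        pose = LigandPose(["C1"], ["C"], np.zeros((1, 3)))
        assert fp.detect_contacts(prot, pose, cutoff=3.5) == [(("A"), 1, "ALA")]

    def test_majority_rule_excludes_minority(self):
        atoms = [("CA", "C", (2.0, 0, 0)), ("CB", "C", (3.0, 0, 0)),
                 ("CG", "C", (9.0, 0, 0)), ("CD", "C", (9.0, 1, 0)),
                 ("CE", "C", (9.0, 2, 0))]
        prot = simple_protein([(1, "LYS", atoms)])
        pose = LigandPose(["C1"], ["C"], np.zeros((1, 3)))
        # 2 of 5 atoms within 3.5 A -> below majority
        assert fp.detect_contacts(prot, pose, cutoff=3.5) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_atom_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        entries = []
        for rid in range(1, 6):
            atoms = [(f"C{j}", "C", rng.normal(0, 6, 3)) for j in range(4)]
            entries.append((rid, "ALA", atoms))
        prot = simple_protein(entries)
        lig_xyz = rng.normal(0, 4, (5, 3))
        pose = LigandPose([f"L{j}" for j in range(5)], ["C"] * 5, lig_xyz)
        got = {r for _c, r, _n in fp.detect_contacts(prot, pose, cutoff=4.0)}
        want = set()
        for rid, _rn, atoms in entries:
            within = sum(
                1 for _a, _e, p in atoms
                if min(np.linalg.norm(np.array(p) - l) for l in lig_xyz) <= 4.0)
            if within / len(atoms) >= 0.5:
                want.add(rid)
        assert got == want


def ser_residue(rid=203, og=(0.0, 0.0, 0.0)):
    og = np.asarray(og, float)
    return (rid, "SER", [("CA", "C", og + [0, 3.0, 0]),
                         ("CB", "C", og + [0, 1.5, 0]),
                         ("OG", "O", tuple(og))])


def asp_residue(rid=113, od1=(0.0, 0.0, 0.0)):
    od1 = np.asarray(od1, float)
    return (rid, "ASP", [("CA", "C", od1 + [0, 4.0, 0]),
                         ("CB", "C", od1 + [0, 2.8, 0]),
                         ("CG", "C", od1 + [0.9, 1.0, 0]),
                         ("OD1", "O", tuple(od1)),
                         ("OD2", "O", od1 + [2.0, 1.4, 0])])


def phe_residue(rid=289, center=(0.0, 0.0, 0.0), normal_axis="z"):
    center = np.asarray(center, float)
    ring = []
    for j, nm in enumerate(["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]):
        a = np.radians(60.0 * j)
        if normal_axis == "z":
            p = center + [1.39 * np.cos(a), 1.39 * np.sin(a), 0.0]
        else:
            p = center + [0.0, 1.39 * np.cos(a), 1.39 * np.sin(a)]
        ring.append((nm, "C", tuple(p)))
    return (rid, "PHE", [("CA", "C", tuple(center + [0, 4.0, 0])),
                         ("CB", "C", tuple(center + [0, 2.5, 0]))] + ring)


def hexagon(center, radius=1.39, tilt_deg=0.0):
    pts = []
    R = Rotation.from_euler("x", tilt_deg, degrees=True).as_matrix()
    for j in range(6):
        a = np.radians(60.0 * j)
        local = np.array([radius * np.cos(a), radius * np.sin(a), 0.0])
        pts.append(np.asarray(center) + R @ local)
    return np.array(pts)


class TestDetectInteractions:
    def test_planted_hbond_inside_thresholds(self):
        prot = simple_protein([ser_residue()])
        donor = np.array([0.0, -2.8, 0.0])
        hyd = np.array([0.0, -1.8, 0.0])  # on the D->A line: angle 180
        pose = LigandPose(["O1", "H1"], ["O", "H"],
                          np.array([donor, hyd]),
                          [LigandFeature("oh", "donor", (0,), hydrogen=1)])
        hits = fp.detect_interactions(prot, pose, types=("hbond",))
        assert len(hits) == 1
        assert hits[0].itype == "hbond" and hits[0].res_id == 203
        assert hits[0].distance == pytest.approx(2.8)
        assert hits[0].angle == pytest.approx(180.0)

    def test_hbond_angle_rejection(self):
        prot = simple_protein([ser_residue()])
        donor = np.array([0.0, -2.8, 0.0])
        hyd = donor + [0.0, -1.0, 0.0]  # points away: angle 0
        pose = LigandPose(["O1", "H1"], ["O", "H"], np.array([donor, hyd]),
                          [LigandFeature("oh", "donor", (0,), hydrogen=1)])
        assert fp.detect_interactions(prot, pose, types=("hbond",)) == []

    def test_salt_bridge_distance_cut(self):
        prot = simple_protein([asp_residue()])
        near = LigandPose(["N1"], ["N"], np.array([[0.0, -3.5, 0.0]]),
                          [LigandFeature("amine", "cation", (0,))])
        far = LigandPose(["N1"], ["N"], np.array([[0.0, -4.5, 0.0]]),
                         [LigandFeature("amine", "cation", (0,))])
        assert len(fp.detect_interactions(prot, near, types=("salt_bridge",))) == 1
        assert fp.detect_interactions(prot, far, types=("salt_bridge",)) == []

    def test_parallel_stack_detected_tilted_rejected(self):
        """Two parallel rings at 3.8 Å stack; a 45° tilt lands in the
        excluded 30–60° window (checked against a plane-fit oracle)."""
        prot = simple_protein([phe_residue()])
        flat = hexagon([0.0, 0.0, 3.8], tilt_deg=0.0)
        tilted = hexagon([0.0, 0.0, 3.8], tilt_deg=45.0)
        for pts, expected in [(flat, 1), (tilted, 0)]:
            pose = LigandPose([f"C{j}" for j in range(6)], ["C"] * 6, pts,
                              [LigandFeature("ring", "ring", tuple(range(6)))])
            hits = fp.detect_interactions(prot, pose, types=("pi_stack",))
            assert len(hits) == expected
            if hits:
                assert hits[0].subtype == "parallel"
                # independent plane-fit oracle for the interplanar angle
                c = pts.mean(0)
                n2 = np.linalg.svd(pts - c)[2][-1]
                assert abs(abs(n2[2]) - 1) < 1e-9
                assert hits[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_tshaped_stack_detected(self):
        prot = simple_protein([phe_residue()])
        perp = hexagon([0.0, 0.0, 4.5], tilt_deg=90.0)
        pose = LigandPose([f"C{j}" for j in range(6)], ["C"] * 6, perp,
                          [LigandFeature("ring", "ring", tuple(range(6)))])
        hits = fp.detect_interactions(prot, pose, types=("pi_stack",))
        assert len(hits) == 1 and hits[0].subtype == "tshaped"

    def test_untyped_ligand_error(self):
        prot = simple_protein([ser_residue()])
        pose = LigandPose(["C1"], ["C"], np.zeros((1, 3)))
        with pytest.raises(UntypedLigandError):
            fp.detect_interactions(prot, pose, types=("hbond",))

    def test_rigid_motion_invariance(self):
        pc = synthgen.make_planted_complex(
            [("hbond", 203), ("salt_bridge", 113), ("pi_stack", 289)], seed=0)
        base = fp.detect_interactions(pc.protein, pc.pose)
        for seed in range(3):
            R = Rotation.random(random_state=np.random.RandomState(seed)
                                ).as_matrix()
            t = np.array([7.0, -3.0, 11.0])
            prot2 = pc.protein.with_coords(pc.protein.coords @ R.T + t)
            pose2 = pc.pose.transformed(R, t)
            moved = fp.detect_interactions(prot2, pose2)
            assert {(h.itype, h.res_id) for h in moved} == \
                {(h.itype, h.res_id) for h in base}
            for a, b in zip(sorted(base, key=lambda h: (h.itype, h.res_id)),
                            sorted(moved, key=lambda h: (h.itype, h.res_id))):
                assert b.distance == pytest.approx(a.distance, abs=1e-9)

    def test_threshold_monotonicity(self):
        """Enlarging every cutoff never removes a detected interaction."""
        pc = synthgen.make_planted_complex(
            [("hbond", 203), ("salt_bridge", 113), ("pi_stack", 289),
             ("contact", 114)], seed=3)
        tight = fp.detect_interactions(pc.protein, pc.pose)
        loose = fp.detect_interactions(
            pc.protein, pc.pose,
            InteractionThresholds(hbond_dist=4.5, hbond_angle=100.0,
                                  salt_bridge_dist=5.0, stack_dist=7.0,
                                  stack_angle_parallel=40.0,
                                  stack_angle_tshaped=50.0,
                                  contact_dist=4.5))
        tight_set = {(h.itype, h.res_id, h.feature_class) for h in tight}
        loose_set = {(h.itype, h.res_id, h.feature_class) for h in loose}
        assert tight_set <= loose_set


class TestEvaluateChecklist:
    def test_fully_planted_fraction_one(self):
        pc = synthgen.make_planted_complex(
            [("hbond", 203), ("salt_bridge", 113),
             ("pi_stack", 289), ("contact", 114)], seed=1)
        f = fp.evaluate_checklist(pc.protein, pc.pose, pc.checklist)
        assert f.fraction == 1.0

    def test_translated_ligand_fraction_zero(self):
        pc = synthgen.make_planted_complex(
            [("hbond", 203), ("salt_bridge", 113),
             ("pi_stack", 289), ("contact", 114)], seed=1)
        away = pc.pose.transformed(np.eye(3), np.array([50.0, 0, 0]))
        f = fp.evaluate_checklist(pc.protein, away, pc.checklist)
        assert f.fraction == 0.0

    def test_partial_plant_satisfies_exactly_planted(self):
        full = synthgen.make_planted_complex(
            [("hbond", 203), ("salt_bridge", 113),
             ("pi_stack", 289), ("contact", 114)], seed=2)
        # strip the probe features of two planted interactions: their
        # checklist entries become unsatisfiable while the geometry of the
        # remaining two is untouched
        kept = {full.checklist[0].feature_class, full.checklist[1].feature_class}
        partial_pose = fp.LigandPose(
            full.pose.atom_name, full.pose.element, full.pose.coords,
            [feat for feat in full.pose.features
             if not feat.feature_class.startswith("probe")
             or feat.feature_class in kept])
        f = fp.evaluate_checklist(full.protein, partial_pose, full.checklist)
        assert f.fraction == pytest.approx(0.5)
        got = {(e.itype, e.res_id) for e in f.satisfied_entries()}
        assert got == {("hbond", 203), ("salt_bridge", 113)}

    def test_unknown_residue_errors(self):
        pc = synthgen.make_planted_complex([("hbond", 203)], seed=0)
        bad = [ChecklistEntry(999, None, "hbond", "probe0")]
        with pytest.raises(KeyError):
            fp.evaluate_checklist(pc.protein, pc.pose, bad)


class TestTriage:
    def build_complexes(self, specs):
        """specs: list of (key, score, plant_fully)."""
        out = []
        plan = [("hbond", 203), ("salt_bridge", 113)]
        checklist = None
        for key, score, full in specs:
            pc = synthgen.make_planted_complex(plan if full else plan[:1],
                                               seed=5)
            pose = pc.pose
            pose.score = score
            protein = synthgen.make_planted_complex(plan, seed=5).protein
            out.append((key, protein, pose))
            checklist = synthgen.make_planted_complex(plan, seed=5).checklist
        return out, checklist

    def test_two_criteria_ordering(self):
        complexes, checklist = self.build_complexes(
            [("best_score", -9.0, False), ("mid", -8.0, True),
             ("worst", -7.0, True)])
        report = fp.triage_poses(complexes, checklist, min_fraction=0.75)
        assert [r.key for r in report.accepted] == ["mid", "worst"]
        assert [r.key for r in report.rejected] == ["best_score"]
        assert report.rejected[0].fraction < 0.75

    def test_all_rejected_reported(self):
        complexes, checklist = self.build_complexes(
            [("a", -9.0, False), ("b", -8.0, False)])
        report = fp.triage_poses(complexes, checklist, min_fraction=0.9)
        assert report.accepted == []
        assert len(report.rejected) == 2

    def test_permutation_invariance(self):
        complexes, checklist = self.build_complexes(
            [("a", -9.0, True), ("b", -8.5, True), ("c", -7.0, True)])
        r1 = fp.triage_poses(complexes, checklist)
        r2 = fp.triage_poses(list(reversed(complexes)), checklist)
        assert [r.key for r in r1.accepted] == [r.key for r in r2.accepted]

    def test_missing_score_errors(self):
        complexes, checklist = self.build_complexes([("a", -9.0, True)])
        key, prot, pose = complexes[0]
        pose.score = None
        with pytest.raises(ValueError):
            fp.triage_poses([(key, prot, pose)], checklist)


class TestSerialization:
    def test_pose_json_roundtrip(self):
        pc = synthgen.make_planted_complex([("hbond", 203)], seed=4)
        pc.pose.score = -7.5
        back = fp.pose_from_json(fp.pose_to_json(pc.pose))
        assert np.allclose(back.coords, pc.pose.coords)
        assert back.score == -7.5
        assert [f.feature_class for f in back.features] == \
            [f.feature_class for f in pc.pose.features]

    def test_checklist_json_roundtrip(self):
        back = fp.checklist_from_json(
            fp.checklist_to_json(fp.B2AR_AGONIST_CHECKLIST))
        assert back == fp.B2AR_AGONIST_CHECKLIST

    def test_preset_uses_tyr316(self):
        tail = [e for e in fp.B2AR_AGONIST_CHECKLIST if e.res_id == 316]
        assert tail and tail[0].res_name == "TYR"


def test_ring_coplanarity_invariant():
    pts = hexagon([0, 0, 0])
    pts[0] += [0, 0, 1.0]  # bend one member out of plane
    with pytest.raises(ValueError, match="coplanar"):
        LigandPose([f"C{j}" for j in range(6)], ["C"] * 6, pts,
                   [LigandFeature("ring", "ring", tuple(range(6)))])
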