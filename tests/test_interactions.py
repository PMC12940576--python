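"""Interaction detection, pose triage, bound-state calls, and set algebra."""

import dataclasses
import itertools

import numpy as np
import pytest

from dynasite.interactions import (
    CopperSite,
    InteractionRecord,
    LigandPose,
    build_interaction_map,
    classify_bound,
    classify_universal_specific,
    cluster_poses,
    copper_proximity_annotation,
    detect_hbonds,
    detect_nonbonded_contacts,
    detect_pi_stacking,
    validate_pose,
)
from dynasite.ligands import LIGAND_TEMPLATES
from dynasite.structmodel import Atom, Ensemble, Structure
from dynasite.synthetic_data import (
    LigandMotionSpec,
    gen_ligand_trajectory,
    gen_toy_active_site,
)

from conftest import make_structure


def _tys_at(origin=(0.0, 0.0, 0.0), serial0=1):
    """TYS ligand atoms translated so that O1 sits at ``origin``."""
    t = LIGAND_TEMPLATES["TYS"]
    names = {a[0]: np.array(a[2]) for a in t.atoms}
    off = np.asarray(origin, dtype=float) - names["O1"]
    return [
        Atom(serial=serial0 + i, name=n, element=e, residue_name="TYS",
             residue_seq=900, chain="L", position=tuple(np.array(xyz) + off),
             is_hetero=True)
        for i, (n, e, xyz) in enumerate(t.atoms)
    ]


class TestHbonds:
    def _frame_with_acceptor(self, acceptor_xyz):
        lig = _tys_at()
        prot = [
            Atom(100, "N", "N", "GLY", 1, "A", (8.0, 8.0, 8.0)),
            Atom(101, "CA", "C", "GLY", 1, "A", (9.4, 8.0, 8.0)),
            Atom(102, "C", "C", "GLY", 1, "A", (10.0, 9.3, 8.0)),
            Atom(103, "O", "O", "GLY", 1, "A", acceptor_xyz),
        ]
        return Structure(lig + prot), list(range(len(lig)))

    def _oh_direction(self):
        t = LIGAND_TEMPLATES["TYS"]
        names = {a[0]: np.array(a[2]) for a in t.atoms}
        d = names["HO1"] - names["O1"]
        return d / np.linalg.norm(d)

    def test_canonical_geometry_detected(self):
        # acceptor along the O-H direction at 2.9 A: angle 180 degrees
        acc = tuple(2.9 * self._oh_direction())
        frame, lig = self._frame_with_acceptor(acc)
        recs = [r for r in detect_hbonds(frame, lig) if r.residue == "G1"]
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.9)
        assert recs[0].angle == pytest.approx(180.0, abs=1e-6)

    def test_beyond_relaxed_cutoff_not_detected(self):
        acc = tuple(3.45 * self._oh_direction())
        frame, lig = self._frame_with_acceptor(acc)
        assert [r for r in detect_hbonds(frame, lig)
                if r.residue == "G1"] == []

    def test_boundary_inclusive_at_relaxed_criteria(self):
        # distance base + 0.39 A and angle base - 19 deg -> still detected
        from scipy.optimize import brentq

        u = self._oh_direction()
        perp = np.cross(u, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        h = 0.97 * u  # hydroxyl hydrogen position (donor at origin)

        def dha_angle(theta):
            acc = 3.39 * (np.cos(theta) * u + np.sin(theta) * perp)
            v1 = -h
            v2 = acc - h
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            return np.degrees(np.arccos(np.clip(cosang, -1, 1)))

        theta = brentq(lambda t: dha_angle(t) - 121.0, 1e-3, np.pi - 1e-3)
        acc = 3.39 * (np.cos(theta) * u + np.sin(theta) * perp)
        frame, lig = self._frame_with_acceptor(tuple(acc))
        recs = [r for r in detect_hbonds(frame, lig) if r.residue == "G1"]
        assert len(recs) == 1
        assert recs[0].angle == pytest.approx(121.0, abs=0.1)
        assert recs[0].distance == pytest.approx(3.39, abs=1e-9)

    def test_apolar_ligand_gives_empty_list(self):
        lig = [Atom(1, "C1", "C", "UNL", 900, "L", (0, 0, 0), is_hetero=True)]
        prot = [Atom(2, "O", "O", "GLY", 1, "A", (2.9, 0, 0))]
        frame = Structure(lig + prot)
        assert detect_hbonds(frame, [0]) == []


class TestNonbondedContacts:
    def _frame(self, d):
        lig = [Atom(1, "C1", "C", "UNL", 900, "L", (0, 0, 0), is_hetero=True)]
        prot = [
            Atom(2, "CA", "C", "LEU", 7, "A", (d, 0, 0)),
            Atom(3, "CB", "C", "LEU", 7, "A", (d + 1.5, 0, 0)),
        ]
        return Structure(lig + prot)

    def test_pair_within_cutoff_reported(self):
        recs = detect_nonbonded_contacts(self._frame(4.5), [0])
        assert [r.residue for r in recs] == ["L7"]
        assert recs[0].distance == pytest.approx(4.5)

    def test_pair_beyond_cutoff_absent(self):
        assert detect_nonbonded_contacts(self._frame(5.2), [0]) == []

    def test_matches_exhaustive_pair_enumeration(self, rng):
        lig = [Atom(i + 1, f"C{i}", "C", "UNL", 900, "L",
                    tuple(rng.uniform(0, 6, 3)), is_hetero=True)
               for i in range(4)]
        prot = []
        serial = 10
        for ri in range(5):
            for an in ("CA", "CB", "O"):
                prot.append(Atom(serial, an, an[0], "VAL", ri + 1, "A",
                                 tuple(rng.uniform(0, 9, 3))))
                serial += 1
        frame = Structure(lig + prot)
        recs = detect_nonbonded_contacts(frame, list(range(4)))
        got = {r.residue: r.distance for r in recs}
        # oracle: exhaustive apolar pair scan
        expected = {}
        for i in range(4):
            for a in prot:
                if a.element != "C":
                    continue
                d = np.linalg.norm(
                    np.array(frame.atoms[i].position) - np.array(a.position)
                )
                if d <= 5.0:
                    lab = f"V{a.residue_seq}"
                    expected[lab] = min(expected.get(lab, np.inf), d)
        assert set(got) == set(expected)
        for lab in got:
            assert got[lab] == pytest.approx(expected[lab], abs=1e-9)


class TestPiStacking:
    def _phe_ring(self, center, normal_rot=None):
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        atoms = []
        for k, n in enumerate(names):
            ang = np.deg2rad(60 * k)
            p = np.array([1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0])
            if normal_rot is not None:
                p = normal_rot @ p
            atoms.append(Atom(200 + k, n, "C", "PHE", 50, "A",
                              tuple(p + center)))
        return atoms

    def _lig_ring_center(self, lig_atoms):
        ring = [np.array(a.position) for a in lig_atoms
                if a.name in ("C1", "C2", "C3", "C4", "C5", "C6")]
        return np.mean(ring, axis=0)

    def test_coplanar_rings_parallel_record(self):
        lig = _tys_at()
        center = self._lig_ring_center(lig) + np.array([0, 0, 3.8])
        frame = Structure(lig + self._phe_ring(center))
        recs = detect_pi_stacking(frame, list(range(len(lig))))
        assert any(r.residue == "F50" and r.angle <= 30 for r in recs)

    def test_distant_rings_ignored(self):
        lig = _tys_at()
        center = self._lig_ring_center(lig) + np.array([0, 0, 6.0])
        frame = Structure(lig + self._phe_ring(center))
        assert detect_pi_stacking(frame, list(range(len(lig)))) == []

    def test_perpendicular_rings_t_shaped(self):
        lig = _tys_at()
        rot = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])  # 90 deg
        center = self._lig_ring_center(lig) + np.array([0, 0, 4.8])
        frame = Structure(lig + self._phe_ring(center, normal_rot=rot))
        recs = detect_pi_stacking(frame, list(range(len(lig))))
        assert any(r.residue == "F50" and 60 <= r.angle <= 90 for r in recs)


class TestValidatePose:
    def _pose(self, o1_at, flip=False):
        atoms = _tys_at(origin=o1_at)
        if flip:
            # mirror the ligand about its O1 so the ring faces the coppers
            o1 = np.array(o1_at, dtype=float)
            atoms = [
                dataclasses.replace(
                    a, position=tuple(2 * o1 - np.array(a.position))
                )
                for a in atoms
            ]
        return LigandPose(ligand=Structure(atoms), binding_energy=-6.0,
                          pose_id="p")

    def test_near_oxygen_oriented_inward_is_valid(self, toy_site):
        _, site = toy_site
        # O1 3.5 A past CuB on the open corridor, ring pointing outward
        o1 = site.cu_b + np.array([3.5, 0.0, 0.0])
        ok, reason = validate_pose(self._pose(tuple(o1)), site)
        assert ok, reason

    def test_oxygen_too_far_is_invalid(self, toy_site):
        _, site = toy_site
        o1 = site.cu_b + np.array([4.5, 0.0, 0.0])
        ok, reason = validate_pose(self._pose(tuple(o1)), site)
        assert not ok
        assert "distance" in reason

    def test_wrong_orientation_is_invalid(self, toy_site):
        # DHI (no carbonyl oxygens): rotating the ligand 180 deg about its
        # anchor hydroxyl puts the ring between the oxygen and the coppers
        _, site = toy_site
        t = LIGAND_TEMPLATES["DHI"]
        names = {a[0]: np.array(a[2]) for a in t.atoms}
        o1 = site.cu_b + np.array([3.5, 0.0, 0.0])
        rot = np.diag([-1.0, -1.0, 1.0])  # proper rotation about z
        atoms = [
            Atom(i + 1, n, e, "DHI", 900, "L",
                 tuple(rot @ (np.array(xyz) - names["O1"]) + o1),
                 is_hetero=True)
            for i, (n, e, xyz) in enumerate(t.atoms)
        ]
        pose = LigandPose(ligand=Structure(atoms), binding_energy=-6.0,
                          pose_id="flip")
        ok, reason = validate_pose(pose, site)
        assert not ok
        assert "orientation" in reason

    def test_missing_candidate_oxygen(self, toy_site):
        _, site = toy_site
        lig = Structure([Atom(1, "C1", "C", "UNL", 900, "L", (0, 0, 0),
                              is_hetero=True)])
        ok, reason = validate_pose(
            LigandPose(ligand=lig, binding_energy=-1.0, pose_id="q"), site
        )
        assert (ok, reason) == (False, "no_candidate_oxygen")

    def test_agrees_with_single_frame_bound_call(self, toy_site):
        _, site = toy_site
        ens = gen_ligand_trajectory(
            site, LigandMotionSpec(mode="bound", jitter_std=0.0, n_frames=1)
        )
        lig_idx = [i for i, a in enumerate(ens.topology.atoms)
                   if a.chain == "L"]
        res = classify_bound(ens, lig_idx, site)
        pose = LigandPose(
            ligand=Structure([ens.topology.atoms[i] for i in lig_idx]),
            binding_energy=-5.0, pose_id="f0",
        )
        ok, _ = validate_pose(pose, site)
        assert res.bound == ok


class TestClusterPoses:
    def _pose(self, dx, energy, pid):
        atoms = _tys_at(origin=(dx, 0.0, 0.0))
        return LigandPose(ligand=Structure(atoms), binding_energy=energy,
                          pose_id=pid)

    def test_identical_poses_one_cluster(self):
        clusters = cluster_poses([self._pose(0, -9, "a"),
                                  self._pose(0, -8, "b")])
        assert len(clusters) == 1
        assert {p.cluster_id for c in clusters for p in c} == {0}

    def test_distant_poses_two_clusters(self):
        clusters = cluster_poses([self._pose(0, -9, "a"),
                                  self._pose(6, -8, "b")])
        assert len(clusters) == 2

    def test_greedy_chain_assignment(self):
        # A-B 4 A, B-C 4 A, A-C 8 A with energies A < B < C
        a = self._pose(0, -9, "A")
        b = self._pose(4, -8, "B")
        c = self._pose(8, -7, "C")
        clusters = cluster_poses([c, a, b])  # order must not matter
        ids = [[p.pose_id for p in cl] for cl in clusters]
        assert ids == [["A", "B"], ["C"]]

    def test_every_pose_in_exactly_one_cluster(self, rng):
        poses = [self._pose(float(rng.uniform(0, 20)),
                            float(rng.uniform(-9, -1)), f"p{i}")
                 for i in range(12)]
        clusters = cluster_poses(poses)
        seen = [p.pose_id for c in clusters for p in c]
        assert sorted(seen) == sorted(p.pose_id for p in poses)
        for cl in clusters:
            seed = min(cl, key=lambda p: p.binding_energy)
            assert seed is cl[0] or seed.binding_energy == cl[0].binding_energy
            seed_xyz = cl[0].heavy_coords()
            for p in cl:
                d = p.heavy_coords() - seed_xyz
                assert np.sqrt(np.mean(np.sum(d * d, axis=1))) <= 5.0 + 1e-9


class TestClassifyBound:
    def test_bound_jitter_stays_bound(self, toy_site):
        _, site = toy_site
        for seed in range(5):
            ens = gen_ligand_trajectory(
                site, LigandMotionSpec(mode="bound", jitter_std=0.3,
                                       seed=seed)
            )
            lig = [i for i, a in enumerate(ens.topology.atoms)
                   if a.chain == "L"]
            res = classify_bound(ens, lig, site)
            assert res.bound
            assert all(res.frame_flags)

    @pytest.mark.parametrize("drift", [0.3, 0.5, 0.7])
    def test_escape_fails_at_analytic_crossing(self, toy_site, drift):
        _, site = toy_site
        spec = LigandMotionSpec(mode="escape", jitter_std=0.0,
                                drift_per_frame=drift, seed=2)
        ens = gen_ligand_trajectory(site, spec)
        lig = [i for i, a in enumerate(ens.topology.atoms) if a.chain == "L"]
        res = classify_bound(ens, lig, site)
        assert not res.bound
        analytic = next(
            k for k in itertools.count()
            if spec.start_distance + (k + 1) * drift > 4.0
        )
        assert res.first_failure_index == analytic

    def test_exactly_at_cutoff_is_bound(self, toy_site):
        _, site = toy_site
        lig = _tys_at(origin=tuple(site.cu_b + np.array([4.0, 0.0, 0.0])))
        top = Structure(lig)
        ens = Ensemble(topology=top, frames=[top.coords], times_ns=[1.0])
        res = classify_bound(ens, list(range(len(lig))), site)
        assert res.bound

    def test_positional_deviation_criterion(self, toy_site):
        _, site = toy_site
        spec = LigandMotionSpec(mode="escape", jitter_std=0.0,
                                drift_per_frame=1.0, seed=0, n_frames=6)
        ens = gen_ligand_trajectory(site, spec)
        lig = [i for i, a in enumerate(ens.topology.atoms) if a.chain == "L"]
        res = classify_bound(ens, lig, site,
                             criterion="positional_deviation")
        assert not res.bound
        # centroid deviation from the reference pose is (k + 1) * drift
        assert res.first_failure_index == 4  # first frame with dev > 4.0


class TestInteractionMap:
    def _record(self, residue, substrate, frame_ns):
        return InteractionRecord(residue=residue, substrate=substrate,
                                 interaction_type="hbond",
                                 frame_ns=frame_ns, distance=2.9)

    def test_full_persistence_included(self):
        recs = [self._record("H367", "s1", float(t)) for t in range(1, 21)]
        imap = build_interaction_map({"s1": recs}, n_analysis_frames=20)
        assert imap.substrate_sets["s1"] == {"H367"}
        assert imap.persistence[("s1", "H367")] == 1.0

    def test_no_records_excluded(self):
        imap = build_interaction_map({"s1": []}, n_analysis_frames=20)
        assert imap.substrate_sets["s1"] == set()

    def test_min_persistence_threshold(self):
        recs = [self._record("K334", "s1", 1.0)]  # 1 of 20 frames
        imap = build_interaction_map({"s1": recs}, n_analysis_frames=20,
                                     min_persistence=0.25)
        assert imap.substrate_sets["s1"] == set()
        assert imap.persistence[("s1", "K334")] == pytest.approx(0.05)

    def test_force_include_histidines(self):
        imap = build_interaction_map(
            {"s1": []}, n_analysis_frames=20,
            force_include={"s1": ["H211", "H390"]},
        )
        assert imap.substrate_sets["s1"] == {"H211", "H390"}
        assert ("s1", "H211") in imap.forced

    def test_transcribed_fixture_union_has_23_members(self, fixtures):
        # per-substrate sets: specific + triad, with the remaining
        # interaction-set members distributed over substrate pairs
        subs = list(fixtures.substrate_sets)
        records = {
            s: [self._record(r, s, 1.0)
                for r in fixtures.substrate_sets[s]]
            for s in subs
        }
        assigned = set().union(*(set(v) for v in
                                 fixtures.substrate_sets.values()))
        rest = [r for r in fixtures.interacting_residues
                if r not in assigned]
        for k, res in enumerate(rest):
            for s in (subs[k % 4], subs[(k + 1) % 4]):
                records[s].append(self._record(res, s, 1.0))
        imap = build_interaction_map(records, n_analysis_frames=20)
        assert len(imap.residue_union) == 23
        cls = classify_universal_specific(imap)
        assert cls.universal == set(fixtures.universal_triad)


class TestUniversalSpecific:
    def _map(self, sets):
        persistence = {(s, r): 1.0 for s, v in sets.items() for r in v}
        from dynasite.interactions import InteractionMap

        return InteractionMap(substrate_sets={k: set(v) for k, v in
                                              sets.items()},
                              persistence=persistence)

    def test_table_fixture_universal_triad(self, fixtures):
        imap = self._map(fixtures.substrate_sets)
        cls = classify_universal_specific(imap)
        assert cls.universal == {"F347", "H367", "S375"}

    def test_dhica_specific_is_r196(self, fixtures):
        imap = self._map(fixtures.substrate_sets)
        cls = classify_universal_specific(imap)
        assert cls.specific["DHICA"] == {"R196"}

    def test_identical_sets_degenerate(self):
        imap = self._map({"a": {"X1", "X2"}, "b": {"X1", "X2"}})
        cls = classify_universal_specific(imap)
        assert cls.universal == {"X1", "X2"}
        assert all(not v for v in cls.specific.values())

    def test_partition_is_exact(self, fixtures):
        imap = self._map(fixtures.substrate_sets)
        cls = classify_universal_specific(imap)
        parts = [cls.universal] + list(cls.specific.values()) + list(
            cls.shared.values()
        )
        union = set().union(*parts)
        assert union == imap.residue_union
        assert sum(len(p) for p in parts) == len(union)  # disjoint


class TestCopperProximity:
    def test_equidistant_residue_is_both(self, toy_site):
        structure, site = toy_site
        atoms = list(structure.atoms) + [
            Atom(9000, "CA", "C", "GLY", 700, "A",
                 tuple(site.midpoint + np.array([0.0, 5.0, 0.0])))
        ]
        s = Structure(atoms)
        out = copper_proximity_annotation(["G700"], site, s)
        assert out["G700"] == "both"

    def test_nearer_copper_wins(self, toy_site):
        structure, site = toy_site
        atoms = list(structure.atoms) + [
            Atom(9001, "CA", "C", "GLY", 701, "A",
                 tuple(site.cu_b + np.array([5.0, 0.0, 0.0])))
        ]
        s = Structure(atoms)
        out = copper_proximity_annotation(["G701"], site, s)
        assert out["G701"] == "CuB"

    def test_toy_site_labels_match_distance_oracle(self, toy_site):
        structure, site = toy_site
        residues = [structure.residue_label(k) for k in structure.residues
                    if structure.residue_name(k) == "HIS"]
        out = copper_proximity_annotation(residues, site, structure)
        for res in residues:
            key = next(k for k in structure.residues
                       if structure.residue_label(k) == res)
            coords = structure.coords[structure.residue_atoms(key)]
            da = np.linalg.norm(coords - site.cu_a, axis=1).min()
            db = np.linalg.norm(coords - site.cu_b, axis=1).min()
            expected = ("both" if abs(da - db) <= 1.0
                        else "CuA" if da < db else "CuB")
            assert out[res] == expected

    def test_unresolvable_residue_unassigned(self, toy_site):
        structure, site = toy_site
        out = copper_proximity_annotation(["Z999"], site, structure)
        assert out["Z999"] == "unassigned"


class TestRigidInvariance:
    def test_detection_invariant_under_rigid_transform(self, rng):
        lig = _tys_at()
        prot = [
            Atom(100, "N", "N", "GLY", 1, "A", (8.0, 8.0, 8.0)),
            Atom(101, "CA", "C", "GLY", 1, "A", (9.4, 8.0, 8.0)),
            Atom(102, "C", "C", "GLY", 1, "A", (10.0, 9.3, 8.0)),
            Atom(103, "O", "O", "GLY", 1, "A", (2.0, 1.0, 0.5)),
        ]
        frame = Structure(lig + prot)
        lig_idx = list(range(len(lig)))
        base = {(r.residue, r.interaction_type,
                 round(r.distance, 6)) for r in
                detect_hbonds(frame, lig_idx)
                + detect_nonbonded_contacts(frame, lig_idx)}
        theta = 0.7
        rot = np.array([
            [np.cos(theta), 0, np.sin(theta)],
            [0, 1, 0],
            [-np.sin(theta), 0, np.cos(theta)],
        ])
        shift = np.array([3.0, -7.0, 11.0])
        moved = Structure([
            dataclasses.replace(
                a, position=tuple(rot @ np.array(a.position) + shift)
            )
            for a in frame.atoms
        ])
        got = {(r.residue, r.interaction_type, round(r.distance, 6))
               for r in detect_hbonds(moved, lig_idx)
               + detect_nonbonded_contacts(moved, lig_idx)}
        assert got == base
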