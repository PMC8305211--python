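"""Trajectory analytics: RMSD series, EED, H-bond and water-bridge occupancy."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cvls.fixtures import (
    PlantedTrajectorySpec,
    make_ligand_trajectory,
    make_planted_trajectory,
)
from cvls.md import (
    HBondCriteria,
    Trajectory,
    end_to_end_distance,
    hbond_occupancy,
    read_trajectory,
    rmsd_series,
    water_bridge_occupancy,
    write_trajectory,
)

RNG = np.random.default_rng(11)


def _traj(names, elements, resids, resnames, frames):
    return Trajectory(list(names), list(elements), list(resids), list(resnames),
                      np.asarray(frames, float))


class TestTrajectoryIO:
    def test_three_model_pdb(self, tmp_path):
        t = make_planted_trajectory(PlantedTrajectorySpec(n_frames=3, direct_fractions=(1.0,)))
        p = tmp_path / "t.pdb"
        write_trajectory(t, p)
        back = read_trajectory(p)
        assert back.n_frames == 3
        assert back.n_atoms == t.n_atoms

    def test_single_model(self, tmp_path):
        t = make_planted_trajectory(PlantedTrajectorySpec(n_frames=1, direct_fractions=(1.0,)))
        p = tmp_path / "one.pdb"
        write_trajectory(t, p)
        assert read_trajectory(p).n_frames == 1

    def test_roundtrip_coordinates_to_format_precision(self, tmp_path):
        t = make_planted_trajectory(PlantedTrajectorySpec(n_frames=4, direct_fractions=(0.5,)))
        p = tmp_path / "t.pdb"
        write_trajectory(t, p)
        back = read_trajectory(p)
        assert np.allclose(back.coords, t.coords, atol=1.5e-3)

    def test_inconsistent_models_rejected(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "MODEL        1\n"
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "ATOM      2  H1  HOH A   1       0.960   0.000   0.000  1.00  0.00           H\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "ENDMDL\nEND\n")
        with pytest.raises(ValueError):
            read_trajectory(p)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            _traj([], [], [], [], np.zeros((0, 0, 3)))


class TestRMSDSeries:
    def test_static_trajectory_all_zero(self):
        X = RNG.normal(size=(10, 3))
        t = _traj([f"C{i}" for i in range(10)], ["C"] * 10, [1] * 10, ["LIG"] * 10,
                  np.tile(X, (5, 1, 1)))
        assert np.allclose(rmsd_series(t, range(10)), 0.0)

    def test_translation_without_fit(self):
        X = RNG.normal(size=(10, 3))
        frames = [X, X + [2.0, 0, 0]]
        t = _traj([f"C{i}" for i in range(10)], ["C"] * 10, [1] * 10, ["LIG"] * 10, frames)
        out = rmsd_series(t, range(10))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(2.0)

    def test_fit_removes_rigid_motion(self):
        X = RNG.normal(size=(10, 3))
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1.0]])
        frames = [X, X @ R.T + [3.0, -1.0, 2.0]]
        t = _traj([f"C{i}" for i in range(10)], ["C"] * 10, [1] * 10, ["LIG"] * 10, frames)
        fitted = rmsd_series(t, range(10), fit_selection=range(10))
        assert fitted[1] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_kabsch_oracle(self):
        from scipy.spatial.transform import Rotation

        for _ in range(10):
            A = RNG.normal(size=(10, 3))
            B = RNG.normal(size=(10, 3))
            t = _traj([f"C{i}" for i in range(10)], ["C"] * 10, [1] * 10,
                      ["LIG"] * 10, [A, B])
            got = rmsd_series(t, range(10), fit_selection=range(10))[1]
            rot, rssd = Rotation.align_vectors(A - A.mean(0), B - B.mean(0))
            expect = rssd / math.sqrt(10)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_empty_selection_rejected(self):
        t = _traj(["C1"], ["C"], [1], ["LIG"], np.zeros((1, 1, 3)))
        with pytest.raises(ValueError):
            rmsd_series(t, [])


class TestEndToEnd:
    def test_closed_form_two_atoms(self):
        t = _traj(["C1", "C1"], ["C", "C"], [1, 2], ["CSL", "CSL"],
                  [[[0, 0, 0], [0, 0, 27.7]]])
        assert end_to_end_distance(t, [0, 1])[0] == pytest.approx(27.7)

    def test_rigid_motion_constant_series(self):
        t = make_ligand_trajectory("ZbB–VbCB–ZbB–VbCB", n_frames=6, drift_per_frame=1.0)
        sel = list(range(t.n_atoms))
        eed = end_to_end_distance(t, sel)
        assert np.allclose(eed, eed[0])

    def test_built_hexasaccharide_in_sanity_window(self):
        t = make_ligand_trajectory("Zb2B–VbC46B–Zb2B–VbC4B–ZbB–VbC6B", n_frames=1)
        eed = end_to_end_distance(t, list(range(t.n_atoms)))[0]
        assert 20.0 <= eed <= 35.0

    def test_centroid_rule(self):
        t = make_ligand_trajectory("ZbB–VbCB", n_frames=2)
        out = end_to_end_distance(t, list(range(t.n_atoms)), terminal_rule="centroid")
        assert out.shape == (2,)
        assert (out > 0).all()

    def test_single_residue_rejected(self):
        t = _traj(["C1"], ["C"], [1], ["CSL"], np.zeros((1, 1, 3)))
        with pytest.raises(ValueError):
            end_to_end_distance(t, [0])


def _brute_force_occupancy(traj, atoms_a, atoms_b, criteria):
    """Per-frame double loop over all donor/H/acceptor triples."""
    from cvls.md import _attached_h

    h_of = _attached_h(traj)

    def polar(atoms):
        donors, acceptors = [], []
        for i in atoms:
            if traj.elements[i] in ("N", "O"):
                for h in h_of.get(i, []):
                    donors.append((i, h))
                if traj.elements[i] == "O" or not h_of.get(i, []):
                    acceptors.append(i)
        return donors, acceptors

    don_a, acc_a = polar(atoms_a)
    don_b, acc_b = polar(atoms_b)
    counts = {}
    for f in range(traj.n_frames):
        X = traj.coords[f]
        seen = set()
        for donors, acceptors, flip in ((don_a, acc_b, False), (don_b, acc_a, True)):
            for d, h in donors:
                for a in acceptors:
                    if np.linalg.norm(X[d] - X[a]) > criteria.distance_cutoff:
                        continue
                    u, v = X[d] - X[h], X[a] - X[h]
                    ang = math.degrees(math.acos(np.clip(
                        np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
                    if ang >= criteria.angle_cutoff:
                        key = ((traj.res_indices[a], traj.res_indices[d]) if flip
                               else (traj.res_indices[d], traj.res_indices[a]))
                        seen.add(key)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return {k: v / traj.n_frames for k, v in counts.items()}


class TestHBondOccupancy:
    def test_planted_fraction_recovered_exactly(self):
        t = make_planted_trajectory(PlantedTrajectorySpec(n_frames=10, direct_fractions=(0.7,)))
        prot = [i for i in range(t.n_atoms) if t.res_names[i] == "PRD"]
        lig = t.select_resnames({"LIG"})
        occ = hbond_occupancy(t, prot, lig)
        assert len(occ) == 1
        assert occ["occupancy"].iloc[0] == 0.70

    def test_distance_just_over_cutoff_does_not_count(self):
        # donor O-H aimed at an acceptor at 3.1 A, angle 180: distance rule fails
        names = ["OG", "HG", "O1"]
        elements = ["O", "H", "O"]
        X = np.array([[0, 0, 0], [0.96, 0, 0], [3.1, 0, 0.0]])
        t = _traj(names, elements, [1, 1, 2], ["PRD", "PRD", "LIG"], [X])
        occ = hbond_occupancy(t, [0, 1], [2])
        assert len(occ) == 0

    def test_matches_brute_force_on_random_fixture(self):
        # 5 donor hydroxyls vs 5 acceptors at random positions in a 6 A box
        rng = np.random.default_rng(3)
        names, elements, resids, resnames, pos = [], [], [], [], []
        for k in range(5):
            o = rng.uniform(0, 6, 3)
            h = o + [0.96, 0, 0]
            names += ["OG", "HG"]
            elements += ["O", "H"]
            resids += [k + 1] * 2
            resnames += ["PRD"] * 2
            pos += [o, h]
        for k in range(5):
            names.append("O1")
            elements.append("O")
            resids.append(100 + k)
            resnames.append("LIG")
            pos.append(rng.uniform(0, 6, 3))
        frames = [np.array(pos) + rng.normal(scale=0.3, size=(15, 3)) for _ in range(4)]
        t = _traj(names, elements, resids, resnames, frames)
        prot = [i for i in range(15) if resnames[i] == "PRD"]
        lig = [i for i in range(15) if resnames[i] == "LIG"]
        crit = HBondCriteria()
        got = {(r.residue_a, r.residue_b): r.occupancy
               for r in hbond_occupancy(t, prot, lig, crit).itertuples()}
        assert got == _brute_force_occupancy(t, prot, lig, crit)

    def test_invariant_to_frame_order(self):
        t = make_planted_trajectory(
            PlantedTrajectorySpec(n_frames=10, direct_fractions=(0.3, 0.6)))
        prot = [i for i in range(t.n_atoms) if t.res_names[i] == "PRD"]
        lig = t.select_resnames({"LIG"})
        a = hbond_occupancy(t, prot, lig)
        rev = Trajectory(t.names, t.elements, t.res_indices, t.res_names,
                         t.coords[::-1].copy())
        b = hbond_occupancy(rev, prot, lig)
        assert a.equals(b)

    def test_occupancy_times_frames_integral(self):
        t = make_planted_trajectory(
            PlantedTrajectorySpec(n_frames=10, direct_fractions=(0.7, 0.2)))
        prot = [i for i in range(t.n_atoms) if t.res_names[i] == "PRD"]
        occ = hbond_occupancy(t, prot, t.select_resnames({"LIG"}))
        for v in occ["occupancy"]:
            assert abs(v * 10 - round(v * 10)) < 1e-9

    @given(st.sampled_from([2.4, 2.7, 3.0]), st.sampled_from([135.0, 150.0, 170.0]))
    def test_tightening_never_increases_occupancy(self, dist, ang):
        t = make_planted_trajectory(
            PlantedTrajectorySpec(n_frames=10, direct_fractions=(0.7, 0.4), jitter=0.02, seed=5))
        prot = [i for i in range(t.n_atoms) if t.res_names[i] == "PRD"]
        lig = t.select_resnames({"LIG"})
        loose = hbond_occupancy(t, prot, lig, HBondCriteria(3.0, 135.0))
        tight = hbond_occupancy(t, prot, lig, HBondCriteria(dist, ang))
        loose_map = {(r.residue_a, r.residue_b): r.occupancy for r in loose.itertuples()}
        for r in tight.itertuples():
            assert r.occupancy <= loose_map.get((r.residue_a, r.residue_b), 0.0) + 1e-12


class TestWaterBridges:
    def test_bridge_every_frame(self):
        t = make_planted_trajectory(
            PlantedTrajectorySpec(n_frames=4, direct_fractions=(), bridge_fractions=(1.0,)))
        prot = [i for i in range(t.n_atoms) if t.res_names[i] == "PRB"]
        lig = t.select_resnames({"LIG"})
        wb = water_bridge_occupancy(t, prot, lig)
        assert len(wb) == 1
        assert wb["occupancy"].iloc[0] == 1.0

    def test_half_planted_bridge(self):
        t = make_planted_trajectory(
            PlantedTrajectorySpec(n_frames=4, direct_fractions=(), bridge_fractions=(0.5,)))
        prot = [i for i in range(t.n_atoms) if t.res_names[i] == "PRB"]
        wb = water_bridge_occupancy(t, prot, t.select_resnames({"LIG"}))
        assert wb["occupancy"].iloc[0] == 0.5

    def test_water_bound_only_to_protein_is_no_bridge(self):
        # water H-bonds the protein acceptor; the ligand oxygen is far away
        names = ["O", "OW", "HW1", "HW2", "O1"]
        elements = ["O", "O", "H", "H", "O"]
        X = np.array([[0, 0, 0], [2.8, 0, 0], [1.84, 0, 0], [3.76, 0, 0],
                      [20.0, 0, 0]])
        t = _traj(names, elements, [1, 2, 2, 2, 3], ["PRB", "HOH", "HOH", "HOH", "LIG"], [X])
        wb = water_bridge_occupancy(t, [0], [4])
        assert len(wb) == 0

    def test_matches_brute_force_triple_loop(self):
        t = make_planted_trajectory(PlantedTrajectorySpec(
            n_frames=6, direct_fractions=(), bridge_fractions=(0.5, 1.0), seed=2))
        prot = [i for i in range(t.n_atoms) if t.res_names[i] == "PRB"]
        lig = t.select_resnames({"LIG"})
        got = {r.protein_residue: r.occupancy
               for r in water_bridge_occupancy(t, prot, lig).itertuples()}
        # oracle: brute force over (protein atom, water, ligand atom)
        from cvls.md import _attached_h, _qualifies
        h_of = _attached_h(t)
        crit = HBondCriteria()
        waters = {}
        for i, rn in enumerate(t.res_names):
            if rn == "HOH":
                waters.setdefault(t.res_indices[i], []).append(i)
        counts = {}
        for f in range(t.n_frames):
            X = t.coords[f]
            hits = set()
            for wid, watoms in waters.items():
                wd = [(i, h) for i in watoms for h in h_of.get(i, [])]
                wa = [i for i in watoms if t.elements[i] == "O"]
                prot_res = set()
                for p in prot:
                    for d, h in wd:
                        if _qualifies(X, (d, h), p, crit):
                            prot_res.add(t.res_indices[p])
                    for h in h_of.get(p, []):
                        if any(_qualifies(X, (p, h), a, crit) for a in wa):
                            prot_res.add(t.res_indices[p])
                lig_ok = False
                for l in lig:
                    for d, h in wd:
                        if _qualifies(X, (d, h), int(l), crit):
                            lig_ok = True
                    for h in h_of.get(int(l), []):
                        if any(_qualifies(X, (int(l), h), a, crit) for a in wa):
                            lig_ok = True
                if lig_ok:
                    hits |= prot_res
            for r in hits:
                counts[r] = counts.get(r, 0) + 1
        expect = {r: c / t.n_frames for r, c in counts.items()}
        assert got == expect


class TestCriteriaValidation:
    def test_bad_distance(self):
        with pytest.raises(ValueError):
            HBondCriteria(distance_cutoff=0.0)

    def test_bad_angle(self):
        with pytest.raises(ValueError):
            HBondCriteria(angle_cutoff=200.0)
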