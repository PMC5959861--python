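"""Superposition, SASA, contact area, and adsorption-metric oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cntor.errors import DegenerateFitError, SelectionError
from cntor.geometry import (
    SasaParams,
    adsorbed_atom_count,
    adsorbed_residues,
    adsorption_series,
    contact_area,
    kabsch_superpose,
    rmsd_series,
    sasa,
    sphere_points,
)
from cntor.synthetic import gen_adsorption_trajectory
from cntor.system import Selection, select

from conftest import make_chain_trajectory


class TestKabsch:
    def test_identity(self):
        x = np.random.default_rng(0).normal(size=(6, 3))
        _, _, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_removed(self):
        x = np.random.default_rng(1).normal(size=(7, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ rot.T + np.array([3.0, -1.0, 2.0])
        _, _, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_proper_rotation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(5, 3))
        rot, _, _ = kabsch_superpose(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    def test_matches_rotation_grid_oracle(self):
        # brute-force oracle: minimize RMSD over Euler angles from a coarse
        # grid of starts, translations handled by centroid matching
        rng = np.random.default_rng(3)
        x = np.array([[0, 0, 0], [2, 0, 0], [0, 1.5, 0], [0.3, 0.4, 2.2]])
        y = x + rng.normal(scale=0.3, size=x.shape)

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)

        def cost(angles):
            r = Rotation.from_euler("xyz", angles).as_matrix()
            return np.sqrt(np.mean(np.sum((xc @ r.T - yc) ** 2, axis=1)))

        best = np.inf
        for a in np.linspace(0, 2 * np.pi, 7):
            for b in np.linspace(0, np.pi, 4):
                for c in np.linspace(0, 2 * np.pi, 7):
                    res = minimize(cost, [a, b, c], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-14})
                    best = min(best, res.fun)
        _, _, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(best, abs=1e-6)

    def test_collinear_rejected(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(x, x + 1.0)


class TestRmsdSeries:
    def test_reference_copies_are_zero(self):
        ref = np.random.default_rng(4).normal(size=(5, 3)) * 4
        traj = make_chain_trajectory(np.stack([ref] * 4))
        sel = select(traj.system, "all")
        series = rmsd_series(traj, ref, sel)
        assert np.allclose(series.rmsd, 0.0, atol=1e-10)

    def test_translation_removed_by_fit(self):
        ref = np.random.default_rng(5).normal(size=(5, 3)) * 4
        traj = make_chain_trajectory(np.stack([ref + np.array([1.0, 0, 0])] * 3))
        sel = select(traj.system, "all")
        series = rmsd_series(traj, ref, sel)
        assert np.allclose(series.rmsd, 0.0, atol=1e-10)

    def test_matches_direct_formula(self):
        # fit on one subset, measure on another; oracle applies the fitted
        # transform explicitly and evaluates sqrt(mean |Δr|²)
        rng = np.random.default_rng(6)
        ref = rng.normal(size=(8, 3)) * 3
        frames = np.stack([ref + rng.normal(scale=0.4, size=ref.shape)
                           for _ in range(2)])
        traj = make_chain_trajectory(frames)
        fit = Selection("fit", np.arange(5))
        measure = Selection("measure", np.arange(5, 8))
        series = rmsd_series(traj, ref, fit, measure)
        for f in range(2):
            rot, trans, _ = kabsch_superpose(frames[f], ref, fit)
            moved = frames[f][5:] @ rot.T + trans
            expected = np.sqrt(np.mean(np.sum((moved - ref[5:]) ** 2, axis=1)))
            assert series.rmsd[f] == pytest.approx(expected, abs=1e-8)

    def test_invariant_under_global_rigid_transform(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(6, 3)) * 3
        frames = np.stack([ref + rng.normal(scale=0.3, size=ref.shape)
                           for _ in range(3)])
        traj = make_chain_trajectory(frames)
        sel = select(traj.system, "all")
        base = rmsd_series(traj, ref, sel).rmsd
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        moved = frames @ rot.T + np.array([5.0, 6.0, -2.0])
        series2 = rmsd_series(make_chain_trajectory(moved), ref, sel).rmsd
        assert np.allclose(base, series2, atol=1e-8)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        total, per = sasa(np.zeros((1, 3)), Selection("a", [0]), np.array([1.7]))
        analytic = 4 * np.pi * 3.1**2
        assert total == pytest.approx(analytic, rel=0.005)
        assert per.sum() == pytest.approx(total)

    def test_coincident_pair_equals_one_sphere(self):
        frame = np.zeros((2, 3))
        total, _ = sasa(frame, Selection("a", [0, 1]), np.array([1.7, 1.7]))
        assert total == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_dimer_matches_dense_point_oracle(self):
        # independent Shrake-style integration at very high point density
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        radii = np.array([1.7, 1.5])
        probe = 1.4
        expanded = radii + probe
        dense = sphere_points(200_000)
        oracle = 0.0
        for i, j in ((0, 1), (1, 0)):
            surface = frame[i] + expanded[i] * dense
            outside = np.sum((surface - frame[j]) ** 2, axis=1) >= expanded[j] ** 2
            oracle += outside.mean() * 4 * np.pi * expanded[i] ** 2
        total, _ = sasa(frame, Selection("d", [0, 1]), radii, probe_radius=probe)
        assert total == pytest.approx(oracle, rel=0.01)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        frame = rng.normal(size=(10, 3)) * 2
        radii = rng.uniform(1.2, 1.9, size=10)
        sel = Selection("s", np.arange(10))
        base, _ = sasa(frame, sel, radii)
        rot = Rotation.from_euler("zyx", [1.0, 0.5, -0.7]).as_matrix()
        rotated, _ = sasa(frame @ rot.T + 3.0, sel, radii)
        assert rotated == pytest.approx(base, rel=1e-3)


class TestContactArea:
    def test_separated_bodies_zero(self):
        frame = np.array([[0.0, 0, 0], [1.5, 0, 0], [50.0, 0, 0], [51.5, 0, 0]])
        radii = np.full(4, 1.7)
        area = contact_area(frame, Selection("rec", [0, 1]),
                            Selection("tube", [2, 3]), radii)
        assert area == pytest.approx(0.0, abs=1e-9)

    def test_coincident_copy_gives_half_sas(self):
        rng = np.random.default_rng(9)
        rec = rng.normal(size=(4, 3)) * 2
        frame = np.vstack([rec, rec])
        radii = np.full(8, 1.7)
        sas_rec, _ = sasa(frame, Selection("rec", [0, 1, 2, 3]), radii)
        area = contact_area(frame, Selection("rec", [0, 1, 2, 3]),
                            Selection("tube", [4, 5, 6, 7]), radii)
        assert area == pytest.approx(0.5 * sas_rec, rel=1e-6)

    def test_equals_definition_from_three_terms(self):
        rng = np.random.default_rng(10)
        rec = rng.normal(size=(6, 3)) * 2
        tube = rng.normal(size=(5, 3)) * 2 + np.array([4.0, 0, 0])
        frame = np.vstack([rec, tube])
        radii = np.full(11, 1.6)
        rec_sel = Selection("rec", np.arange(6))
        tube_sel = Selection("tube", np.arange(6, 11))
        area = contact_area(frame, rec_sel, tube_sel, radii)
        s_r, _ = sasa(frame, rec_sel, radii)
        s_t, _ = sasa(frame, tube_sel, radii)
        s_c, _ = sasa(frame, Selection("c", np.arange(11)), radii)
        assert area == pytest.approx(0.5 * ((s_r + s_t) - s_c), abs=1e-9)

    def test_overlapping_selections_rejected(self):
        frame = np.zeros((3, 3))
        with pytest.raises(SelectionError):
            contact_area(frame, Selection("a", [0, 1]), Selection("b", [1, 2]),
                         np.full(3, 1.7))


class TestAdsorption:
    def test_cutoff_boundary_inclusive(self):
        frame = np.array([[0.0, 0, 0], [5.9, 0, 0]])
        rec = Selection("rec", [1])
        tube = Selection("tube", [0])
        assert adsorbed_atom_count(frame, rec, tube, cutoff=6.0) == 1
        frame2 = np.array([[0.0, 0, 0], [6.1, 0, 0]])
        assert adsorbed_atom_count(frame2, rec, tube, cutoff=6.0) == 0

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            rec_xyz = rng.uniform(0, 25, size=(50, 3))
            tube_xyz = rng.uniform(0, 25, size=(100, 3))
            frame = np.vstack([rec_xyz, tube_xyz])
            rec = Selection("rec", np.arange(50))
            tube = Selection("tube", np.arange(50, 150))
            brute = sum(
                1
                for a in rec_xyz
                if np.min(np.linalg.norm(tube_xyz - a, axis=1)) <= 6.0
            )
            assert adsorbed_atom_count(frame, rec, tube) == brute

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(12)
        frame = np.vstack([rng.uniform(0, 15, size=(30, 3)),
                           rng.uniform(0, 15, size=(40, 3))])
        rec = Selection("rec", np.arange(30))
        tube = Selection("tube", np.arange(30, 70))
        counts = [adsorbed_atom_count(frame, rec, tube, cutoff=c)
                  for c in (2.0, 4.0, 6.0, 8.0)]
        assert counts == sorted(counts)

    def test_adsorbed_residues_brute_force(self):
        traj, truth = gen_adsorption_trajectory(
            approach_schedule=[(0, 1, 1.0)], jitter=0.0, seed=13
        )
        system = traj.system
        tube = select(system, "group tube")
        result = adsorbed_residues(traj.frames[0], system, tube, cutoff=6.0)
        heavy = select(system, "group receptor and heavy")
        tube_xyz = traj.frames[0][tube.atom_indices]
        brute = set()
        for a in heavy.atom_indices:
            d = np.min(np.linalg.norm(tube_xyz - traj.frames[0][a], axis=1))
            if d <= 6.0:
                brute.add(int(system.residue_indices[a]))
        assert result == brute
        assert len(result) > 0

    def test_plateau_recovery_exact(self):
        traj, truth = gen_adsorption_trajectory(jitter=0.0, seed=14)
        rec = select(traj.system, "group receptor and heavy")
        tube = select(traj.system, "group tube")
        series = adsorption_series(traj, rec, tube, cutoff=truth["cutoff"])
        assert list(series.adsorbed_atom_count) == truth["true_counts"]
        assert len(set(truth["true_counts"])) == 3

    def test_stride(self):
        traj, _ = gen_adsorption_trajectory(
            approach_schedule=[(0, 20, 10.0)], jitter=0.0, seed=15
        )
        rec = select(traj.system, "group receptor and heavy")
        tube = select(traj.system, "group tube")
        series = adsorption_series(traj, rec, tube, stride=10)
        assert len(series.adsorbed_atom_count) == 2
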