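"""Plane fits, tetrad descriptors, Kabsch superposition and RMSD maps."""

import numpy as np
import pytest

import g4integrity as g4
from g4integrity.geometry import (DegeneracyError, _batched_rmsd,
                                  aligned_mean_structure, fit_plane,
                                  guanine_angles, kabsch_superpose,
                                  rmsd_matrix, rmsd_series,
                                  tetrad_com_distance, twist_angle)
from g4integrity.structure import nucleic_heavy_indices, tetrad_core_indices
from .conftest import brute_force_rotation_rmsd


class TestFitPlane:
    def test_flat_square(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        fit = fit_plane(pts, axis_hint=[0, 0, 1])
        assert np.allclose(fit.normal, [0, 0, 1])
        assert fit.rms_out_of_plane == pytest.approx(0.0, abs=1e-12)

    def test_lifted_point_matches_closed_form(self):
        # square at z=0 plus one point at height h over the centre: the
        # least-squares plane is z = h/5, rms = sqrt((4(h/5)^2+(4h/5)^2)/5)
        h = 1.0
        pts = np.array([[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0],
                        [0, 0, h]], float)
        fit = fit_plane(pts)
        expected = np.sqrt((4 * (h / 5) ** 2 + (4 * h / 5) ** 2) / 5)
        assert fit.rms_out_of_plane == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pts", [
        np.zeros((2, 3)),
        np.outer(np.arange(5), [1.0, 2.0, 3.0]),  # collinear
    ])
    def test_degenerate_inputs_rejected(self, pts):
        with pytest.raises(DegeneracyError):
            fit_plane(pts)


class TestGuanineAngles:
    def test_ideal_tetrad_is_90_and_180(self, ideal_model, ideal_topology):
        for tet in ideal_topology.tetrads:
            adj, opp = guanine_angles(ideal_model, ideal_model.coordinates, tet)
            assert np.allclose(adj, 90.0, atol=1e-9)
            assert np.allclose(opp, 180.0, atol=1e-9)

    def test_radial_displacement_keeps_central_angles(self, ideal_model,
                                                      ideal_topology):
        # central angles depend on direction only, not radius, for a fixed
        # vertex
        tet = ideal_topology.tetrads[0]
        coords = ideal_model.coordinates.copy()
        vertex = np.mean([g4.topology.base_com(ideal_model, coords, g)
                          for g in tet.guanines], axis=0)
        com0 = g4.topology.base_com(ideal_model, coords, tet.guanines[0])
        direction = (com0 - vertex) / np.linalg.norm(com0 - vertex)
        coords[ideal_model.resids == tet.guanines[0]] += 2.0 * direction
        adj, opp = guanine_angles(ideal_model, coords, tet, vertex=vertex)
        assert np.allclose(adj, 90.0, atol=1e-9)

    def test_azimuthal_rotation_shifts_adjacent_angles(self, ideal_model,
                                                       ideal_topology):
        tet = ideal_topology.tetrads[0]
        coords = ideal_model.coordinates.copy()
        vertex = np.mean([g4.topology.base_com(ideal_model, coords, g)
                          for g in tet.guanines], axis=0)
        theta = np.radians(10.0)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        mask = ideal_model.resids == tet.guanines[0]
        coords[mask] = (coords[mask] - vertex) @ rot.T + vertex
        adj, _ = guanine_angles(ideal_model, coords, tet, vertex=vertex)
        assert sorted(np.round(adj, 6)) == [80.0, 90.0, 90.0, 100.0]


class TestTetradDescriptors:
    def test_com_distance_equals_rise(self, ideal_model, ideal_topology):
        c = ideal_model.coordinates
        t0, t1, t2 = ideal_topology.tetrads
        assert tetrad_com_distance(ideal_model, c, t0, t1) == \
            pytest.approx(3.3, abs=1e-9)
        assert tetrad_com_distance(ideal_model, c, t0, t2) == \
            pytest.approx(6.6, abs=1e-9)
        assert tetrad_com_distance(ideal_model, c, t1, t1) == 0.0

    @pytest.mark.parametrize("twist,expected", [(30.0, 30.0), (-25.0, -25.0)])
    def test_twist_recovers_builder_parameter_and_sign(self, twist, expected):
        model = g4.build_ideal_g4(g4.BuilderParams(twist=twist))
        top = g4.detect_topology(model)
        measured = twist_angle(model, model.coordinates, top.tetrads[0],
                               top.tetrads[1], top.axis)
        assert measured == pytest.approx(expected, abs=1e-6)

    def test_zero_twist_between_superposed_columns(self, ideal_model,
                                                   ideal_topology):
        t0 = ideal_topology.tetrads[0]
        assert twist_angle(ideal_model, ideal_model.coordinates, t0, t0,
                           ideal_topology.axis) == pytest.approx(0.0, abs=1e-9)

    def test_n9_convention_agrees_on_ideal_stack(self, ideal_model,
                                                 ideal_topology):
        t0, t1 = ideal_topology.tetrads[:2]
        c1 = twist_angle(ideal_model, ideal_model.coordinates, t0, t1,
                         ideal_topology.axis, vectors="c1")
        n9 = twist_angle(ideal_model, ideal_model.coordinates, t0, t1,
                         ideal_topology.axis, vectors="n9")
        assert c1 == pytest.approx(n9, abs=1e-6)


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        res = kabsch_superpose(X, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3)) * 5
        theta = np.radians(73.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        Y = X @ rot.T + [4.0, -2.0, 7.0]
        assert kabsch_superpose(X, Y).rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_rotation_search(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            n = int(rng.integers(4, 13))
            X = rng.normal(size=(n, 3)) * 4
            Y = X + rng.normal(size=(n, 3)) * 0.7
            ours = kabsch_superpose(X, Y).rmsd
            oracle = brute_force_rotation_rmsd(X, Y, seed=trial)
            assert ours == pytest.approx(oracle, abs=1e-4)
            assert ours <= oracle + 1e-9  # ours is the claimed minimum

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_flagged(self):
        X = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        Y = np.outer(np.arange(5.0), [0.0, 1.0, 0.0])
        assert kabsch_superpose(X, Y).degenerate

    def test_batched_path_agrees_with_scipy_path(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(6, 20, 3)) * 3
        B = A + rng.normal(size=(6, 20, 3)) * 0.5
        batched = _batched_rmsd(A, B)
        single = [kabsch_superpose(a, b).rmsd for a, b in zip(A, B)]
        assert np.allclose(batched, single, atol=1e-9)


@pytest.fixture(scope="module")
def noisy_ensemble(ideal_model):
    return g4.generate_ensemble(
        ideal_model, g4.EnsembleParams(n_frames=60, seed=5))


class TestRmsdSeriesAndMatrix:
    def test_identical_frames_are_zero(self, ideal_model):
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=4, seed=1, sigma_core=0.0, sigma_loop=0.0,
            rigid_motion=False))
        series = rmsd_series(traj, np.arange(ideal_model.n_atoms))
        assert np.allclose(series.values, 0.0, atol=1e-12)

    def test_translation_removed_by_superposition(self, ideal_model):
        frames = np.stack([ideal_model.coordinates,
                           ideal_model.coordinates + [10.0, 0.0, 0.0]])
        traj = g4.Trajectory(model=ideal_model, frames=frames)
        series = rmsd_series(traj, np.arange(ideal_model.n_atoms))
        assert series.values[1] == pytest.approx(0.0, abs=1e-9)

    def test_empty_selection_rejected(self, noisy_ensemble):
        with pytest.raises(ValueError):
            rmsd_series(noisy_ensemble, np.empty(0, dtype=int))

    def test_matrix_symmetric_zero_diagonal(self, noisy_ensemble, ideal_model):
        sel = tetrad_core_indices(ideal_model,
                                  g4.detect_topology(ideal_model).tetrad_resids)
        mat = rmsd_matrix(noisy_ensemble, sel, stride=2)
        assert np.array_equal(mat.values, mat.values.T)
        assert mat.values.diagonal().max() == 0.0
        assert (mat.values >= 0.0).all()

    def test_two_identical_frames_give_zero_matrix(self, ideal_model):
        frames = np.stack([ideal_model.coordinates] * 2)
        traj = g4.Trajectory(model=ideal_model, frames=frames)
        mat = rmsd_matrix(traj, np.arange(ideal_model.n_atoms))
        assert np.allclose(mat.values, 0.0, atol=1e-12)

    def test_whole_dna_exceeds_tetrad_only(self, noisy_ensemble, ideal_model):
        top = g4.detect_topology(ideal_model)
        core = tetrad_core_indices(ideal_model, top.tetrad_resids)
        whole = nucleic_heavy_indices(ideal_model)
        core_mat = rmsd_matrix(noisy_ensemble, core, stride=2)
        whole_mat = rmsd_matrix(noisy_ensemble, whole, stride=2)
        assert whole_mat.mean_off_diagonal > core_mat.mean_off_diagonal

    def test_aligned_mean_recovers_reference(self, ideal_model):
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=40, seed=9, sigma_core=0.2, sigma_loop=0.2))
        mean = aligned_mean_structure(traj)
        fit = kabsch_superpose(mean, traj.frames[0])
        # the aligned mean is much closer to any frame's underlying
        # geometry than the per-frame noise level
        assert fit.rmsd < 0.2 * np.sqrt(6)
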