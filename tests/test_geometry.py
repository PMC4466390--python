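"""Superposition, RMSD/RMSF and ring geometry."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pdzbind.errors import GeometryError
from pdzbind.geometry import (kabsch_superpose, ring_geometry, rmsd,
                              rmsd_series, rmsf_profile)
from pdzbind.structures import AtomRecord, Selection, Trajectory


def random_points(n, seed=0, scale=5.0):
    return np.random.default_rng(seed).normal(0, scale, (n, 3))


def pentagon(center=(0.0, 0.0, 0.0), radius=1.16):
    pts = [(center[0] + radius * math.cos(2 * math.pi * k / 5),
            center[1] + radius * math.sin(2 * math.pi * k / 5),
            center[2]) for k in range(5)]
    return np.array(pts)


class TestKabsch:
    def test_identity_on_equal_point_sets(self):
        pts = random_points(8, seed=1)
        sup = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(sup.translation, 0, atol=1e-9)
        assert sup.rmsd_fit == pytest.approx(0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1, abs=1e-9)

    def test_recovers_known_rotation(self):
        pts = random_points(10, seed=2)
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        moved = pts @ R.T + t
        sup = kabsch_superpose(moved, pts)
        assert sup.rmsd_fit == pytest.approx(0, abs=1e-9)
        np.testing.assert_allclose(sup.apply(moved), pts, atol=1e-9)
        np.testing.assert_allclose(sup.rotation, R.T, atol=1e-9)

    def test_optimal_against_rotation_grid(self):
        """Kabsch RMSD must beat every rotation from a brute-force search
        (coarse Euler grid plus seeded random rotations), each given its own
        optimal translation."""
        rng = np.random.default_rng(3)
        a = random_points(10, seed=4)
        b = a @ Rotation.from_euler("xyz", [20, -40, 65], degrees=True
                                    ).as_matrix().T + rng.normal(0, 0.3, (10, 3))
        best = kabsch_superpose(b, a).rmsd_fit

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        grid = np.deg2rad(np.arange(0, 360, 6.0))
        euler = np.stack(np.meshgrid(grid, grid[:30], grid, indexing="ij"),
                         axis=-1).reshape(-1, 3)
        mats = Rotation.from_euler("xyz", euler).as_matrix()
        rand = Rotation.random(20000, random_state=5).as_matrix()
        mats = np.concatenate([mats, rand])
        # RMSD after centering is optimal-translation RMSD for each rotation
        rotated = np.einsum("rij,nj->rni", mats, bc)
        rmsds = np.sqrt(np.mean(np.sum((rotated - ac) ** 2, axis=2), axis=1))
        assert best <= rmsds.min() + 1e-9

    def test_weighted_fit_prefers_heavy_points(self):
        a = random_points(6, seed=6)
        b = a.copy()
        b[0] += 2.0  # outlier
        w = np.ones(6)
        w[0] = 1e-6
        sup = kabsch_superpose(b, a, weights=w)
        # downweighting the outlier leaves the others nearly perfect
        np.testing.assert_allclose(sup.apply(b)[1:], a[1:], atol=1e-4)

    def test_forward_backward_compose_to_identity(self):
        a = random_points(7, seed=7)
        b = random_points(7, seed=8)
        f = kabsch_superpose(a, b)
        g = kabsch_superpose(b, a)
        np.testing.assert_allclose(f.rotation @ g.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(g.apply(f.apply(a)), a, atol=1e-9)

    @pytest.mark.parametrize("pts", [
        np.zeros((2, 3)),
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),
    ])
    def test_degenerate_inputs_rejected(self, pts):
        with pytest.raises(GeometryError):
            kabsch_superpose(pts, pts + 1.0)


def make_traj(coords, atom_names=None):
    n_atoms = coords.shape[1]
    names = atom_names or ["CA"] * n_atoms
    atoms = [AtomRecord(i + 1, names[i], "C", "ALA", i + 1, "A",
                        tuple(coords[0, i])) for i in range(n_atoms)]
    return Trajectory(atoms, coords)


class TestRmsdSeries:
    def test_identical_frames_zero(self):
        ref = random_points(6, seed=9)
        traj = make_traj(np.repeat(ref[None], 4, axis=0))
        s = rmsd_series(traj, Selection(), Selection())
        np.testing.assert_allclose(s.values, 0, atol=1e-9)

    def test_rigid_transform_invisible_after_fit(self):
        ref = random_points(6, seed=10)
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        coords = np.stack([ref, ref @ R.T + np.array([3.0, 1.0, -2.0])])
        traj = make_traj(coords)
        s = rmsd_series(traj, Selection(), Selection())
        assert s.values[1] == pytest.approx(0, abs=1e-9)

    def test_two_atom_displacement_hand_value(self):
        # fit atoms (res 1-4) static; analysis atoms (res 5-6) shifted by d
        d = 0.8
        ref = np.vstack([random_points(4, seed=11), [[10, 0, 0], [11, 1, 0]]])
        frame2 = ref.copy()
        frame2[4:, 0] += d
        traj = make_traj(np.stack([ref, frame2]))
        s = rmsd_series(traj, Selection(res_first=1, res_last=4),
                        Selection(res_first=5, res_last=6))
        assert s.values[1] == pytest.approx(d, abs=1e-9)


class TestRmsf:
    def test_static_ensemble_zero(self):
        ref = random_points(5, seed=12)
        traj = make_traj(np.repeat(ref[None], 10, axis=0))
        prof = rmsf_profile(traj, Selection())
        assert all(v == pytest.approx(0, abs=1e-12) for v in prof.values.values())

    def test_two_frame_hand_value(self):
        ref = random_points(4, seed=13)
        frame2 = ref.copy()
        frame2[0] += np.array([1.0, 0.0, 0.0])
        traj = make_traj(np.stack([ref, frame2]))
        prof = rmsf_profile(traj, Selection())
        assert prof.values[("A", 1)] == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert prof.values[("A", 2)] == pytest.approx(0, abs=1e-12)

    def test_isotropic_gaussian_closed_form(self):
        """RMSF about the reference converges to sqrt(3)*sigma."""
        sigma = 0.5
        rng = np.random.default_rng(14)
        ref = random_points(4, seed=15)
        n = 20000
        coords = np.empty((n, 4, 3))
        coords[0] = ref
        coords[1:] = ref[None] + rng.normal(0, sigma, (n - 1, 4, 3))
        traj = make_traj(coords)
        prof = rmsf_profile(traj, Selection())
        expected = math.sqrt(3) * sigma
        for v in prof.values.values():
            assert v == pytest.approx(expected, rel=0.02)

    def test_single_frame_mean_reference_rejected(self):
        traj = make_traj(random_points(4, seed=16)[None])
        with pytest.raises(ValueError):
            rmsf_profile(traj, Selection(), reference_mode="ensemble-mean")

    def test_mean_reference_never_exceeds_starting(self):
        rng = np.random.default_rng(17)
        ref = random_points(4, seed=18)
        coords = ref[None] + rng.normal(0, 0.4, (500, 4, 3))
        traj = make_traj(coords)
        start = rmsf_profile(traj, Selection(), reference_mode="starting")
        mean = rmsf_profile(traj, Selection(), reference_mode="ensemble-mean")
        for k in start.values:
            assert mean.values[k] <= start.values[k] + 1e-12


class TestRingGeometry:
    def test_parallel_stack_same_ordering(self):
        r1 = pentagon()
        r2 = pentagon(center=(0, 0, 3.4))
        g = ring_geometry(r1, r2)
        assert g.centroid_distance == pytest.approx(3.4, abs=1e-9)
        assert g.normal_angle == pytest.approx(0, abs=1e-9)

    def test_opposed_ordering_reads_180(self):
        r1 = pentagon()
        r2 = pentagon(center=(0, 0, 3.4))[::-1]
        g = ring_geometry(r1, r2)
        assert g.normal_angle == pytest.approx(180, abs=1e-9)

    def test_perpendicular_planes(self):
        r1 = pentagon()
        r2 = (pentagon() @ Rotation.from_euler("x", 90, degrees=True
                                               ).as_matrix().T) + np.array([4.0, 0, 0])
        g = ring_geometry(r1, r2)
        assert g.normal_angle == pytest.approx(90, abs=1e-9)

    def test_constructed_target_geometry_recovered(self):
        r1 = pentagon()
        axis = np.array([1.0, 0.0, 0.0])
        R = Rotation.from_rotvec(np.deg2rad(160) * axis).as_matrix()
        r2 = (r1 - r1.mean(0)) @ R.T + r1.mean(0) + np.array([0, 0, 5.0])
        g = ring_geometry(r1, r2)
        assert g.centroid_distance == pytest.approx(5.0, abs=1e-6)
        assert g.normal_angle == pytest.approx(160.0, abs=1e-6)

    def test_swap_symmetric(self):
        r1 = pentagon()
        r2 = (pentagon() @ Rotation.from_euler("y", 25, degrees=True
                                               ).as_matrix().T) + np.array([1, 2, 3.0])
        a = ring_geometry(r1, r2)
        b = ring_geometry(r2, r1)
        assert a.centroid_distance == pytest.approx(b.centroid_distance, abs=1e-12)
        assert a.normal_angle == pytest.approx(b.normal_angle, abs=1e-9)

    def test_collinear_ring_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]])
        with pytest.raises(GeometryError):
            ring_geometry(line, pentagon())


def test_descriptors_invariant_under_global_rigid_motion(planted_ensemble):
    """Applying one rigid transform to every frame changes nothing after
    alignment."""
    _, traj, _ = planted_ensemble
    sub = traj.slice_frames(0, 40)
    R = Rotation.from_euler("xyz", [33, -12, 78], degrees=True).as_matrix()
    t = np.array([5.0, -3.0, 9.0])
    moved = Trajectory(sub.atoms, sub.coords @ R.T + t)

    fit = Selection(chain_id="A", atom_names=("CA",))
    s0 = rmsd_series(sub, fit, fit)
    s1 = rmsd_series(moved, fit, fit)
    np.testing.assert_allclose(s0.values, s1.values, atol=1e-9)

    p0 = rmsf_profile(sub, fit, align_sel=fit)
    p1 = rmsf_profile(moved, fit, align_sel=fit)
    for k in p0.values:
        assert p0.values[k] == pytest.approx(p1.values[k], abs=1e-9)
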