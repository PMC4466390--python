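"""Interaction detectors vs brute-force oracles, occupancies, time series."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pdzbind.interactions import (InteractionCriteria, PairSpec,
                                  detect_hbonds, detect_hydrophobic,
                                  detect_salt_bridges, detect_stacking,
                                  distance_series, occupancy_table)
from pdzbind.structures import AtomRecord, Trajectory
from pdzbind.synthetic import (PlantedInteraction, SyntheticEnsembleConfig,
                               generate_ensemble, plant_pair_specs)

CRIT = InteractionCriteria()


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops, no package geometry helpers)
# ---------------------------------------------------------------------------

def dist(c, i, j):
    return math.dist(c[i], c[j])


def brute_hbonds(c, donors, acceptors, crit, mode):
    out = set()
    for d, h in donors:
        for a in acceptors:
            if a == d or dist(c, d, a) > crit.hbond_da_max:
                continue
            if mode == "with_hydrogens":
                if dist(c, h, a) > crit.hbond_ha_max:
                    continue
                v1 = np.array(c[d]) - np.array(c[h])
                v2 = np.array(c[a]) - np.array(c[h])
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if math.degrees(math.acos(max(-1, min(1, cosang)))) < crit.hbond_dha_min:
                    continue
                out.add((d, h, a))
            else:
                out.add((d, a))
    return out


def brute_salt_pairs(c, cation, anion, crit):
    return {(n, o) for n in cation for o in anion
            if dist(c, n, o) <= crit.salt_no_max}


def brute_hydrophobic(c, c1, c2, crit):
    return {(i, j) for i in c1 for j in c2
            if i != j and dist(c, i, j) <= crit.hydrophobic_cc_max}


def plane_normal_newell(ring):
    ring = np.asarray(ring, float)
    ctr = ring.mean(axis=0)
    n = np.zeros(3)
    for i in range(len(ring)):
        n += np.cross(ring[i] - ctr, ring[(i + 1) % len(ring)] - ctr)
    return n / np.linalg.norm(n)


def brute_stacking(c, ring1, ring2, crit):
    r1 = np.asarray([c[i] for i in ring1])
    r2 = np.asarray([c[i] for i in ring2])
    d = np.linalg.norm(r1.mean(0) - r2.mean(0))
    ang = math.degrees(math.acos(max(-1.0, min(1.0,
        float(np.dot(plane_normal_newell(r1), plane_normal_newell(r2)))))))
    return (d <= crit.stack_centroid_max and
            (ang <= crit.stack_parallel_tol or ang >= 180 - crit.stack_parallel_tol),
            d, ang)


def random_planar_ring(rng, n=5):
    """Exactly planar random pentagon: random plane, random placement."""
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    flat = np.array([[1.3 * math.cos(2 * math.pi * k / n),
                      1.3 * math.sin(2 * math.pi * k / n), 0.0]
                     for k in range(n)])
    return flat @ R.T + rng.uniform(-4, 4, 3)


# ---------------------------------------------------------------------------

class TestHbond:
    def test_ideal_linear_geometry_detected(self):
        c = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])  # D, H, A
        ev = detect_hbonds(c, [(0, 1)], [2], CRIT)
        assert len(ev) == 1
        assert ev[0].distance == pytest.approx(2.9)
        assert ev[0].angle == pytest.approx(180.0)

    def test_long_donor_acceptor_distance_rejected(self):
        c = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.6, 0, 0]])
        assert detect_hbonds(c, [(0, 1)], [2], CRIT) == []

    def test_bent_geometry_rejected(self):
        # D-A = 3.0 but the D-H-A angle is acute
        c = np.array([[0.0, 0, 0], [1.0, 1.5, 0], [3.0, 0, 0]])
        assert detect_hbonds(c, [(0, 1)], [2], CRIT) == []

    def test_heavy_only_mode_uses_distance_alone(self):
        c = np.array([[0.0, 0, 0], [1.0, 1.5, 0], [3.0, 0, 0]])
        ev = detect_hbonds(c, [(0, None)], [2], CRIT, mode="heavy_only")
        assert len(ev) == 1 and ev[0].angle is None

    def test_hydrogen_required_in_full_mode(self):
        c = np.zeros((2, 3))
        with pytest.raises(ValueError):
            detect_hbonds(c, [(0, None)], [1], CRIT, mode="with_hydrogens")


class TestSaltBridge:
    def test_close_pair_detected(self):
        c = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        ev = detect_salt_bridges(c, [(0,)], [(1,)], CRIT)
        assert len(ev) == 1 and not ev[0].bifurcated

    def test_distant_pair_rejected(self):
        c = np.array([[0.0, 0, 0], [4.5, 0, 0]])
        assert detect_salt_bridges(c, [(0,)], [(1,)], CRIT) == []

    def test_bifurcated_reported_once_with_flag(self):
        c = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 3.0, 0]])  # N, O1, O2
        ev = detect_salt_bridges(c, [(0,)], [(1, 2)], CRIT)
        assert len(ev) == 1
        assert ev[0].bifurcated
        assert set(ev[0].participants) == {0, 1, 2}
        assert len(ev[0].pairs) == 2


class TestHydrophobicAndStacking:
    def test_contact_within_cutoff(self):
        c = np.array([[0.0, 0, 0], [4.5, 0, 0]])
        ev = detect_hydrophobic(c, [0], [1], CRIT)
        assert len(ev) == 1 and ev[0].distance == pytest.approx(4.5)

    def test_contact_beyond_cutoff(self):
        c = np.array([[0.0, 0, 0], [5.2, 0, 0]])
        assert detect_hydrophobic(c, [0], [1], CRIT) == []

    def test_antiparallel_stack_detected(self):
        rng = np.random.default_rng(0)
        r1 = random_planar_ring(rng)
        ctr = r1.mean(0)
        n1 = plane_normal_newell(r1)
        axis = (r1[0] - ctr) / np.linalg.norm(r1[0] - ctr)
        R = Rotation.from_rotvec(np.deg2rad(160) * axis).as_matrix()
        r2 = (r1 - ctr) @ R.T + ctr + 5.0 * n1
        c = np.vstack([r1, r2])
        ev = detect_stacking(c, tuple(range(5)), tuple(range(5, 10)), CRIT)
        assert len(ev) == 1
        assert ev[0].distance == pytest.approx(5.0, abs=1e-9)
        assert ev[0].angle == pytest.approx(160.0, abs=1e-9)

    def test_far_rings_rejected(self):
        rng = np.random.default_rng(1)
        r1 = random_planar_ring(rng)
        r2 = r1 + np.array([0, 0, 7.0]) @ np.eye(3)
        c = np.vstack([r1, r1 + plane_normal_newell(r1) * 7.0])
        assert detect_stacking(c, tuple(range(5)), tuple(range(5, 10)), CRIT) == []

    def test_t_shaped_rejected(self):
        r1 = np.array([[1.3 * math.cos(2 * math.pi * k / 5),
                        1.3 * math.sin(2 * math.pi * k / 5), 0.0]
                       for k in range(5)])
        R = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        r2 = r1 @ R.T + np.array([0, 0, 4.0])
        c = np.vstack([r1, r2])
        assert detect_stacking(c, tuple(range(5)), tuple(range(5, 10)), CRIT) == []


class TestOracleEquivalence:
    """Production detectors must match naive all-pairs filters exactly."""

    @pytest.mark.parametrize("seed", range(5))
    def test_hbond_salt_hydrophobic_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(0, 12, (50, 3))
        donors = [(int(i), int(i + 1)) for i in range(0, 16, 2)]
        acceptors = [int(i) for i in rng.choice(np.arange(20, 40), 10, replace=False)]
        ev = detect_hbonds(c, donors, acceptors, CRIT)
        assert {e.participants for e in ev} == brute_hbonds(
            c, donors, acceptors, CRIT, "with_hydrogens")

        ev = detect_hbonds(c, [(d, None) for d, _ in donors], acceptors,
                           CRIT, mode="heavy_only")
        assert {e.participants for e in ev} == brute_hbonds(
            c, donors, acceptors, CRIT, "heavy_only")

        cation = (40, 41, 42)
        anion = (43, 44)
        ev = detect_salt_bridges(c, [cation], [anion], CRIT)
        flat = {(n, o) for e in ev for n, o, _ in e.pairs}
        assert flat == brute_salt_pairs(c, cation, anion, CRIT)

        c1 = list(range(0, 25))
        c2 = list(range(25, 50))
        ev = detect_hydrophobic(c, c1, c2, CRIT)
        assert {e.participants for e in ev} == brute_hydrophobic(c, c1, c2, CRIT)

    @pytest.mark.parametrize("seed", range(5))
    def test_stacking_on_random_planar_rings(self, seed):
        rng = np.random.default_rng(100 + seed)
        hits = 0
        for _ in range(40):
            r1 = random_planar_ring(rng)
            r2 = random_planar_ring(rng)
            c = np.vstack([r1, r2])
            ev = detect_stacking(c, tuple(range(5)), tuple(range(5, 10)), CRIT)
            expect, d, ang = brute_stacking(c, range(5), range(5, 10), CRIT)
            assert bool(ev) == expect
            if ev:
                hits += 1
                assert ev[0].distance == pytest.approx(d, abs=1e-9)
                assert ev[0].angle == pytest.approx(ang, abs=1e-6)

    def test_detection_symmetric_under_partner_swap(self):
        rng = np.random.default_rng(42)
        c = rng.uniform(0, 10, (30, 3))
        g1, g2 = list(range(15)), list(range(15, 30))
        fwd = {e.participants for e in detect_hydrophobic(c, g1, g2, CRIT)}
        rev = {(j, i) for e in detect_hydrophobic(c, g2, g1, CRIT)
               for i, j in [e.participants]}
        assert fwd == rev

    def test_criteria_monotonicity(self):
        """Enlarging any cutoff never removes an event."""
        rng = np.random.default_rng(43)
        c = rng.uniform(0, 10, (40, 3))
        small = InteractionCriteria(hydrophobic_cc_max=4.0, salt_no_max=3.0)
        big = InteractionCriteria(hydrophobic_cc_max=6.0, salt_no_max=4.5)
        g1, g2 = list(range(20)), list(range(20, 40))
        ev_small = {e.participants for e in detect_hydrophobic(c, g1, g2, small)}
        ev_big = {e.participants for e in detect_hydrophobic(c, g1, g2, big)}
        assert ev_small <= ev_big
        sb_small = {p for e in detect_salt_bridges(c, [(0, 1)], [(2, 3)], small)
                    for p in e.pairs}
        sb_big = {p for e in detect_salt_bridges(c, [(0, 1)], [(2, 3)], big)
                  for p in e.pairs}
        assert {x[:2] for x in sb_small} <= {x[:2] for x in sb_big}


# ---------------------------------------------------------------------------

def pair_traj(distances):
    """Two-atom trajectory with prescribed per-frame separations."""
    atoms = [AtomRecord(1, "CB", "C", "ALA", 1, "A", (0.0, 0, 0)),
             AtomRecord(2, "CB", "C", "ALA", 1, "B", (float(distances[0]), 0, 0))]
    coords = np.zeros((len(distances), 2, 3))
    coords[:, 1, 0] = distances
    return Trajectory(atoms, coords)


class TestOccupancy:
    def test_always_and_never(self):
        traj = pair_traj([4.0] * 10)
        spec = PairSpec("p", "hydrophobic", (0,), (1,))
        rec = occupancy_table(traj, [spec])[0]
        assert rec.occupancy == 1.0 and rec.stable
        assert rec.mean_distance == pytest.approx(4.0)

        far = pair_traj([8.0] * 10)
        rec = occupancy_table(far, [spec])[0]
        assert rec.occupancy == 0.0 and rec.mean_distance is None
        assert not rec.stable

    def test_planted_half_occupancy_recovered(self):
        cfg = SyntheticEnsembleConfig(
            seed=21, n_frames=2000, sigma=0.2,
            plants=(PlantedInteraction(
                label="half", type="hydrophobic",
                atoms1=(("A", 27, "CD2"),), atoms2=(("B", 7, "CB"),),
                distance=4.2, target_occupancy=0.5),))
        traj, manifest = generate_ensemble(cfg)
        spec = plant_pair_specs(traj, cfg)[0]
        rec = occupancy_table(traj, [spec])[0]
        # exact agreement with the generator's realized frames
        assert rec.occupancy == pytest.approx(
            manifest["plants"][0]["realized_occupancy"], abs=1e-12)
        # and statistical agreement with the target
        assert rec.occupancy == pytest.approx(0.5, abs=3 * math.sqrt(0.25 / 2000))

    def test_occupancy_invariant_under_frame_permutation(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(3.0, 7.0, 200)
        spec = PairSpec("p", "hydrophobic", (0,), (1,))
        occ1 = occupancy_table(pair_traj(d), [spec])[0].occupancy
        occ2 = occupancy_table(pair_traj(rng.permutation(d)), [spec])[0].occupancy
        assert occ1 == occ2

    def test_empty_frame_range_rejected(self):
        traj = pair_traj([4.0] * 5)
        spec = PairSpec("p", "hydrophobic", (0,), (1,))
        with pytest.raises(ValueError):
            occupancy_table(traj, [spec], frame_range=(5, 5, 1))

    def test_records_sorted_by_label(self):
        traj = pair_traj([4.0] * 5)
        specs = [PairSpec("zz", "hydrophobic", (0,), (1,)),
                 PairSpec("aa", "hydrophobic", (0,), (1,))]
        recs = occupancy_table(traj, specs)
        assert [r.label for r in recs] == ["aa", "zz"]


class TestDistanceSeries:
    def test_static_trajectory_constant(self):
        traj = pair_traj([3.3] * 8)
        spec = PairSpec("p", "hydrophobic", (0,), (1,))
        ts = distance_series(traj, spec)
        assert ts["distance_A"].nunique() == 1
        assert ts["distance_A"].iloc[0] == pytest.approx(3.3)

    def test_oscillating_pair_min_max(self):
        d = [2.0 if i % 2 == 0 else 3.0 for i in range(20)]
        traj = pair_traj(d)
        spec = PairSpec("p", "hydrophobic", (0,), (1,))
        ts = distance_series(traj, spec)
        assert ts["distance_A"].min() == pytest.approx(2.0)
        assert ts["distance_A"].max() == pytest.approx(3.0)

    def test_gaussian_distance_mean_recovered(self):
        rng = np.random.default_rng(4)
        d = rng.normal(4.6, 0.6, 2000)
        traj = pair_traj(d)
        spec = PairSpec("p", "hydrophobic", (0,), (1,))
        ts = distance_series(traj, spec)
        assert ts["distance_A"].mean() == pytest.approx(4.6, abs=0.05)
        assert ts["distance_A"].std() == pytest.approx(0.6, rel=0.1)

    def test_frame_range_window(self):
        traj = pair_traj(np.arange(10, dtype=float) + 1)
        spec = PairSpec("p", "hydrophobic", (0,), (1,))
        ts = distance_series(traj, spec, frame_range=(2, 8, 2))
        assert list(ts["frame"]) == [2, 4, 6]
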