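"""Geometric detection of non-covalent interactions and their occupancies.

Four interaction classes are detected per frame under explicit, configurable
geometric criteria:

hydrogen bond
    with hydrogens: donor-acceptor distance, hydrogen-acceptor distance and
    donor-hydrogen-acceptor angle must all pass; heavy-atom-only mode uses
    the donor-acceptor distance alone.
salt bridge
    any cationic nitrogen within a distance cutoff of any anionic oxygen;
    when one nitrogen reaches both carboxylate oxygens (or one oxygen both
    guanidinium nitrogens) in the same frame, the contact is reported once
    as a *bifurcated* event rather than twice.
hydrophobic contact
    apolar carbon pair within a distance cutoff.
ring stacking
    ring centroid distance within a cutoff and the raw inter-normal angle
    within a tolerance of parallel (0 deg) or antiparallel (180 deg).

Aggregation over a trajectory yields per-pair occupancies (fraction of
analysed frames in which the criteria hold) with distance/angle statistics
computed over the detected frames only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .geometry import ring_geometry
from .structures import Trajectory

__all__ = [
    "InteractionCriteria",
    "InteractionEvent",
    "OccupancyRecord",
    "PairSpec",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_hydrophobic",
    "detect_stacking",
    "occupancy_table",
    "distance_series",
]


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for interaction detection.

    Distances in Å, angles in degrees. The stacking tolerance is applied to
    both ends of [0, 180] (parallel and antiparallel). ``stable_occupancy_min``
    is the occupancy fraction above which a contact is labelled stable.
    """

    hbond_da_max: float = 3.5
    hbond_ha_max: float = 2.5
    hbond_dha_min: float = 120.0
    salt_no_max: float = 4.0
    hydrophobic_cc_max: float = 5.0
    stack_centroid_max: float = 6.0
    stack_parallel_tol: float = 30.0
    stable_occupancy_min: float = 0.7

    def __post_init__(self):
        for name in ("hbond_da_max", "hbond_ha_max", "salt_no_max",
                     "hydrophobic_cc_max", "stack_centroid_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hbond_dha_min <= 180:
            raise ValueError("hbond_dha_min must be in (0, 180]")
        if not 0 < self.stack_parallel_tol <= 180:
            raise ValueError("stack_parallel_tol must be in (0, 180]")
        if not 0 <= self.stable_occupancy_min <= 1:
            raise ValueError("stable_occupancy_min must be in [0, 1]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionCriteria":
        return cls(**d)


@dataclass(frozen=True)
class InteractionEvent:
    """One detected interaction in one frame.

    ``participants`` are topology atom indices: (donor, hydrogen, acceptor)
    for hydrogen bonds, the involved N/O atoms for salt bridges, the carbon
    pair for hydrophobic contacts, and the concatenated ring atoms for
    stacking. ``pairs`` holds the qualifying (atom_i, atom_j, distance)
    triples behind a (possibly bifurcated) salt-bridge event.
    """

    type: str
    frame: int
    participants: tuple[int, ...]
    distance: float
    angle: float | None = None
    bifurcated: bool = False
    pairs: tuple[tuple[int, int, float], ...] = ()


@dataclass(frozen=True)
class OccupancyRecord:
    label: str
    type: str
    occupancy: float
    n_frames: int
    n_detected: int
    mean_distance: float | None
    sd_distance: float | None
    mean_angle: float | None = None
    sd_angle: float | None = None
    stable: bool = False


@dataclass(frozen=True)
class PairSpec:
    """A named candidate interaction, addressed by topology atom indices.

    ``group1``/``group2`` meaning depends on ``type``:
      hbond        group1 = (donor,), group2 = (acceptor,), hydrogen set
      salt_bridge  group1 = cationic N indices, group2 = anionic O indices
      hydrophobic  group1 = (carbon,), group2 = (carbon,)
      stacking     group1/group2 = ordered ring atom cycles
    """

    label: str
    type: str
    group1: tuple[int, ...]
    group2: tuple[int, ...]
    hydrogen: int | None = None

    def __post_init__(self):
        if self.type not in ("hbond", "salt_bridge", "hydrophobic", "stacking"):
            raise ValueError(f"unknown interaction type {self.type!r}")


def _dist(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[i] - coords[j]))


def _angle_deg(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle at j of the i-j-k triple, degrees."""
    v1 = coords[i] - coords[j]
    v2 = coords[k] - coords[j]
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("coincident atoms in angle computation")
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def detect_hbonds(coords: np.ndarray,
                  donors: list[tuple[int, int | None]],
                  acceptors: list[int],
                  criteria: InteractionCriteria = InteractionCriteria(),
                  mode: str = "with_hydrogens",
                  frame: int = 0) -> list[InteractionEvent]:
    """Hydrogen bonds between donor (D, H) pairs and acceptor atoms.

    ``mode='with_hydrogens'`` applies the full three-part criterion
    (D-A <= da_max, H-A <= ha_max, angle D-H-A >= dha_min); every donor must
    then carry a hydrogen index. ``mode='heavy_only'`` applies the D-A
    distance alone. One event is emitted per (D, H, A) triple.
    """
    if mode not in ("with_hydrogens", "heavy_only"):
        raise ValueError("mode must be 'with_hydrogens' or 'heavy_only'")
    coords = np.asarray(coords, dtype=float)
    events = []
    for d, h in donors:
        if mode == "with_hydrogens" and h is None:
            raise ValueError(
                "mode 'with_hydrogens' requires a hydrogen for every donor; "
                "use mode='heavy_only' for hydrogen-free topologies")
        for a in acceptors:
            if a == d:
                continue
            da = _dist(coords, d, a)
            if da > criteria.hbond_da_max:
                continue
            angle = None
            if mode == "with_hydrogens":
                ha = _dist(coords, h, a)
                if ha > criteria.hbond_ha_max:
                    continue
                angle = _angle_deg(coords, d, h, a)
                if angle < criteria.hbond_dha_min:
                    continue
            participants = (d, h, a) if mode == "with_hydrogens" else (d, a)
            events.append(InteractionEvent(
                type="hbond", frame=frame, participants=participants,
                distance=da, angle=angle))
    return events


def detect_salt_bridges(coords: np.ndarray,
                        cationic_groups: list[tuple[int, ...]],
                        anionic_groups: list[tuple[int, ...]],
                        criteria: InteractionCriteria = InteractionCriteria(),
                        frame: int = 0) -> list[InteractionEvent]:
    """Salt bridges between charged groups, merging bifurcated contacts.

    For every (cationic group, anionic group) pairing, all N-O pairs within
    ``salt_no_max`` qualify. A nitrogen reaching two oxygens of the same
    carboxylate (or an oxygen reaching two guanidinium nitrogens) is
    reported as one bifurcated event carrying all qualifying pairs; isolated
    pairs become individual events. The reported distance is the minimum
    over the event's pairs.
    """
    coords = np.asarray(coords, dtype=float)
    events: list[InteractionEvent] = []
    for cg in cationic_groups:
        for ag in anionic_groups:
            q = [(n, o, _dist(coords, n, o))
                 for n in cg for o in ag
                 if _dist(coords, n, o) <= criteria.salt_no_max]
            if not q:
                continue
            remaining = list(q)
            # bifurcation through a shared nitrogen
            for n in cg:
                mine = [p for p in remaining if p[0] == n]
                if len(mine) >= 2:
                    events.append(_bridge_event(mine, frame, bifurcated=True))
                    remaining = [p for p in remaining if p[0] != n]
            # bifurcation through a shared oxygen
            for o in ag:
                mine = [p for p in remaining if p[1] == o]
                if len(mine) >= 2:
                    events.append(_bridge_event(mine, frame, bifurcated=True))
                    remaining = [p for p in remaining if p[1] != o]
            for p in remaining:
                events.append(_bridge_event([p], frame, bifurcated=False))
    return events


def _bridge_event(pairs, frame, bifurcated):
    atoms = sorted({a for n, o, _ in pairs for a in (n, o)})
    return InteractionEvent(
        type="salt_bridge", frame=frame, participants=tuple(atoms),
        distance=min(d for _, _, d in pairs), bifurcated=bifurcated,
        pairs=tuple(pairs))


def detect_hydrophobic(coords: np.ndarray,
                       carbons1: list[int],
                       carbons2: list[int],
                       criteria: InteractionCriteria = InteractionCriteria(),
                       frame: int = 0) -> list[InteractionEvent]:
    """Apolar carbon-carbon contacts within ``hydrophobic_cc_max``."""
    coords = np.asarray(coords, dtype=float)
    events = []
    for i in carbons1:
        for j in carbons2:
            if i == j:
                continue
            d = _dist(coords, i, j)
            if d <= criteria.hydrophobic_cc_max:
                events.append(InteractionEvent(
                    type="hydrophobic", frame=frame,
                    participants=(i, j), distance=d))
    return events


def detect_stacking(coords: np.ndarray,
                    ring1: tuple[int, ...],
                    ring2: tuple[int, ...],
                    criteria: InteractionCriteria = InteractionCriteria(),
                    frame: int = 0) -> list[InteractionEvent]:
    """Parallel/antiparallel ring stacking.

    An event requires centroid distance <= ``stack_centroid_max`` and the
    raw inter-normal angle within ``stack_parallel_tol`` of 0 or 180 deg;
    the event carries the distance and the unfolded angle.
    """
    coords = np.asarray(coords, dtype=float)
    geom = ring_geometry(coords[list(ring1)], coords[list(ring2)])
    tol = criteria.stack_parallel_tol
    if geom.centroid_distance <= criteria.stack_centroid_max and (
            geom.normal_angle <= tol or geom.normal_angle >= 180.0 - tol):
        return [InteractionEvent(
            type="stacking", frame=frame,
            participants=tuple(ring1) + tuple(ring2),
            distance=geom.centroid_distance, angle=geom.normal_angle)]
    return []


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _frame_indices(n_frames: int, frame_range) -> list[int]:
    if frame_range is None:
        return list(range(n_frames))
    start, stop, stride = frame_range
    if stop is None:
        stop = n_frames
    idx = list(range(n_frames))[start:stop:stride]
    if not idx:
        raise ValueError(f"frame range {frame_range} selects no frames")
    return idx


def _measure(coords: np.ndarray, spec: PairSpec,
             criteria: InteractionCriteria,
             hbond_mode: str) -> tuple[bool, float, float | None]:
    """(detected, distance, angle) for one spec in one frame."""
    if spec.type == "hbond":
        ev = detect_hbonds(coords, [(spec.group1[0], spec.hydrogen)],
                           [spec.group2[0]], criteria, mode=hbond_mode)
        d = _dist(coords, spec.group1[0], spec.group2[0])
        return bool(ev), d, (ev[0].angle if ev else None)
    if spec.type == "salt_bridge":
        ev = detect_salt_bridges(coords, [spec.group1], [spec.group2], criteria)
        d = min(_dist(coords, n, o) for n in spec.group1 for o in spec.group2)
        return bool(ev), d, None
    if spec.type == "hydrophobic":
        d = _dist(coords, spec.group1[0], spec.group2[0])
        return d <= criteria.hydrophobic_cc_max, d, None
    if spec.type == "stacking":
        geom = ring_geometry(coords[list(spec.group1)], coords[list(spec.group2)])
        tol = criteria.stack_parallel_tol
        det = geom.centroid_distance <= criteria.stack_centroid_max and (
            geom.normal_angle <= tol or geom.normal_angle >= 180.0 - tol)
        return det, geom.centroid_distance, geom.normal_angle
    raise ValueError(spec.type)


def occupancy_table(traj: Trajectory,
                    pair_specs: list[PairSpec],
                    criteria: InteractionCriteria = InteractionCriteria(),
                    frame_range=None,
                    hbond_mode: str = "with_hydrogens") -> list[OccupancyRecord]:
    """Occupancy and distance/angle statistics per candidate pair.

    Occupancy is the fraction of analysed frames in which the pair meets
    its criteria; distance/angle means and SDs are taken over the detected
    frames only. Records are ordered by pair label. ``frame_range`` is a
    0-based half-open (start, stop, stride) window.
    """
    frames = _frame_indices(traj.n_frames, frame_range)
    records = []
    for spec in sorted(pair_specs, key=lambda s: s.label):
        dists, angles, n_det = [], [], 0
        for fi in frames:
            det, d, a = _measure(traj.coords[fi], spec, criteria, hbond_mode)
            if det:
                n_det += 1
                dists.append(d)
                if a is not None:
                    angles.append(a)
        occ = n_det / len(frames)
        records.append(OccupancyRecord(
            label=spec.label, type=spec.type, occupancy=occ,
            n_frames=len(frames), n_detected=n_det,
            mean_distance=float(np.mean(dists)) if dists else None,
            sd_distance=float(np.std(dists, ddof=1)) if len(dists) > 1 else (
                0.0 if dists else None),
            mean_angle=float(np.mean(angles)) if angles else None,
            sd_angle=float(np.std(angles, ddof=1)) if len(angles) > 1 else (
                0.0 if angles else None),
            stable=occ >= criteria.stable_occupancy_min))
    return records


def occupancy_frame(records: list[OccupancyRecord]) -> pd.DataFrame:
    """Occupancy records as a tidy DataFrame (TSV-ready)."""
    return pd.DataFrame([{
        "pair": r.label, "type": r.type, "occupancy": r.occupancy,
        "mean_dist_A": r.mean_distance, "sd_dist_A": r.sd_distance,
        "mean_angle_deg": r.mean_angle, "sd_angle_deg": r.sd_angle,
        "stable": r.stable,
    } for r in records])


def distance_series(traj: Trajectory, spec: PairSpec,
                    frame_range=None) -> pd.DataFrame:
    """Per-frame distance (and angle, for ring pairs) time series.

    For stacking specs the distance is centroid-centroid and the angle the
    raw inter-normal angle; for salt bridges the minimum N-O distance; for
    everything else the distance between the two addressed atoms.
    """
    frames = _frame_indices(traj.n_frames, frame_range)
    rows = []
    for fi in frames:
        coords = traj.coords[fi]
        if spec.type == "stacking":
            geom = ring_geometry(coords[list(spec.group1)],
                                 coords[list(spec.group2)])
            rows.append({"frame": fi, "distance_A": geom.centroid_distance,
                         "angle_deg": geom.normal_angle})
        elif spec.type == "salt_bridge":
            d = min(_dist(coords, n, o)
                    for n in spec.group1 for o in spec.group2)
            rows.append({"frame": fi, "distance_A": d})
        else:
            rows.append({"frame": fi,
                         "distance_A": _dist(coords, spec.group1[0],
                                             spec.group2[0])})
    return pd.DataFrame(rows)
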