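"""Synthetic structural ensembles and titration curves with known ground truth.

The ensemble generator emulates what a solvated MD trajectory of a
PDZ-domain-peptide complex looks like to the *analysis* code: a fixed
two-chain topology whose atoms fluctuate isotropically about a reference
structure, with selected interactions planted at controlled geometry in a
controlled (Bernoulli) fraction of frames. No physics is simulated; atom
names follow real residue templates only so the name-based interaction
templates resolve.

Construction rules:

* frame 0 is the unperturbed reference structure; frames t >= 1 are
  reference + iid isotropic Gaussian displacement with the per-residue
  sigma (Å);
* in an "on" frame a planted interaction's partner atoms are placed exactly
  at the requested distance/angle relative to the (noised) anchor atom, so
  detector output on planted pairs equals the manifest with no boundary
  flicker; in an "off" frame partners sit at least 1 Å beyond the distance
  criterion;
* the reference structure itself satisfies every planted geometry, so
  reference-frame candidate scans discover the planted pairs;
* all randomness derives from one master seed through per-purpose
  ``numpy.random.default_rng([seed, stream, ...])`` keys, so adding a plant
  never perturbs the base fluctuations or earlier plants' frames.

The default configuration mirrors the interface this package was built to
analyse: a bifurcated Glu-carboxylate/Arg-guanidinium salt bridge at 2.5 Å,
His-ring-carbon/Arg C-C contacts at 4.6 and 4.5 Å, His-His imidazole
stacking at centroid distance 5.0 Å with a raw inter-normal angle of 160
deg (and a second pair at 5.2 Å), and a Thr-hydroxyl hydrogen bond.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .binding import TitrationCurve, isotherm
from .errors import ConfigError
from .interactions import InteractionCriteria, PairSpec
from .structures import AtomRecord, Trajectory, write_multimodel_pdb

__all__ = [
    "PlantedInteraction",
    "SyntheticEnsembleConfig",
    "SyntheticTitrationConfig",
    "build_scaffold",
    "default_ensemble_config",
    "generate_ensemble",
    "plant_pair_specs",
    "generate_titration",
    "write_ensemble",
    "write_titration_csv",
]

Addr = tuple[str, int, str]  # (chain_id, res_seq, atom_name)


@dataclass(frozen=True)
class PlantedInteraction:
    """One interaction planted at controlled geometry and occupancy.

    ``atoms1`` anchor side, ``atoms2`` placed side (addresses as
    (chain, res_seq, name)); for hydrogen bonds ``hydrogen`` is the donor's
    proton, placed on the donor-acceptor axis. ``distance`` is the planted
    criterion distance (Å): donor-acceptor, minimum N-O, C-C or centroid-
    centroid depending on ``type``; ``angle`` (deg) applies to stacking.
    """

    label: str
    type: str
    atoms1: tuple[Addr, ...]
    atoms2: tuple[Addr, ...]
    distance: float
    target_occupancy: float
    angle: float | None = None
    hydrogen: Addr | None = None

    def __post_init__(self):
        if self.type not in ("hbond", "salt_bridge", "hydrophobic", "stacking"):
            raise ValueError(f"unknown planted type {self.type!r}")
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target_occupancy must be in [0, 1]")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class SyntheticEnsembleConfig:
    seed: int = 0
    n_frames: int = 2000
    sigma: float | dict = 0.3          # Å, per-residue isotropic fluctuation
    plants: tuple[PlantedInteraction, ...] = ()
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class SyntheticTitrationConfig:
    seed: int = 0
    kd: float = 5.5e-6                 # M
    a0: float = 0.05
    am: float = 0.25
    ligand_total: float = 1.0e-6       # M (labelled peptide, fixed)
    protein_totals: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.1e-6, 100e-6, 12))
    noise_sd: float = 0.0              # anisotropy units
    replicates: int = 1

    def __post_init__(self):
        self.protein_totals = np.asarray(self.protein_totals, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.protein_totals.size == 0 or np.any(np.diff(self.protein_totals) <= 0):
            raise ValueError("protein_totals must be non-empty and ascending")


# ---------------------------------------------------------------------------
# Scaffold
# ---------------------------------------------------------------------------

def _pentagon(center, radius=1.16):
    """Planar 5-ring in the xz-plane around ``center``; cycle order matches
    the imidazole template CG->ND1->CE1->NE2->CD2."""
    pts = []
    for k in range(5):
        th = 2.0 * math.pi * k / 5.0
        pts.append((center[0] + radius * math.cos(th), center[1],
                    center[2] + radius * math.sin(th)))
    return pts


def _residue_atoms(res_name: str, origin) -> list[tuple[str, tuple[float, float, float]]]:
    ox, oy, oz = origin

    def at(name, dx, dy, dz):
        return (name, (ox + dx, oy + dy, oz + dz))

    backbone = [at("N", 0.0, 0.0, 0.0), at("H", -0.4, 0.8, 0.0),
                at("CA", 1.2, 0.0, 0.4), at("C", 2.0, 1.0, -0.3),
                at("O", 2.0, 2.2, -0.1)]
    side = []
    if res_name == "ALA":
        side = [at("CB", 1.6, -1.3, 1.0)]
    elif res_name == "GLY":
        side = []
    elif res_name == "THR":
        side = [at("CB", 1.6, -1.3, 1.0), at("OG1", 1.1, -2.5, 0.6),
                at("HG1", 1.5, -3.2, 1.1), at("CG2", 3.1, -1.4, 1.2)]
    elif res_name == "LEU":
        side = [at("CB", 1.6, -1.3, 1.0), at("CG", 1.2, -2.6, 0.4),
                at("CD1", 1.8, -3.8, 1.1), at("CD2", -0.3, -2.8, 0.4)]
    elif res_name == "PHE":
        ring = _pentagon((1.4, -3.0, 0.6))  # 5 of 6 ring atoms suffice here
        names = ["CG", "CD1", "CE1", "CZ", "CE2"]
        side = [at("CB", 1.6, -1.3, 1.0)] + [
            (n, p) for n, p in zip(names, ring)] + [at("CD2", 2.9, -3.0, 0.1)]
    elif res_name == "TYR":
        side = [at("CB", 1.6, -1.3, 1.0), at("OH", 1.4, -4.5, 0.6),
                at("HH", 1.9, -5.2, 1.0)]
    elif res_name == "HIS":
        ring = _pentagon((1.4, -3.0, 0.6))
        names = ["CG", "ND1", "CE1", "NE2", "CD2"]
        side = ([at("CB", 1.6, -1.3, 1.0)] +
                [(n, p) for n, p in zip(names, ring)] +
                [at("HD1", ring[1][0] - ox - 0.5, ring[1][1] - oy - 0.9,
                    ring[1][2] - oz)])
    elif res_name == "GLU":
        side = [at("CB", 1.6, -1.3, 1.0), at("CG", 1.2, -2.6, 0.4),
                at("CD", 1.8, -3.8, 1.1), at("OE1", 1.4, -4.9, 0.6),
                at("OE2", 2.8, -3.8, 1.9)]
    elif res_name == "ASN":
        side = [at("CB", 1.6, -1.3, 1.0), at("CG", 1.2, -2.6, 0.4),
                at("OD1", 1.9, -3.6, 0.5), at("ND2", -0.1, -2.8, -0.1),
                at("HD21", -0.5, -3.7, -0.2), at("HD22", -0.7, -2.0, -0.3)]
    elif res_name == "ARG":
        side = [at("CB", 1.6, -1.3, 1.0), at("CG", 1.2, -2.6, 0.4),
                at("CD", 1.8, -3.8, 1.1), at("NE", 1.4, -5.0, 0.4),
                at("HE", 0.5, -5.0, -0.1), at("CZ", 2.1, -6.2, 0.5),
                at("NH1", 3.2, -6.3, 1.2), at("HH11", 3.7, -5.5, 1.6),
                at("HH12", 3.6, -7.2, 1.3), at("NH2", 1.6, -7.3, -0.1),
                at("HH21", 0.8, -7.3, -0.7), at("HH22", 2.1, -8.2, 0.0)]
    else:
        raise ValueError(f"no scaffold template for residue {res_name}")
    return backbone + side


_DOMAIN_RESIDUES = [
    (23, "GLY"), (24, "TYR"), (25, "GLY"), (26, "PHE"), (27, "HIS"),
    (28, "LEU"), (29, "HIS"), (43, "GLU"), (72, "HIS"),
]
# peptide numbered 1..8; res 8 is the carboxy terminus (ligand position 0)
_PEPTIDE_RESIDUES = [
    (1, "ALA"), (2, "HIS"), (3, "HIS"), (4, "ASN"), (5, "ALA"),
    (6, "THR"), (7, "ARG"), (8, "LEU"),
]


def build_scaffold() -> Trajectory:
    """Minimal two-chain complex (domain chain A, peptide chain B).

    Residues carry real atom names (Arg guanidinium, Glu carboxylate, His
    imidazole pentagons, ...) so interaction templates resolve; the peptide
    C-terminal Leu carries OXT. Geometry is schematic, not stereochemical.
    """
    atoms: list[AtomRecord] = []
    serial = 1
    for i, (res_seq, res_name) in enumerate(_DOMAIN_RESIDUES):
        # gentle out-of-line curvature so backbone selections are never collinear
        origin = (6.0 * i, 2.0 * math.sin(0.9 * i), 1.5 * math.cos(1.7 * i))
        for name, xyz in _residue_atoms(res_name, origin):
            element = "H" if name.startswith("H") else name[0]
            atoms.append(AtomRecord(serial, name, element, res_name, res_seq,
                                    "A", xyz))
            serial += 1
    for i, (res_seq, res_name) in enumerate(_PEPTIDE_RESIDUES):
        base = (6.0 * i, 14.0 + 2.0 * math.sin(1.1 * i), 1.5 * math.cos(0.8 * i))
        for name, xyz in _residue_atoms(res_name, base):
            element = "H" if name.startswith("H") else name[0]
            atoms.append(AtomRecord(serial, name, element, res_name, res_seq,
                                    "B", xyz))
            serial += 1
        if res_seq == 8:  # C-terminal carboxylate
            atoms.append(AtomRecord(serial, "OXT", "O", res_name, res_seq,
                                    "B", (base[0] + 3.0, base[1] + 1.4, base[2] - 1.0)))
            serial += 1
    coords = np.array([a.xyz for a in atoms], dtype=float)[None, :, :]
    return Trajectory(atoms, coords)


def default_ensemble_config(seed: int = 0, n_frames: int = 2000,
                            sigma: float = 0.3) -> SyntheticEnsembleConfig:
    """The standard planted complex used throughout tests and examples."""
    plants = (
        PlantedInteraction(
            label="Glu43-Arg(-1) salt bridge", type="salt_bridge",
            atoms1=(("B", 7, "NH2"),),
            atoms2=(("A", 43, "OE1"), ("A", 43, "OE2")),
            distance=2.5, target_occupancy=0.9),
        PlantedInteraction(
            label="His27.CD2-Arg(-1).CB", type="hydrophobic",
            atoms1=(("A", 27, "CD2"),), atoms2=(("B", 7, "CB"),),
            distance=4.6, target_occupancy=0.8),
        PlantedInteraction(
            label="His27.CE1-Arg(-1).CG", type="hydrophobic",
            atoms1=(("A", 27, "CE1"),), atoms2=(("B", 7, "CG"),),
            distance=4.5, target_occupancy=0.8),
        PlantedInteraction(
            label="His29-His(-5) stacking", type="stacking",
            atoms1=tuple(("A", 29, n) for n in ("CG", "ND1", "CE1", "NE2", "CD2")),
            atoms2=tuple(("B", 3, n) for n in ("CG", "ND1", "CE1", "NE2", "CD2")),
            distance=5.0, angle=160.0, target_occupancy=0.8),
        PlantedInteraction(
            label="His72-His(-6) stacking", type="stacking",
            atoms1=tuple(("A", 72, n) for n in ("CG", "ND1", "CE1", "NE2", "CD2")),
            atoms2=tuple(("B", 2, n) for n in ("CG", "ND1", "CE1", "NE2", "CD2")),
            distance=5.2, angle=160.0, target_occupancy=0.8),
        PlantedInteraction(
            label="Thr(-2).OG1-Glu43.O hbond", type="hbond",
            atoms1=(("B", 6, "OG1"),), atoms2=(("A", 43, "O"),),
            hydrogen=("B", 6, "HG1"),
            distance=2.9, target_occupancy=0.7),
    )
    return SyntheticEnsembleConfig(seed=seed, n_frames=n_frames, sigma=sigma,
                                   plants=plants)


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

def _placed_atoms(plant: PlantedInteraction) -> tuple[Addr, ...]:
    """Atoms whose coordinates the plant overwrites each frame."""
    if plant.type == "stacking":
        return plant.atoms1 + plant.atoms2
    if plant.type == "hbond":
        return plant.atoms2 + ((plant.hydrogen,) if plant.hydrogen else ())
    return plant.atoms2


def _check_feasible(plants) -> None:
    owned: dict[Addr, str] = {}
    for p in plants:
        for a in _placed_atoms(p):
            if a in owned:
                raise ConfigError(
                    f"atom {a} placed by both {owned[a]!r} and {p.label!r}")
            owned[a] = p.label
    # an anchor overwritten by another plant would break that plant's geometry
    for p in plants:
        anchors = () if p.type == "stacking" else p.atoms1
        for a in anchors:
            if a in owned and owned[a] != p.label:
                raise ConfigError(
                    f"anchor {a} of {p.label!r} is placed by {owned[a]!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ConfigError("coincident anchor/partner in planted geometry")
    return v / n


def _rotation_about(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    axis = _unit(axis)
    th = math.radians(theta_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


def _newell_normal(coords: np.ndarray) -> np.ndarray:
    c = coords.mean(axis=0)
    centered = coords - c
    n = np.zeros(3)
    for i in range(len(coords)):
        n += np.cross(centered[i], centered[(i + 1) % len(coords)])
    return _unit(n)


def _stack_rings(ref_ring1: np.ndarray, distance: float,
                 angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Ring1 at its reference position; ring2 = ring1 rotated by the target
    angle about an in-plane axis through its centroid, centroid displaced by
    ``distance`` along ring1's normal. Same cyclic atom order on both rings,
    so the raw inter-normal angle equals ``angle_deg`` exactly."""
    c1 = ref_ring1.mean(axis=0)
    n1 = _newell_normal(ref_ring1)
    # any in-plane axis works; take the direction to the first atom
    axis = _unit(ref_ring1[0] - c1)
    R = _rotation_about(axis, angle_deg)
    ring2 = (ref_ring1 - c1) @ R.T + c1 + distance * n1
    return ref_ring1.copy(), ring2


def _apply_plant(coords: np.ndarray, ref: np.ndarray,
                 plant: PlantedInteraction, idx1, idx2, h_idx,
                 on: bool, off_jitter: float,
                 criteria: InteractionCriteria) -> None:
    """Overwrite participant coordinates in one frame (in place)."""
    if plant.type == "stacking":
        if on:
            d = plant.distance
        else:
            d = criteria.stack_centroid_max + 1.0 + off_jitter
        r1, r2 = _stack_rings(ref[idx1], d, plant.angle)
        coords[idx1] = r1
        coords[idx2] = r2
        return

    anchor = coords[idx1[0]]
    u = _unit(ref[idx2[0]] - ref[idx1[0]])
    if plant.type == "salt_bridge":
        cutoff = criteria.salt_no_max
        if on:
            coords[idx2[0]] = anchor + plant.distance * u
            # second carboxylate oxygen slightly farther: bifurcated contact
            for k, j in enumerate(idx2[1:], start=1):
                d2 = min(plant.distance + 0.4 * k, cutoff - 0.1)
                v = _rotation_about(_perp(u), 10.0 * k) @ u
                coords[j] = anchor + d2 * v
        else:
            for k, j in enumerate(idx2):
                coords[j] = anchor + (cutoff + 1.0 + off_jitter + 0.3 * k) * u
        return

    if plant.type == "hydrophobic":
        cutoff = criteria.hydrophobic_cc_max
        d = plant.distance if on else cutoff + 1.0 + off_jitter
        coords[idx2[0]] = anchor + d * u
        return

    if plant.type == "hbond":
        cutoff = criteria.hbond_da_max
        d = plant.distance if on else cutoff + 1.0 + off_jitter
        coords[idx2[0]] = anchor + d * u           # acceptor on the axis
        if h_idx is not None:
            coords[h_idx] = anchor + 1.0 * u       # linear D-H...A
        return
    raise ValueError(plant.type)


def _perp(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, trial))


def generate_ensemble(config: SyntheticEnsembleConfig,
                      scaffold: Trajectory | None = None
                      ) -> tuple[Trajectory, dict]:
    """Generate a trajectory plus its ground-truth manifest.

    Returns ``(trajectory, manifest)``; the manifest records, per plant, the
    exact frames in which it is on, the planted geometry, and the realised
    occupancy, plus the fluctuation sigma per residue. Fully deterministic
    given ``config.seed``.
    """
    base = scaffold if scaffold is not None else build_scaffold()
    _check_feasible(config.plants)
    ref = base.coords[0].copy()
    n_atoms = base.n_atoms

    # per-atom sigma from per-residue config
    if isinstance(config.sigma, dict):
        sig = np.array([float(config.sigma.get((a.chain_id, a.res_seq), 0.0))
                        for a in base.atoms])
    else:
        sig = np.full(n_atoms, float(config.sigma))
    if np.any(sig < 0):
        raise ConfigError("sigma must be >= 0")

    # resolve plant addresses once and bake planted geometry into the reference
    resolved = []
    for p in config.plants:
        idx1 = [base.atom_index(*a) for a in p.atoms1]
        idx2 = [base.atom_index(*a) for a in p.atoms2]
        h_idx = base.atom_index(*p.hydrogen) if p.hydrogen else None
        resolved.append((p, idx1, idx2, h_idx))
    for p, idx1, idx2, h_idx in resolved:
        _apply_plant(ref, ref, p, idx1, idx2, h_idx, on=True,
                     off_jitter=0.0, criteria=config.criteria)

    rng_base = np.random.default_rng([config.seed, 0])
    coords = np.empty((config.n_frames, n_atoms, 3))
    coords[0] = ref                      # frame 0: unperturbed reference
    if config.n_frames > 1:
        noise = rng_base.standard_normal((config.n_frames - 1, n_atoms, 3))
        coords[1:] = ref[None] + noise * sig[None, :, None]

    manifest_plants = []
    for pi, (p, idx1, idx2, h_idx) in enumerate(resolved):
        rng_p = np.random.default_rng([config.seed, 1, pi])
        on = rng_p.random(config.n_frames) < p.target_occupancy
        on[0] = True                     # reference satisfies every plant
        jit = rng_p.random(config.n_frames) * 0.5
        for fi in range(config.n_frames):
            _apply_plant(coords[fi], ref, p, idx1, idx2, h_idx,
                         on=bool(on[fi]), off_jitter=float(jit[fi]),
                         criteria=config.criteria)
        manifest_plants.append({
            "label": p.label, "type": p.type,
            "target_occupancy": p.target_occupancy,
            "distance": p.distance, "angle": p.angle,
            "on_frames": np.flatnonzero(on).tolist(),
            "realized_occupancy": float(on.mean()),
        })

    traj = Trajectory(base.atoms, coords)
    manifest = {
        "seed": config.seed,
        "n_frames": config.n_frames,
        "sigma": (config.sigma if not isinstance(config.sigma, dict)
                  else {f"{c}:{r}": s for (c, r), s in config.sigma.items()}),
        "topology_hash": traj.topology_hash,
        "plants": manifest_plants,
    }
    return traj, manifest


def plant_pair_specs(traj: Trajectory,
                     config: SyntheticEnsembleConfig) -> list[PairSpec]:
    """PairSpecs addressing exactly the planted interactions."""
    specs = []
    for p in config.plants:
        specs.append(PairSpec(
            label=p.label, type=p.type,
            group1=tuple(traj.atom_index(*a) for a in p.atoms1),
            group2=tuple(traj.atom_index(*a) for a in p.atoms2),
            hydrogen=traj.atom_index(*p.hydrogen) if p.hydrogen else None))
    return specs


# ---------------------------------------------------------------------------
# Titration generation
# ---------------------------------------------------------------------------

def generate_titration(config: SyntheticTitrationConfig
                       ) -> tuple[list[TitrationCurve], dict]:
    """Noisy 1:1 FP titration replicates plus the generating truth."""
    curves = []
    clean = isotherm(config.a0, config.am, config.kd,
                     config.ligand_total, config.protein_totals)
    for r in range(config.replicates):
        rng = np.random.default_rng([config.seed, 2, r])
        noisy = clean + rng.standard_normal(clean.shape) * config.noise_sd
        noisy = np.clip(noisy, -0.5, 1.0)
        curves.append(TitrationCurve(
            ligand_total=config.ligand_total,
            protein_totals=config.protein_totals.copy(),
            anisotropy=noisy, replicate=str(r + 1)))
    truth = {"kd": config.kd, "a0": config.a0, "am": config.am,
             "ligand_total": config.ligand_total,
             "noise_sd": config.noise_sd, "replicates": config.replicates,
             "seed": config.seed}
    return curves, truth


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_ensemble(traj: Trajectory, manifest: dict, pdb_path,
                   manifest_path) -> None:
    write_multimodel_pdb(traj, pdb_path)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def write_titration_csv(curves: list[TitrationCurve], path) -> None:
    import pandas as pd
    rows = []
    for c in curves:
        for p, a in zip(c.protein_totals, c.anisotropy):
            rows.append({"protein_total_uM": p * 1e6, "anisotropy": a,
                         "replicate": c.replicate,
                         "ligand_total_uM": c.ligand_total * 1e6})
    pd.DataFrame(rows).to_csv(path, index=False)
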