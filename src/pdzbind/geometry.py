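"""Rigid-body superposition and ensemble descriptors.

Superposition is the classical least-squares (Kabsch) fit, delegated to
:func:`scipy.spatial.transform.Rotation.align_vectors`, which returns the
optimal proper rotation (reflections excluded). On top of it sit the
ensemble descriptors used to characterise a complex:

* per-frame RMSD of an analysis selection after fitting on a fit selection
  (e.g. peptide backbone RMSD after superposing on the domain Cα atoms);
* per-residue RMSF about the starting structure or the ensemble mean;
* imidazole ring centroid/normal geometry for His-His stacking.

Ring-plane normals are oriented by the signed ordering of the ring atom
cycle (Newell's method), so the inter-normal angle is reported raw on
[0, 180] degrees without folding: two near-parallel imidazole rings whose
atom cycles run in opposite senses legitimately read ~160 degrees rather
than ~20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError
from .structures import Selection, Trajectory, require_selection

__all__ = [
    "SuperpositionResult",
    "RmsdSeries",
    "RmsfProfile",
    "RingGeometry",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "ring_geometry",
    "rmsd",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference coordinates.

    ``apply(x) = x @ rotation.T + translation``.
    """

    rotation: np.ndarray      # (3, 3) proper orthonormal
    translation: np.ndarray   # (3,) Å
    rmsd_fit: float           # Å over the fitted points

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RmsdSeries:
    values: np.ndarray        # per-frame RMSD, Å
    fit_selection: Selection
    analysis_selection: Selection
    reference_frame: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


@dataclass(frozen=True)
class RmsfProfile:
    """Per-residue RMSF in Å keyed by (chain_id, res_seq)."""

    values: dict[tuple[str, int], float]
    reference_mode: str       # 'starting' | 'ensemble-mean'


@dataclass(frozen=True)
class RingGeometry:
    centroid1: np.ndarray
    centroid2: np.ndarray
    centroid_distance: float  # Å
    normal_angle: float       # degrees, raw in [0, 180]


def _validate_points(coords: np.ndarray, what: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"{what}: expected (n, 3) coordinates")
    if coords.shape[0] < 3:
        raise GeometryError(f"{what}: need at least 3 points")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise GeometryError(f"{what}: points are collinear")
    return coords


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation and translation minimising the (weighted)
    RMSD between paired points; at least 3 non-collinear pairs required.
    """
    mobile = _validate_points(mobile, "mobile")
    reference = _validate_points(reference, "reference")
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(mobile),) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, matching length")

    mc = np.average(mobile, axis=0, weights=w)
    rc = np.average(reference, axis=0, weights=w)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc, weights=w)
    R = rot.as_matrix()
    t = rc - R @ mc
    rmsd_fit = float(rssd / np.sqrt(w.sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd_fit=rmsd_fit)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two equal-shape point sets (no fit)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, fit_sel: Selection, analysis_sel: Selection,
                reference_frame: int = 0, align: bool = True) -> RmsdSeries:
    """Per-frame RMSD of ``analysis_sel`` after superposing on ``fit_sel``.

    Each frame is rigid-fit onto the reference frame using the fit
    selection, then the RMSD is evaluated over the analysis selection.
    The reference frame itself yields exactly 0.
    """
    fit_idx = require_selection(traj, fit_sel, "fit selection")
    ana_idx = require_selection(traj, analysis_sel, "analysis selection")
    ref_fit = traj.coords[reference_frame][fit_idx]
    ref_ana = traj.coords[reference_frame][ana_idx]

    values = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        ana = traj.coords[fi][ana_idx]
        if align:
            sup = kabsch_superpose(traj.coords[fi][fit_idx], ref_fit)
            ana = sup.apply(ana)
        values[fi] = rmsd(ana, ref_ana)
    # the reference against itself is exactly zero by definition
    values[reference_frame] = 0.0
    return RmsdSeries(values=values, fit_selection=fit_sel,
                      analysis_selection=analysis_sel,
                      reference_frame=reference_frame)


def rmsf_profile(traj: Trajectory, atom_sel: Selection,
                 reference_mode: str = "starting",
                 align_sel: Selection | None = None) -> RmsfProfile:
    """Per-residue RMSF of the selected atoms.

    RMSF(i) = sqrt(mean_t |x_i(t) - x_i(ref)|^2), with the reference taken
    from the starting structure (default, the field's usual convention when
    monitoring drift) or the ensemble mean. When a residue contributes
    several selected atoms its RMSF is the RMS over those atoms. Frames are
    assumed pre-aligned unless ``align_sel`` is given, in which case each
    frame is first superposed onto frame 0 using that selection.
    """
    if reference_mode not in ("starting", "ensemble-mean"):
        raise ValueError("reference_mode must be 'starting' or 'ensemble-mean'")
    if traj.n_frames < 2:
        if reference_mode == "ensemble-mean":
            raise ValueError("ensemble-mean RMSF undefined for a single frame")
    idx = require_selection(traj, atom_sel, "RMSF selection")

    coords = traj.coords
    if align_sel is not None:
        fit_idx = require_selection(traj, align_sel, "alignment selection")
        ref_fit = coords[0][fit_idx]
        aligned = np.empty_like(coords)
        for fi in range(traj.n_frames):
            sup = kabsch_superpose(coords[fi][fit_idx], ref_fit)
            aligned[fi] = sup.apply(coords[fi])
        coords = aligned

    sel = coords[:, idx, :]                      # (F, S, 3)
    ref = sel[0] if reference_mode == "starting" else sel.mean(axis=0)
    msf = np.mean(np.sum((sel - ref) ** 2, axis=2), axis=0)   # (S,)

    per_res: dict[tuple[str, int], list[float]] = {}
    for j, ai in enumerate(idx):
        a = traj.atoms[ai]
        per_res.setdefault((a.chain_id, a.res_seq), []).append(msf[j])
    values = {k: float(np.sqrt(np.mean(v))) for k, v in per_res.items()}
    return RmsfProfile(values=values, reference_mode=reference_mode)


def _ring_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring, oriented by the atom cycle.

    The least-squares plane normal (smallest right singular vector of the
    centered coordinates) has arbitrary sign; it is flipped to agree with
    the Newell cross-product sum over the ordered atom cycle, so rings whose
    atoms are listed in opposite senses get opposite normals.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise GeometryError("ring needs at least 3 atoms")
    c = coords.mean(axis=0)
    centered = coords - c
    s = np.linalg.svd(centered, compute_uv=True)
    U, S, Vt = s
    if S[1] < 1e-9:
        raise GeometryError("degenerate (collinear) ring")
    normal = Vt[2]
    # Newell orientation over the closed cycle.
    newell = np.zeros(3)
    n = len(coords)
    for i in range(n):
        newell += np.cross(centered[i], centered[(i + 1) % n])
    if np.linalg.norm(newell) < 1e-12:
        raise GeometryError("degenerate ring ordering")
    if np.dot(normal, newell) < 0:
        normal = -normal
    return c, normal / np.linalg.norm(normal)


def ring_geometry(ring_coords_1: np.ndarray,
                  ring_coords_2: np.ndarray) -> RingGeometry:
    """Centroid-centroid distance and raw inter-normal angle of two rings.

    The angle is reported unfolded on [0, 180] degrees; the orientation of
    each normal follows the ring's atom ordering (see module docstring).
    """
    c1, n1 = _ring_normal(ring_coords_1)
    c2, n2 = _ring_normal(ring_coords_2)
    dist = float(np.linalg.norm(c2 - c1))
    cosang = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return RingGeometry(centroid1=c1, centroid2=c2,
                        centroid_distance=dist, normal_angle=angle)
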