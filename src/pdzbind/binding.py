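"""Binding-assay mathematics: FP anisotropy isotherms and ITC thermodynamics.

Fluorescence polarization (FP)
    Anisotropy r = (I_par - I_perp) / (I_par + 2 I_perp). A titration of
    protein P into a fixed concentration L of labelled peptide follows the
    exact 1:1 ligand-depletion isotherm

        A = A0 + (Am - A0) * (Kd + L + P - sqrt((Kd + L + P)^2 - 4 L P)) / (2 L)

    where A0/Am are the free/bound anisotropies. The quadratic form is
    required because the labelled-peptide concentration is comparable to
    K_D, so free protein cannot be approximated by total protein.

Isothermal titration calorimetry (ITC)
    The instrument fit supplies K_D (as 1/K_a), ΔH° and the stoichiometry n;
    this module derives ΔG° = -RT ln(K_a) against a 1 M standard state and
    ΔS° from ΔG° = ΔH° - TΔS°, and differences mutant-vs-reference records
    into ΔΔG°/ΔΔH°/ΔΔS°.

Histidine protonation
    The Henderson-Hasselbalch protonated fraction 1/(1 + 10^(pH - pKa))
    converts printed side-chain pKa values into populations at a given pH.

Units: concentrations molar internally (μM accepted at the CSV interfaces
with explicit _uM column tags), energies kcal/mol, entropies cal/(mol K),
temperatures Kelvin. R = 1.9872e-3 kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError

__all__ = [
    "R_KCAL",
    "TitrationCurve",
    "BindingFit",
    "ThermoRecord",
    "DeltaDelta",
    "anisotropy",
    "isotherm",
    "fit_isotherm",
    "gibbs_energy",
    "entropy_from",
    "delta_delta",
    "protonated_fraction",
    "read_titration_csv",
    "read_thermo_csv",
]

R_KCAL = 1.9872e-3  # gas constant, kcal mol^-1 K^-1


def anisotropy(i_parallel: float, i_perpendicular: float) -> float:
    """Fluorescence anisotropy r = (I_par - I_perp) / (I_par + 2 I_perp).

    Bounded on [-0.5, 1]: r = 1 when all emission is parallel, -0.5 when
    all is perpendicular.
    """
    ipar = float(i_parallel)
    iperp = float(i_perpendicular)
    if ipar < 0 or iperp < 0:
        raise ValueError("intensities must be non-negative")
    denom = ipar + 2.0 * iperp
    if denom == 0:
        raise ZeroDivisionError("anisotropy undefined: both intensities zero")
    return (ipar - iperp) / denom


def isotherm(a0: float, am: float, kd: float, l_total: float,
             p_total) -> np.ndarray | float:
    """Exact 1:1 ligand-depletion binding isotherm.

    Predicted anisotropy at total protein ``p_total`` given total labelled
    ligand ``l_total`` (same concentration units as ``kd``). Equals ``a0``
    at P = 0 and approaches ``am`` at saturation; for Kd = 0 and P >= L the
    value is exactly ``am``. The discriminant is clamped at zero against
    roundoff.
    """
    if l_total <= 0:
        raise ValueError("l_total must be positive")
    if kd < 0:
        raise ValueError("kd must be non-negative")
    p = np.asarray(p_total, dtype=float)
    if np.any(p < 0):
        raise ValueError("p_total must be non-negative")
    s = kd + l_total + p
    disc = np.maximum(s * s - 4.0 * l_total * p, 0.0)
    bound_frac = (s - np.sqrt(disc)) / (2.0 * l_total)
    if kd == 0:  # full depletion: bound fraction is min(P, L)/L exactly
        bound_frac = np.minimum(p, l_total) / l_total
    out = a0 + (am - a0) * bound_frac
    out = np.where(p == 0, a0, out)  # exact free-ligand limit
    return float(out) if np.isscalar(p_total) else out


@dataclass(frozen=True)
class TitrationCurve:
    """One FP titration replicate: fixed labelled ligand, protein series."""

    ligand_total: float               # M
    protein_totals: np.ndarray        # M, strictly increasing
    anisotropy: np.ndarray            # dimensionless
    replicate: str = "1"

    def __post_init__(self):
        p = np.asarray(self.protein_totals, dtype=float)
        a = np.asarray(self.anisotropy, dtype=float)
        object.__setattr__(self, "protein_totals", p)
        object.__setattr__(self, "anisotropy", a)
        if self.ligand_total <= 0:
            raise ValueError("ligand_total must be positive")
        if p.shape != a.shape:
            raise ValueError("protein_totals and anisotropy lengths differ")
        if np.any(np.diff(p) <= 0):
            raise ValueError("protein_totals must be strictly increasing")
        if np.any(a < -0.5) or np.any(a > 1.0):
            raise ValueError("anisotropy values outside [-0.5, 1]")


@dataclass(frozen=True)
class BindingFit:
    """Fitted 1:1 isotherm parameters with Jacobian standard errors."""

    kd: float                  # M
    a0: float
    am: float
    kd_se: float
    a0_se: float
    am_se: float
    rss: float
    n_points: int
    converged: bool
    identifiable: bool = True
    saturation_reached: bool = True

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6


def _initial_guesses(p: np.ndarray, a: np.ndarray) -> list[tuple[float, float, float]]:
    a0 = float(a[np.argmin(p)])
    am = float(a[np.argmax(p)])
    half = a0 + 0.5 * (am - a0)
    # protein concentration where the curve crosses half-range
    crossing = p[np.argmin(np.abs(a - half))]
    kd0 = float(max(crossing, p[p > 0].min() if np.any(p > 0) else 1e-9))
    guesses = [(a0, am, kd0)]
    for kd in np.geomspace(max(p.max(), 1e-12) * 1e-3,
                           max(p.max(), 1e-12) * 1e2, 5):
        guesses.append((a0, am, float(kd)))
    return guesses


def fit_isotherm(curves: TitrationCurve | list[TitrationCurve],
                 init_policy: str = "auto",
                 weights: np.ndarray | None = None) -> BindingFit:
    """Weighted least-squares fit of (A0, Am, Kd) to FP titration data.

    Accepts one curve or a list of replicates sharing the ligand
    concentration (points are pooled). Kd is bounded below by zero and the
    fit is multi-started from log-spaced Kd guesses; standard errors come
    from the Jacobian at the optimum. A flat curve (Am ~ A0) is returned
    with ``identifiable=False`` rather than raising; ``saturation_reached``
    is False when the highest protein concentration is below the fitted Kd.
    """
    if isinstance(curves, TitrationCurve):
        curves = [curves]
    if not curves:
        raise ValueError("no titration data")
    l_total = curves[0].ligand_total
    for c in curves[1:]:
        if not math.isclose(c.ligand_total, l_total, rel_tol=1e-9):
            raise ValueError("replicates must share ligand_total")
    p = np.concatenate([c.protein_totals for c in curves])
    a = np.concatenate([c.anisotropy for c in curves])
    if len(np.unique(p)) < 4:
        raise ValueError("need at least 4 distinct protein concentrations")
    w = np.ones_like(a) if weights is None else np.asarray(weights, float)

    def residuals(theta):
        a0, am, kd = theta
        return (isotherm(a0, am, kd, l_total, p) - a) * np.sqrt(w)

    lower = [-0.5, -0.5, 0.0]
    upper = [1.0, 1.0, np.inf]
    best = None
    for a0g, amg, kdg in (_initial_guesses(p, a) if init_policy == "auto"
                          else [(float(a.min()), float(a.max()), float(np.median(p)))]):
        x0 = [np.clip(a0g, -0.5, 1.0), np.clip(amg, -0.5, 1.0), max(kdg, 1e-12)]
        try:
            res = least_squares(residuals, x0, bounds=(lower, upper),
                                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("isotherm fit failed to converge from every start")

    a0, am, kd = best.x
    rss = float(2 * best.cost)
    n = len(a)
    dof = max(n - 3, 1)
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        ses = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        identifiable = bool(np.all(np.isfinite(ses)))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
        identifiable = False
    amplitude = abs(am - a0)
    if amplitude < 1e-6 or (identifiable and ses[2] > 10 * max(kd, 1e-12)):
        identifiable = False
    return BindingFit(
        kd=float(kd), a0=float(a0), am=float(am),
        a0_se=float(ses[0]), am_se=float(ses[1]), kd_se=float(ses[2]),
        rss=rss, n_points=n, converged=True, identifiable=identifiable,
        saturation_reached=bool(p.max() >= kd))


# ---------------------------------------------------------------------------
# ITC thermodynamics
# ---------------------------------------------------------------------------

def gibbs_energy(kd: float, t: float = 298.15) -> float:
    """ΔG° = -RT ln(Ka) in kcal/mol, with Ka = 1/Kd against 1 M standard state."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if t <= 0:
        raise ValueError("temperature must be positive")
    return -R_KCAL * t * math.log(1.0 / kd)


def entropy_from(dh: float, dg: float, t: float = 298.15) -> float:
    """ΔS° = 1000 (ΔH° - ΔG°) / T in cal mol^-1 K^-1."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    return 1000.0 * (dh - dg) / t


@dataclass(frozen=True)
class ThermoRecord:
    """One ITC result row: K_D, ΔH°, T (plus optionally the instrument's own
    ΔG°/ΔS° as printed, kept alongside the recomputed values).

    ``dg``/``ds`` fall back to values computed from ``kd``/``dh`` when not
    supplied. When a supplied ΔG° disagrees with -RT ln(1/Kd) by more than
    0.05 kcal/mol (rounding of K_D in source tables), the record flags the
    discrepancy instead of forcing agreement.
    """

    label: str
    kd: float                   # M
    dh: float                   # kcal/mol
    t: float = 298.15           # K
    n: float = 1.0
    dg_supplied: float | None = None
    ds_supplied: float | None = None

    @property
    def dg_computed(self) -> float:
        return gibbs_energy(self.kd, self.t)

    @property
    def dg(self) -> float:
        return self.dg_supplied if self.dg_supplied is not None else self.dg_computed

    @property
    def ds_computed(self) -> float:
        return entropy_from(self.dh, self.dg, self.t)

    @property
    def ds(self) -> float:
        return self.ds_supplied if self.ds_supplied is not None else self.ds_computed

    @property
    def dg_discrepant(self) -> bool:
        if self.dg_supplied is None:
            return False
        return abs(self.dg_supplied - self.dg_computed) > 0.05


@dataclass(frozen=True)
class DeltaDelta:
    """Mutant-minus-reference differences of binding thermodynamics."""

    mutant: str
    reference: str
    ddg: float    # kcal/mol
    ddh: float    # kcal/mol
    dds: float    # cal mol^-1 K^-1
    t: float


def delta_delta(mutant: ThermoRecord, reference: ThermoRecord) -> DeltaDelta:
    """Componentwise ΔΔ quantities; both records must share the temperature."""
    if not math.isclose(mutant.t, reference.t, rel_tol=0, abs_tol=1e-9):
        raise ValueError(
            f"temperature mismatch: {mutant.t} K vs {reference.t} K")
    return DeltaDelta(
        mutant=mutant.label, reference=reference.label,
        ddg=mutant.dg - reference.dg,
        ddh=mutant.dh - reference.dh,
        dds=mutant.ds - reference.ds,
        t=mutant.t)


def protonated_fraction(ph: float, pka: float) -> float:
    """Henderson-Hasselbalch protonated fraction 1/(1 + 10^(pH - pKa))."""
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


# ---------------------------------------------------------------------------
# Delimited-text interfaces
# ---------------------------------------------------------------------------

def read_titration_csv(path, ligand_total_uM: float | None = None
                       ) -> list[TitrationCurve]:
    """Read FP titrations from CSV: protein_total_uM, anisotropy, replicate
    (optional), ligand_total_uM (optional column, else argument)."""
    df = pd.read_csv(path)
    required = {"protein_total_uM", "anisotropy"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration CSV needs columns {sorted(required)}")
    if "ligand_total_uM" in df.columns:
        lt_by_row = df["ligand_total_uM"].astype(float)
    elif ligand_total_uM is not None:
        lt_by_row = pd.Series(float(ligand_total_uM), index=df.index)
    else:
        raise ValueError("ligand_total_uM column or argument required")
    if "replicate" not in df.columns:
        df = df.assign(replicate="1")
    df = df.assign(_lt=lt_by_row)
    curves = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("protein_total_uM")
        curves.append(TitrationCurve(
            ligand_total=float(grp["_lt"].iloc[0]) * 1e-6,
            protein_totals=grp["protein_total_uM"].to_numpy(float) * 1e-6,
            anisotropy=grp["anisotropy"].to_numpy(float),
            replicate=str(rep)))
    return curves


def read_thermo_csv(path) -> list[ThermoRecord]:
    """Read ITC records from CSV: label, kd_uM, dH_kcal_mol, T_K, n, plus
    optional dG_kcal_mol / dS_cal_mol_K columns carrying instrument values."""
    df = pd.read_csv(path)
    required = {"label", "kd_uM", "dH_kcal_mol"}
    if not required.issubset(df.columns):
        raise ValueError(f"thermo CSV needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        records.append(ThermoRecord(
            label=str(row["label"]),
            kd=float(row["kd_uM"]) * 1e-6,
            dh=float(row["dH_kcal_mol"]),
            t=float(row["T_K"]) if "T_K" in df.columns and pd.notna(row.get("T_K")) else 298.15,
            n=float(row["n"]) if "n" in df.columns and pd.notna(row.get("n")) else 1.0,
            dg_supplied=(float(row["dG_kcal_mol"])
                         if "dG_kcal_mol" in df.columns and pd.notna(row.get("dG_kcal_mol"))
                         else None),
            ds_supplied=(float(row["dS_cal_mol_K"])
                         if "dS_cal_mol_K" in df.columns and pd.notna(row.get("dS_cal_mol_K"))
                         else None)))
    return records
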