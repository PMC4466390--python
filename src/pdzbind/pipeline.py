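"""End-to-end analysis orchestration from a single run configuration.

Stages run in fixed order — io, align/descriptors (RMSD, RMSF), interaction
occupancies, stacking report, distance series, FP binding fits, ITC
thermodynamics — skipping any stage whose inputs are absent from the
config. Artifacts are plain TSV/JSON for diffability; the report echoes the
full configuration so a run can be reproduced bit-identically. A stage
failure raises :class:`StageError` tagged with the stage name; artifacts of
earlier stages are already on disk by then, so a corrupt titration CSV
cannot disturb trajectory-analysis outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import templates
from .binding import (delta_delta, fit_isotherm, read_thermo_csv,
                      read_titration_csv)
from .errors import ConfigError, StageError
from .geometry import rmsd_series, rmsf_profile
from .interactions import (InteractionCriteria, PairSpec, distance_series,
                           occupancy_frame, occupancy_table)
from .structures import (Selection, Trajectory, peptide_positions,
                         read_multimodel_pdb, resolve_selection)

__all__ = ["RunConfig", "AnalysisReport", "run", "auto_scan_pairs"]

log = logging.getLogger("pdzbind")

_SCAN_MARGIN = 1.5  # candidate pairs within margin x the type cutoff


@dataclass
class RunConfig:
    """Everything one analysis run needs; round-trips through YAML/JSON."""

    # trajectory analysis
    ensemble_pdb: str | None = None
    frame_range: tuple[int, int | None, int] = (0, None, 1)
    peptide_chain: str | None = None
    fit_selection: dict | None = None          # Selection.from_dict payload
    analysis_selection: dict | None = None
    rmsf_selection: dict | None = None
    rmsf_reference_mode: str = "starting"
    criteria: dict = field(default_factory=dict)
    hbond_mode: str = "auto"                   # auto | with_hydrogens | heavy_only
    pairs: list[dict] = field(default_factory=list)
    auto_scan: bool = False
    charged_his: bool = False
    series_pairs: list[str] = field(default_factory=list)  # labels to dump

    # binding assays
    titration_csv: str | None = None
    ligand_total_uM: float | None = None
    thermo_csv: str | None = None
    thermo_reference_label: str | None = None

    temperature: float = 298.15
    output_dir: str = "pdzbind_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.frame_range is not None:
            fr = tuple(cfg.frame_range)
            if len(fr) != 3 or (fr[2] is not None and fr[2] < 1):
                raise ConfigError("frame_range must be (start, stop, stride>=1)")
            cfg.frame_range = (fr[0], fr[1], fr[2] or 1)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["frame_range"] = list(self.frame_range)
        return d


@dataclass
class AnalysisReport:
    """All tables produced by one run, JSON-serializable via ``payload``."""

    config_echo: dict
    versions: dict
    rmsd: pd.DataFrame | None = None
    rmsf: pd.DataFrame | None = None
    occupancy: pd.DataFrame | None = None
    stacking: pd.DataFrame | None = None
    series: dict[str, pd.DataFrame] = field(default_factory=dict)
    binding_fits: list[dict] = field(default_factory=list)
    thermo: pd.DataFrame | None = None
    delta_delta: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def payload(self) -> dict:
        def tbl(df):
            return None if df is None else json.loads(df.to_json(orient="records"))
        return {
            "config": self.config_echo,
            "versions": self.versions,
            "rmsd": tbl(self.rmsd),
            "rmsf": tbl(self.rmsf),
            "occupancy": tbl(self.occupancy),
            "stacking": tbl(self.stacking),
            "series": {k: tbl(v) for k, v in sorted(self.series.items())},
            "binding_fits": self.binding_fits,
            "thermo": tbl(self.thermo),
            "delta_delta": tbl(self.delta_delta),
            "warnings": self.warnings,
        }


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"pdzbind": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


def _res_label(traj: Trajectory, chain: str, res_seq: int,
               positions: dict[str, dict[int, int]]) -> str:
    res_name = next(n for c, r, n in traj.residues(chain) if r == res_seq)
    name = templates.canonical_res_name(res_name).title()
    if chain in positions:
        return f"{name}({positions[chain][res_seq]})"
    return f"{name}{res_seq}"


def _atom_label(traj, idx, positions) -> str:
    a = traj.atoms[idx]
    return f"{_res_label(traj, a.chain_id, a.res_seq, positions)}.{a.name}"


def _topology_has_hydrogens(traj: Trajectory) -> bool:
    return any(a.element == "H" or a.name.startswith("H") for a in traj.atoms)


def auto_scan_pairs(traj: Trajectory, peptide_chain: str,
                    criteria: InteractionCriteria = InteractionCriteria(),
                    charged_his: bool = False,
                    hbond_mode: str = "auto",
                    reference_frame: int = 0) -> list[PairSpec]:
    """Enumerate inter-chain candidate pairs from residue-type templates.

    Candidates are (donor/acceptor, charged group, apolar carbon, ring)
    pairings across the domain/peptide chain boundary whose reference-frame
    distance lies within 1.5x the relevant cutoff. Ordering is deterministic
    (by type, then atom indices).
    """
    chains = traj.chain_ids
    if peptide_chain not in chains:
        raise ConfigError(f"peptide chain {peptide_chain!r} not in topology")
    positions = {peptide_chain: peptide_positions(traj, peptide_chain)}
    coords = traj.coords[reference_frame]
    if hbond_mode == "auto":
        hbond_mode = ("with_hydrogens" if _topology_has_hydrogens(traj)
                      else "heavy_only")

    side_pep = [i for i, a in enumerate(traj.atoms) if a.chain_id == peptide_chain]
    side_dom = [i for i, a in enumerate(traj.atoms) if a.chain_id != peptide_chain]

    def per_residue(side):
        out: dict[tuple[str, int, str], list[int]] = {}
        for i in side:
            a = traj.atoms[i]
            out.setdefault((a.chain_id, a.res_seq, a.res_name), []).append(i)
        return out

    dom_res = per_residue(side_dom)
    pep_res = per_residue(side_pep)

    def atom_of(res_atoms, name):
        for i in res_atoms:
            if traj.atoms[i].name == name:
                return i
        return None

    specs: list[PairSpec] = []

    def donors_of(res_key, res_atoms):
        _, _, res_name = res_key
        out = []
        for heavy, hs in templates.donors_for(res_name, charged_his).items():
            d = atom_of(res_atoms, heavy)
            if d is None:
                continue
            found_h = [atom_of(res_atoms, h) for h in hs]
            found_h = [h for h in found_h if h is not None]
            if hbond_mode == "with_hydrogens":
                out.extend((d, h) for h in found_h)
            else:
                out.append((d, None))
        return out

    def acceptors_of(res_key, res_atoms):
        _, _, res_name = res_key
        return [a for name in templates.acceptors_for(res_name, charged_his)
                if (a := atom_of(res_atoms, name)) is not None]

    # hydrogen bonds, both directions across the interface
    for src, dst in ((dom_res, pep_res), (pep_res, dom_res)):
        for rk1, atoms1 in src.items():
            for d, h in donors_of(rk1, atoms1):
                for rk2, atoms2 in dst.items():
                    for acc in acceptors_of(rk2, atoms2):
                        if np.linalg.norm(coords[d] - coords[acc]) \
                                > _SCAN_MARGIN * criteria.hbond_da_max:
                            continue
                        label = (f"{_atom_label(traj, d, positions)}-"
                                 f"{_atom_label(traj, acc, positions)} hbond")
                        specs.append(PairSpec(label=label, type="hbond",
                                              group1=(d,), group2=(acc,),
                                              hydrogen=h))

    # salt bridges
    def charged_groups(res_map, table):
        out = []
        for rk, res_atoms in res_map.items():
            _, _, res_name = rk
            has_oxt = atom_of(res_atoms, "OXT") is not None
            groups = (table(res_name, charged_his) if table is not _anionic
                      else table(res_name, has_oxt))
            for g in groups:
                idx = tuple(i for n in g if (i := atom_of(res_atoms, n)) is not None)
                if idx:
                    out.append((rk, idx))
        return out

    def _cationic(res_name, flag):
        return templates.cationic_groups_for(res_name, flag)

    def _anionic(res_name, has_oxt):
        return templates.anionic_groups_for(res_name, has_oxt)

    for cat_map, an_map in ((dom_res, pep_res), (pep_res, dom_res)):
        for rk1, cg in charged_groups(cat_map, _cationic):
            for rk2, ag in charged_groups(an_map, _anionic):
                dmin = min(np.linalg.norm(coords[n] - coords[o])
                           for n in cg for o in ag)
                if dmin > _SCAN_MARGIN * criteria.salt_no_max:
                    continue
                label = (f"{_res_label(traj, rk1[0], rk1[1], positions)}-"
                         f"{_res_label(traj, rk2[0], rk2[1], positions)}"
                         " salt bridge")
                specs.append(PairSpec(label=label, type="salt_bridge",
                                      group1=cg, group2=ag))

    # hydrophobic carbon pairs
    for rk1, atoms1 in dom_res.items():
        c1s = [i for n in templates.apolar_for(rk1[2])
               if (i := atom_of(atoms1, n)) is not None]
        for rk2, atoms2 in pep_res.items():
            c2s = [j for n in templates.apolar_for(rk2[2])
                   if (j := atom_of(atoms2, n)) is not None]
            for i in c1s:
                for j in c2s:
                    if np.linalg.norm(coords[i] - coords[j]) \
                            > _SCAN_MARGIN * criteria.hydrophobic_cc_max:
                        continue
                    label = (f"{_atom_label(traj, i, positions)}-"
                             f"{_atom_label(traj, j, positions)} contact")
                    specs.append(PairSpec(label=label, type="hydrophobic",
                                          group1=(i,), group2=(j,)))

    # ring stacking
    def rings(res_map):
        out = []
        for rk, res_atoms in res_map.items():
            for cycle in templates.rings_for(rk[2]):
                idx = tuple(i for n in cycle
                            if (i := atom_of(res_atoms, n)) is not None)
                if len(idx) == len(cycle):
                    out.append((rk, idx))
        return out

    for rk1, r1 in rings(dom_res):
        for rk2, r2 in rings(pep_res):
            c1 = coords[list(r1)].mean(axis=0)
            c2 = coords[list(r2)].mean(axis=0)
            if np.linalg.norm(c1 - c2) > _SCAN_MARGIN * criteria.stack_centroid_max:
                continue
            label = (f"{_res_label(traj, rk1[0], rk1[1], positions)}-"
                     f"{_res_label(traj, rk2[0], rk2[1], positions)} stacking")
            specs.append(PairSpec(label=label, type="stacking",
                                  group1=r1, group2=r2))

    order = {"hbond": 0, "salt_bridge": 1, "hydrophobic": 2, "stacking": 3}
    specs.sort(key=lambda s: (order[s.type], s.group1, s.group2))
    return specs


def _parse_atom_addr(traj: Trajectory, addr: str) -> int:
    chain, res, name = addr.split(":")
    return traj.atom_index(chain, int(res), name)


def _pairs_from_config(traj: Trajectory, pair_dicts: list[dict]) -> list[PairSpec]:
    specs = []
    for d in pair_dicts:
        specs.append(PairSpec(
            label=d["label"], type=d["type"],
            group1=tuple(_parse_atom_addr(traj, a) for a in d["atoms1"]),
            group2=tuple(_parse_atom_addr(traj, a) for a in d["atoms2"]),
            hydrogen=(_parse_atom_addr(traj, d["hydrogen"])
                      if d.get("hydrogen") else None)))
    return specs


def run(config: RunConfig) -> AnalysisReport:
    """Execute the configured stages and write artifacts to the output dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(config_echo=config.to_dict(), versions=_versions())
    criteria = InteractionCriteria.from_dict(config.criteria) \
        if config.criteria else InteractionCriteria()

    traj = None
    if config.ensemble_pdb:
        try:
            traj = read_multimodel_pdb(config.ensemble_pdb)
            start, stop, stride = config.frame_range
            traj = traj.slice_frames(start, stop, stride)
            log.info("loaded %d frames x %d atoms", traj.n_frames, traj.n_atoms)
        except Exception as exc:
            raise StageError("io", str(exc)) from exc

    if traj is not None:
        try:
            fit_sel = Selection.from_dict(config.fit_selection) \
                if config.fit_selection else Selection(atom_names=("CA",))
            ana_sel = Selection.from_dict(config.analysis_selection) \
                if config.analysis_selection else fit_sel
            rser = rmsd_series(traj, fit_sel, ana_sel, reference_frame=0)
            report.rmsd = pd.DataFrame(
                {"frame": np.arange(traj.n_frames), "rmsd_A": rser.values})
            report.rmsd.to_csv(outdir / "rmsd.tsv", sep="\t", index=False)

            if traj.n_frames >= 2:
                rmsf_sel = Selection.from_dict(config.rmsf_selection) \
                    if config.rmsf_selection else Selection(atom_names=("CA",))
                prof = rmsf_profile(traj, rmsf_sel,
                                    reference_mode=config.rmsf_reference_mode)
                report.rmsf = pd.DataFrame(
                    [{"chain": c, "res_seq": r, "rmsf_A": v}
                     for (c, r), v in sorted(prof.values.items())])
                report.rmsf.to_csv(outdir / "rmsf.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("descriptors", str(exc)) from exc

        try:
            specs = _pairs_from_config(traj, config.pairs)
            if config.auto_scan:
                if not config.peptide_chain:
                    raise ConfigError("auto_scan requires peptide_chain")
                known = {s.label for s in specs}
                specs += [s for s in auto_scan_pairs(
                    traj, config.peptide_chain, criteria,
                    charged_his=config.charged_his,
                    hbond_mode=config.hbond_mode) if s.label not in known]
            if specs:
                mode = config.hbond_mode
                if mode == "auto":
                    mode = ("with_hydrogens" if _topology_has_hydrogens(traj)
                            else "heavy_only")
                records = occupancy_table(traj, specs, criteria,
                                          hbond_mode=mode)
                occ = occupancy_frame(records)
                report.occupancy = occ
                occ.to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
                report.stacking = occ[occ["type"] == "stacking"].reset_index(drop=True)
                report.stacking.to_csv(outdir / "stacking.tsv", sep="\t",
                                       index=False)
                wanted = set(config.series_pairs)
                for spec in specs:
                    if spec.label in wanted:
                        ts = distance_series(traj, spec)
                        report.series[spec.label] = ts
                        safe = "".join(ch if ch.isalnum() else "_"
                                       for ch in spec.label)
                        ts.to_csv(outdir / f"series_{safe}.tsv", sep="\t",
                                  index=False)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("interactions", str(exc)) from exc

    if config.titration_csv:
        try:
            curves = read_titration_csv(config.titration_csv,
                                        ligand_total_uM=config.ligand_total_uM)
            fit = fit_isotherm(curves)
            fd = {"kd_uM": fit.kd_uM, "kd_se_uM": fit.kd_se * 1e6,
                  "a0": fit.a0, "am": fit.am, "a0_se": fit.a0_se,
                  "am_se": fit.am_se, "rss": fit.rss,
                  "n_points": fit.n_points, "converged": fit.converged,
                  "identifiable": fit.identifiable,
                  "saturation_reached": fit.saturation_reached}
            report.binding_fits.append(fd)
            if not fit.identifiable:
                report.warnings.append("binding fit not identifiable (flat curve?)")
            if not fit.saturation_reached:
                report.warnings.append("saturation not approached: max [P] < Kd")
            with open(outdir / "binding_fits.json", "w") as fh:
                json.dump(report.binding_fits, fh, indent=1)
        except Exception as exc:
            raise StageError("binding", str(exc)) from exc

    if config.thermo_csv:
        try:
            records = read_thermo_csv(config.thermo_csv)
            rows = []
            for r in records:
                rows.append({
                    "label": r.label, "kd_uM": r.kd * 1e6, "dH_kcal_mol": r.dh,
                    "T_K": r.t, "n": r.n,
                    "dG_kcal_mol": r.dg_computed, "dS_cal_mol_K": r.ds_computed,
                    "dG_supplied": r.dg_supplied, "dS_supplied": r.ds_supplied,
                    "dG_discrepant": r.dg_discrepant})
            report.thermo = pd.DataFrame(rows)
            report.thermo.to_csv(outdir / "thermo.tsv", sep="\t", index=False)
            ref_label = config.thermo_reference_label
            if ref_label is not None:
                ref = next((r for r in records if r.label == ref_label), None)
                if ref is None:
                    raise ConfigError(f"reference label {ref_label!r} not in "
                                      "thermo records")
                dd_rows = []
                for r in records:
                    if r.label == ref.label:
                        continue
                    dd = delta_delta(r, ref)
                    dd_rows.append({"mutant": dd.mutant, "reference": dd.reference,
                                    "ddG_kcal_mol": dd.ddg, "ddH_kcal_mol": dd.ddh,
                                    "ddS_cal_mol_K": dd.dds, "T_K": dd.t})
                report.delta_delta = pd.DataFrame(dd_rows)
                report.delta_delta.to_csv(outdir / "delta_delta.tsv", sep="\t",
                                          index=False)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("thermo", str(exc)) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report.payload(), fh, indent=1, sort_keys=True)
    _write_summary(report, outdir / "summary.txt")
    return report


def _write_summary(report: AnalysisReport, path: Path) -> None:
    lines = ["pdzbind analysis summary", "========================"]
    if report.rmsd is not None:
        lines.append(f"RMSD: mean {report.rmsd['rmsd_A'].mean():.2f} A over "
                     f"{len(report.rmsd)} frames")
    if report.rmsf is not None:
        lines.append(f"RMSF: {len(report.rmsf)} residues, max "
                     f"{report.rmsf['rmsf_A'].max():.2f} A")
    if report.occupancy is not None:
        stable = int(report.occupancy["stable"].sum())
        lines.append(f"interactions: {len(report.occupancy)} candidate pairs, "
                     f"{stable} stable")
    for f in report.binding_fits:
        lines.append(f"FP fit: Kd = {f['kd_uM']:.3g} uM "
                     f"(A0 {f['a0']:.3f}, Am {f['am']:.3f})")
    if report.thermo is not None:
        lines.append(f"thermo: {len(report.thermo)} records")
    if report.delta_delta is not None:
        for _, row in report.delta_delta.iterrows():
            lines.append(f"  ddG({row['mutant']} - {row['reference']}) = "
                         f"{row['ddG_kcal_mol']:.2f} kcal/mol")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    path.write_text("\n".join(lines) + "\n")
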