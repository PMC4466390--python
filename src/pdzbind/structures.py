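"""Multi-model PDB ensembles: atom records, trajectories, selections.

The interchange format for structural ensembles is the multi-model PDB
file (MODEL/ENDMDL-delimited, fixed columns per the v3.3 ATOM record).
A :class:`Trajectory` holds one shared topology (the ordered atom list)
plus an ``(n_frames, n_atoms, 3)`` coordinate array; every geometric
operation in the package consumes trajectories and atom-index selections.

Peptide ligand residues follow the PDZ-field convention of being numbered
backwards from zero at the carboxy terminus (0, -1, -2, ...);
:func:`peptide_positions` maps author residue numbers onto that scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import PdbFormatError, PdbParseError, SelectionError, TopologyError

__all__ = [
    "AtomRecord",
    "StructureFrame",
    "Trajectory",
    "Selection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "resolve_selection",
    "peptide_positions",
]

_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model: identity plus Cartesian coordinates in Å."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: tuple[float, float, float]

    @property
    def key(self) -> tuple[str, int, str]:
        """Topology identity: (chain_id, res_seq, name)."""
        return (self.chain_id, self.res_seq, self.name)

    def __post_init__(self):
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinate for atom {self.key}")


@dataclass(frozen=True)
class StructureFrame:
    """One model of an ensemble: frame ordinal plus its ordered atoms."""

    index: int
    atoms: tuple[AtomRecord, ...]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


class Trajectory:
    """An ordered ensemble of models sharing one topology.

    Parameters
    ----------
    atoms
        Template atom records (coordinates taken as frame 0 if no
        ``coords`` given). Order defines topology order.
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    """

    def __init__(self, atoms: Sequence[AtomRecord], coords: np.ndarray):
        atoms = tuple(atoms)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if coords.shape[1] != len(atoms):
            raise ValueError("coords second axis must match the atom count")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in trajectory")
        keys = [a.key for a in atoms]
        if len(set(keys)) != len(keys):
            raise TopologyError("duplicate (chain, res_seq, name) in topology")
        self.atoms = atoms
        self.coords = coords

    # -- basic introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def topology_keys(self) -> list[tuple[str, int, str]]:
        return [a.key for a in self.atoms]

    @property
    def topology_hash(self) -> str:
        h = hashlib.sha256()
        for k in self.topology_keys:
            h.update(repr(k).encode())
        return h.hexdigest()[:16]

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def frame(self, i: int) -> StructureFrame:
        xyz = self.coords[i]
        atoms = tuple(
            AtomRecord(a.serial, a.name, a.element, a.res_name, a.res_seq,
                       a.chain_id, (float(x), float(y), float(z)))
            for a, (x, y, z) in zip(self.atoms, xyz)
        )
        return StructureFrame(index=i, atoms=atoms)

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        key = (chain_id, res_seq, name)
        try:
            return self._index_map[key]
        except AttributeError:
            self._index_map = {a.key: i for i, a in enumerate(self.atoms)}
            return self.atom_index(chain_id, res_seq, name)
        except KeyError:
            raise LookupError(f"atom {key} not in topology") from None

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, res_seq, res_name) tuples."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            seen.setdefault((a.chain_id, a.res_seq), a.res_name)
        return [(c, r, n) for (c, r), n in seen.items()]

    def slice_frames(self, start: int = 0, stop: int | None = None,
                     stride: int = 1) -> "Trajectory":
        """Half-open, 0-based frame window [start, stop) with stride >= 1."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        sub = self.coords[start:stop:stride]
        if sub.shape[0] == 0:
            raise ValueError("frame range selects no frames")
        return Trajectory(self.atoms, sub.copy())


@dataclass(frozen=True)
class Selection:
    """Declarative atom filter: chain, inclusive residue range, atom names.

    All fields optional; ``None`` means "no constraint". Residue ranges are
    inclusive at both ends to match the field's "residues 13-91" phrasing.
    """

    chain_id: str | None = None
    res_first: int | None = None
    res_last: int | None = None
    atom_names: tuple[str, ...] | None = None

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.res_first is not None and atom.res_seq < self.res_first:
            return False
        if self.res_last is not None and atom.res_seq > self.res_last:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True

    @classmethod
    def from_dict(cls, d: dict) -> "Selection":
        names = d.get("atom_names")
        return cls(
            chain_id=d.get("chain"),
            res_first=d.get("res_first"),
            res_last=d.get("res_last"),
            atom_names=tuple(names) if names is not None else None,
        )


def resolve_selection(traj: Trajectory, selection: Selection) -> list[int]:
    """Atom indices matching ``selection``, in topology order.

    Pure function of (topology, selection); an empty result is allowed.
    """
    return [i for i, a in enumerate(traj.atoms) if selection.matches(a)]


def require_selection(traj: Trajectory, selection: Selection,
                      what: str = "selection") -> list[int]:
    idx = resolve_selection(traj, selection)
    if not idx:
        raise SelectionError(f"{what} resolved to no atoms: {selection}")
    return idx


def peptide_positions(traj: Trajectory, peptide_chain: str) -> dict[int, int]:
    """Map author residue numbers of a peptide chain to ligand positions.

    The carboxy-terminal residue (largest res_seq) is position 0; residues
    upstream are -1, -2, ... The returned image is a contiguous interval
    ending at 0 when the chain is contiguously numbered.
    """
    res = [r for c, r, _ in traj.residues(peptide_chain)]
    if not res:
        raise LookupError(f"peptide chain {peptide_chain!r} not in topology")
    top = max(res)
    return {r: r - top for r in sorted(res)}


# ---------------------------------------------------------------------------
# Fixed-column PDB reading/writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    """Parse one ATOM/HETATM line; None when skipped by policy (caller filters
    altloc/water before committing the record)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PdbParseError(
            f"line {lineno}: malformed coordinate record: {line.rstrip()!r} ({exc})"
        ) from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # Fall back on the leading letter of the atom name.
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else "X"
    return AtomRecord(serial, name, element, res_name, res_seq, chain_id,
                      (x, y, z))


def read_multimodel_pdb(path, altloc_policy: str = "A",
                        drop_waters: bool = True) -> Trajectory:
    """Read a MODEL/ENDMDL-delimited (or single implicit model) PDB file.

    Alternate locations are resolved by keeping atoms whose altloc field is
    blank or equals ``altloc_policy``. Insertion codes are ignored. Water
    residues are dropped unless ``drop_waters`` is False. Every model must
    present the identical (chain, res_seq, name) sequence; a mismatch raises
    :class:`TopologyError` naming the offending frame.
    """
    frames: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model_record = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                if in_model:
                    raise PdbParseError(f"line {lineno}: nested MODEL record")
                in_model = True
                current = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise PdbParseError(f"line {lineno}: ENDMDL without MODEL")
                frames.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                altloc = line[16] if len(line) > 16 else " "
                if altloc not in (" ", altloc_policy):
                    continue
                atom = _parse_atom_line(line, lineno)
                if drop_waters and atom.res_name in _WATER_RESNAMES:
                    continue
                current.append(atom)

    if saw_model_record:
        if in_model:  # MODEL without closing ENDMDL: accept trailing model
            frames.append(current)
    else:
        frames = [current]

    frames = [f for f in frames if f] or [[]]
    if not frames[0]:
        raise PdbParseError(f"{path}: no ATOM/HETATM records found")

    ref_keys = [a.key for a in frames[0]]
    coords = np.empty((len(frames), len(ref_keys), 3), dtype=float)
    for fi, frame_atoms in enumerate(frames):
        keys = [a.key for a in frame_atoms]
        if keys != ref_keys:
            raise TopologyError(
                f"frame {fi}: atom list differs from frame 0 "
                f"({len(keys)} vs {len(ref_keys)} atoms)"
            )
        coords[fi] = [a.xyz for a in frame_atoms]
    return Trajectory(frames[0], coords)


def _format_atom_name(name: str, element: str) -> str:
    # Names of <=3 chars for 1-letter elements start in column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write ``traj`` as a standard multi-model PDB file.

    One MODEL/ENDMDL block per frame, %8.3f coordinates, TER after each
    chain, END at end of file.
    """
    if traj.n_atoms == 0:
        raise PdbFormatError("trajectory has no atoms")
    if np.any(traj.coords >= 10000.0) or np.any(traj.coords <= -1000.0):
        raise PdbFormatError("coordinate magnitude does not fit the 8.3 field")

    lines: list[str] = []
    for fi in range(traj.n_frames):
        lines.append(f"MODEL     {fi + 1:4d}")
        prev_chain = None
        last_atom = None
        for a, (x, y, z) in zip(traj.atoms, traj.coords[fi]):
            if prev_chain is not None and a.chain_id != prev_chain:
                lines.append(_ter_line(last_atom))
            lines.append(
                "ATOM  {serial:5d} {name} {res:<3s} {chain}{seq:4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                "{elem:>2s}".format(
                    serial=a.serial % 100000,
                    name=_format_atom_name(a.name, a.element),
                    res=a.res_name[:3],
                    chain=a.chain_id[:1],
                    seq=a.res_seq % 10000,
                    x=x, y=y, z=z, occ=1.0, b=0.0,
                    elem=a.element[:2],
                )
            )
            prev_chain = a.chain_id
            last_atom = a
        lines.append(_ter_line(last_atom))
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _ter_line(atom: AtomRecord | None) -> str:
    if atom is None:
        return "TER"
    return "TER   {serial:5d}      {res:<3s} {chain}{seq:4d}".format(
        serial=(atom.serial + 1) % 100000, res=atom.res_name[:3],
        chain=atom.chain_id[:1], seq=atom.res_seq % 10000)
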