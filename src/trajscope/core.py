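"""Domain types and I/O for structures and trajectories.

Coordinates are stored internally in angstroms (Å).  Residues carry a dual
numbering: a 1-based sequence index (contiguous within a chain) and the
author residue number from the PDB `resSeq` column; the two are related by a
per-chain constant offset.  Selections, profiles and network node labels are
always reported in author numbering.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Bondi (1964) van der Waals radii, Å.  Unknown elements fall back to
# _DEFAULT_VDW with a logged warning.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "NA": 2.27, "K": 2.75, "MG": 1.73,
    "CA": 2.31, "FE": 2.05, "CU": 1.40,
}
_DEFAULT_VDW = 1.70

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971, "ZN": 65.38, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "FE": 55.845, "CU": 63.546,
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "SE", "ZN", "NA", "MG", "FE", "CU"}

WATER_RESNAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "T3P"}

BACKBONE_NAMES = ("N", "CA", "C", "O")


class EmptyStructureError(ValueError):
    """No atoms survive parsing/filtering."""


class TopologyMismatchError(ValueError):
    """Frame atom count disagrees with the topology."""


class SelectionError(ValueError):
    """Selection expression invalid or matched nothing."""


@dataclass
class Atom:
    """A single atom with PDB-style metadata and coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_index: int      # 1-based sequence position within the chain
    author_resid: int       # PDB resSeq
    chain: str
    coords: np.ndarray      # shape (3,), Å
    mass: float = 0.0
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        key = self.element.upper()
        if self.mass <= 0:
            self.mass = ATOMIC_MASSES.get(key, 12.011)
        if self.vdw_radius <= 0:
            if key not in VDW_RADII:
                logger.warning("unknown element %r: using vdW radius %.2f Å",
                               self.element, _DEFAULT_VDW)
            self.vdw_radius = VDW_RADII.get(key, _DEFAULT_VDW)


@dataclass
class Structure:
    """An ordered collection of atoms grouped into residues.

    ``residues`` holds one ``(residue_index, author_resid, resname, chain)``
    tuple per residue, in chain order.
    """

    atoms: list[Atom]
    residues: list[tuple[int, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            self.residues = self._derive_residues()
        self._validate()

    def _derive_residues(self) -> list[tuple[int, int, str, str]]:
        out, seen = [], set()
        for a in self.atoms:
            key = (a.chain, a.residue_index)
            if key not in seen:
                seen.add(key)
                out.append((a.residue_index, a.author_resid, "UNK", a.chain))
        return out

    def _validate(self) -> None:
        per_chain: dict[str, int] = {}
        for ridx, author, _name, chain in self.residues:
            prev = per_chain.get(chain)
            if prev is not None and ridx <= prev:
                raise ValueError("residue_index must strictly increase within a chain")
            per_chain[chain] = ridx
        offsets: dict[str, int] = {}
        for ridx, author, _name, chain in self.residues:
            off = author - ridx
            if chain in offsets and offsets[chain] != off:
                raise ValueError(
                    f"inconsistent numbering offset in chain {chain!r}: "
                    f"{offsets[chain]} vs {off}")
            offsets[chain] = off
        self._offsets = offsets
        res_keys = {(c, i) for i, _a, _n, c in self.residues}
        for a in self.atoms:
            if (a.chain, a.residue_index) not in res_keys:
                raise ValueError(f"atom {a.serial} maps to no residue")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def numbering_offset(self, chain: str | None = None) -> int:
        """Author-number minus sequence-index offset for ``chain``."""
        if chain is None:
            chain = self.residues[0][3]
        return self._offsets[chain]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atom_masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def atom_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def residue_of_atom(self, atom_pos: int) -> tuple[int, int, str, str]:
        a = self.atoms[atom_pos]
        for r in self.residues:
            if r[0] == a.residue_index and r[3] == a.chain:
                return r
        raise KeyError(atom_pos)

    def residue_label(self, residue: tuple[int, int, str, str]) -> str:
        _idx, author, name, chain = residue
        return f"{chain}:{name}:{author}"


@dataclass
class AtomSelection:
    """Ordered, duplicate-free 0-based atom positions into a Structure."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise SelectionError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Trajectory:
    """Topology plus ordered coordinate frames, Å.

    ``frames`` has shape (n_frames, n_atoms, 3); ``frame_times`` (ns) is
    optional and must be strictly increasing when present.
    """

    topology: Structure
    frames: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"frames carry {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}")
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != self.frames.shape[0] or np.any(np.diff(t) <= 0):
                raise ValueError("frame_times must match n_frames and strictly increase")
            self.frame_times = t

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM/HETATM records; MODEL/ENDMDL for trajectories)
# ---------------------------------------------------------------------------

def infer_element(atom_name: str, resname: str = "") -> str:
    """Element from a PDB atom-name field when columns 77-78 are absent.

    The raw 4-character name field is used when available: a name starting
    in column 13 (no leading space) whose first two letters form a known
    two-letter element symbol is taken as that element (e.g. ``FE``), while
    left-padded names like ``" CA "`` are single-letter elements (Cα carbon).
    """
    raw = atom_name
    stripped = raw.strip()
    if not stripped:
        raise ValueError("empty atom name")
    letters = re.sub(r"[^A-Za-z]", "", stripped).upper()
    if len(raw) >= 2 and raw[0] not in (" ", "") and letters[:2] in _TWO_LETTER_ELEMENTS:
        return letters[:2].capitalize()
    if len(raw) == len(stripped) and letters[:2] in _TWO_LETTER_ELEMENTS and stripped[0].isalpha() and len(stripped) == 2:
        return letters[:2].capitalize()
    return letters[0]


def _parse_atom_line(line: str) -> dict:
    name = line[12:16]
    resname = line[17:20].strip() or "UNK"
    chain = line[21].strip() or "A"
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name, resname)
    return {
        "serial": int(line[6:11]),
        "name": name.strip(),
        "raw_name": name,
        "resname": resname,
        "chain": chain,
        "author_resid": int(line[22:26]),
        "x": float(line[30:38]),
        "y": float(line[38:46]),
        "z": float(line[46:54]),
        "element": element.capitalize(),
        "het": line.startswith("HETATM"),
    }


def read_pdb(path: str | Path, include_hetero: bool = False,
             include_waters: bool = False) -> Structure:
    """Read a (single-model) PDB file into a Structure.

    Waters and hetero groups are excluded by default.  If the file holds
    multiple MODEL blocks only the first is read; use :func:`read_trajectory`
    for the full set.
    """
    path = Path(path)
    records = []
    in_model = 0
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    for line in text.splitlines():
        if line.startswith("MODEL"):
            in_model += 1
            if in_model > 1:
                break
        elif line.startswith("ENDMDL") and in_model:
            break
        elif line.startswith(("ATOM  ", "HETATM")):
            rec = _parse_atom_line(line)
            if rec["resname"] in WATER_RESNAMES and not include_waters:
                continue
            if rec["het"] and not include_hetero and rec["resname"] not in WATER_RESNAMES:
                continue
            records.append(rec)
    if not records:
        raise EmptyStructureError(f"no atoms in {path} after filtering")
    return _records_to_structure(records)


def _records_to_structure(records: list[dict]) -> Structure:
    atoms: list[Atom] = []
    residues: list[tuple[int, int, str, str]] = []
    seq_index: dict[str, int] = {}
    current: dict[str, int | None] = {}
    for rec in records:
        chain = rec["chain"]
        if current.get(chain) != rec["author_resid"]:
            seq_index[chain] = seq_index.get(chain, 0) + 1
            current[chain] = rec["author_resid"]
            residues.append((seq_index[chain], rec["author_resid"],
                             rec["resname"], chain))
        atoms.append(Atom(
            serial=rec["serial"], name=rec["name"], element=rec["element"],
            residue_index=seq_index[chain], author_resid=rec["author_resid"],
            chain=chain, coords=np.array([rec["x"], rec["y"], rec["z"]]),
        ))
    return Structure(atoms=atoms, residues=residues)


def read_trajectory(traj_path: str | Path, topology: Structure | None = None,
                    stride: int = 1) -> Trajectory:
    """Read a multi-model PDB or a DCD file as a Trajectory.

    For DCD a ``topology`` Structure is required (DCD stores no atom
    metadata); for multi-model PDB the topology is taken from the first
    model unless one is supplied.  Frames are strided by ``stride``,
    keeping models 1, 1+stride, ...
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    traj_path = Path(traj_path)
    if traj_path.suffix.lower() == ".dcd":
        if topology is None:
            raise ValueError("DCD trajectories require a topology Structure")
        frames = _read_dcd_frames(traj_path)
    else:
        frames, first_model = _read_multimodel_pdb(traj_path)
        if topology is None:
            topology = first_model
    frames = frames[::stride]
    if frames.shape[0] == 0:
        raise ValueError(f"no frames read from {traj_path}")
    if frames.shape[1] != topology.n_atoms:
        raise TopologyMismatchError(
            f"trajectory atoms ({frames.shape[1]}) != topology atoms "
            f"({topology.n_atoms})")
    return Trajectory(topology=topology, frames=frames)


def _read_multimodel_pdb(path: Path) -> tuple[np.ndarray, Structure]:
    models: list[list[dict]] = []
    current: list[dict] | None = None
    saw_model_kw = False
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            saw_model_kw = True
            current = []
        elif line.startswith("ENDMDL"):
            if current:
                models.append(current)
            current = None
        elif line.startswith(("ATOM  ", "HETATM")):
            rec = _parse_atom_line(line)
            if rec["resname"] in WATER_RESNAMES or (rec["het"] and rec["resname"] not in WATER_RESNAMES):
                continue
            if current is None:
                if saw_model_kw:
                    continue
                current = []
            current.append(rec)
    if current:
        models.append(current)
    if not models:
        raise EmptyStructureError(f"no models with atoms in {path}")
    n_atoms = len(models[0])
    for k, m in enumerate(models):
        if len(m) != n_atoms:
            raise TopologyMismatchError(
                f"model {k + 1} has {len(m)} atoms, expected {n_atoms}")
    topo = _records_to_structure(models[0])
    frames = np.array([[[r["x"], r["y"], r["z"]] for r in m] for m in models])
    return frames, topo


def _read_dcd_frames(path: Path) -> np.ndarray:
    # X-PLOR/CHARMM-style DCD, coordinates in Å.
    from MDAnalysis.lib.formats.libdcd import DCDFile

    frames = []
    with DCDFile(str(path)) as dcd:
        for ts in dcd:
            frames.append(np.array(ts.xyz, dtype=float))
    if not frames:
        raise ValueError(f"no frames in DCD {path}")
    return np.stack(frames)


def _format_atom_line(atom: Atom, resname: str, xyz: np.ndarray,
                      serial: int) -> str:
    name = atom.name
    # PDB atom-name justification: 1-3 char names of 1-letter elements are
    # left-padded into column 14.
    if len(name) < 4 and len(atom.element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (f"ATOM  {serial:5d} {name_field} {resname:>3s} {atom.chain:1s}"
            f"{atom.author_resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element.upper():>2s}")


def write_structure(structure: Structure, frame: np.ndarray | None,
                    path: str | Path) -> None:
    """Write one coordinate frame of ``structure`` as a single-model PDB.

    ``frame=None`` writes the structure's own coordinates.  Round-tripping
    through :func:`read_pdb` reproduces coordinates to 0.001 Å (the PDB
    fixed-column precision).
    """
    if frame is None:
        frame = structure.coords
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (structure.n_atoms, 3):
        raise ValueError(
            f"frame shape {frame.shape} does not match {structure.n_atoms} atoms")
    resname_of = {(r[3], r[0]): r[2] for r in structure.residues}
    lines = []
    for i, atom in enumerate(structure.atoms):
        resname = resname_of[(atom.chain, atom.residue_index)]
        lines.append(_format_atom_line(atom, resname, frame[i], i + 1))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB."""
    structure = traj.topology
    resname_of = {(r[3], r[0]): r[2] for r in structure.residues}
    lines = []
    for m in range(traj.n_frames):
        lines.append(f"MODEL     {m + 1:4d}")
        for i, atom in enumerate(structure.atoms):
            resname = resname_of[(atom.chain, atom.residue_index)]
            lines.append(_format_atom_line(atom, resname, traj.frames[m, i], i + 1))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?::(-?\d+))?$")


def _parse_range(token: str) -> tuple[int, int]:
    m = _RANGE_RE.match(token)
    if not m:
        raise SelectionError(f"bad residue range {token!r}")
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    if hi < lo:
        raise SelectionError(f"empty range {token!r}")
    return lo, hi


def select_atoms(structure: Structure, expression: str) -> AtomSelection:
    """Select atoms with a small expression language.

    Clauses joined by ``and``:

    * ``name CA`` / ``name N CA C`` — atom names
    * ``backbone`` — shorthand for ``name N CA C O``
    * ``resid 37:47`` — author residue numbers (inclusive range or single)
    * ``index 17:27`` — 1-based sequence indices
    * ``chain A`` — chain identifiers

    Selection is deterministic and preserves file order.
    """
    expr = expression.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    mask = np.ones(structure.n_atoms, dtype=bool)
    for clause in re.split(r"\s+and\s+", expr):
        tokens = clause.split()
        if not tokens:
            raise SelectionError(f"empty clause in {expression!r}")
        kw, args = tokens[0].lower(), tokens[1:]
        if kw == "backbone":
            if args:
                raise SelectionError("'backbone' takes no arguments")
            names = set(BACKBONE_NAMES)
            mask &= np.array([a.name in names for a in structure.atoms])
        elif kw == "name":
            if not args:
                raise SelectionError("'name' needs at least one atom name")
            names = {t.upper() for t in args}
            mask &= np.array([a.name.upper() in names for a in structure.atoms])
        elif kw in ("resid", "index"):
            if not args:
                raise SelectionError(f"'{kw}' needs a range")
            sub = np.zeros(structure.n_atoms, dtype=bool)
            for tok in args:
                lo, hi = _parse_range(tok)
                if kw == "resid":
                    sub |= np.array([lo <= a.author_resid <= hi
                                     for a in structure.atoms])
                else:
                    sub |= np.array([lo <= a.residue_index <= hi
                                     for a in structure.atoms])
            mask &= sub
        elif kw == "chain":
            if not args:
                raise SelectionError("'chain' needs a chain id")
            chains = set(args)
            mask &= np.array([a.chain in chains for a in structure.atoms])
        else:
            raise SelectionError(f"unknown selection keyword {kw!r}")
    indices = np.nonzero(mask)[0]
    if len(indices) == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return AtomSelection(indices=indices, label=expression)
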