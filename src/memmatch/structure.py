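"""Domain types for molecular structures plus PDB/GRO readers and writers.

All internal coordinates are in Angstrom; GRO files (nm) are converted on the
way in and out.  Multi-model PDB files (MODEL/ENDMDL) and concatenated GRO
blocks map to multi-frame trajectories.
"""
from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._elements import element_from_name, mass_of

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "DimerTopology",
    "ParseError",
    "TopologyError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "select",
]

HYDROPHOBIC = frozenset("AVLIFMGT")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class ParseError(ValueError):
    """A malformed record in a structure file; message names the line."""


class TopologyError(ValueError):
    """Frames of one trajectory disagree on atom metadata."""


class SelectionError(ValueError):
    """Malformed selection expression."""


@dataclass
class Atom:
    """A single atom with metadata and a position in Angstrom."""

    name: str
    element: str
    residue_index: int  # 0-based within its chain
    residue_name: str
    chain_id: str
    position: np.ndarray
    mass: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.mass == 0.0:
            self.mass = mass_of(self.element)
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")


@dataclass
class Frame:
    """One coordinate snapshot: ordered atoms, periodic box (Angstrom), time (ps)."""

    atoms: list[Atom]
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be a positive 3-vector")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def with_positions(self, positions: np.ndarray, time: float | None = None) -> "Frame":
        """New frame sharing atom metadata but with replaced coordinates."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("positions shape mismatch")
        atoms = [replace(a, position=positions[i]) for i, a in enumerate(self.atoms)]
        return Frame(atoms=atoms, box=self.box.copy(),
                     time=self.time if time is None else time)

    def topology_hash(self) -> str:
        h = hashlib.sha1()
        for a in self.atoms:
            h.update(f"{a.name}|{a.element}|{a.residue_index}|{a.residue_name}|{a.chain_id};".encode())
        return h.hexdigest()


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    frames: list[Frame]
    topology_hash: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        if not self.topology_hash:
            self.topology_hash = self.frames[0].topology_hash()
        for i, fr in enumerate(self.frames):
            if fr.topology_hash() != self.topology_hash:
                raise TopologyError(f"frame {i} does not match trajectory topology")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coordinates(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """(n_frames, k, 3) stack of coordinates for the given atom indices."""
        if indices is None:
            return np.stack([f.positions for f in self.frames])
        idx = np.asarray(indices, dtype=int)
        return np.stack([f.positions[idx] for f in self.frames])


MOTIF_LENGTH = 9  # G V x x G V x x T
MOTIF_CONSERVED = {0: "G", 1: "V", 4: "G", 5: "V", 8: "T"}


def find_motif(sequence: str) -> int:
    """0-based index of the first GVxxGVxxT motif (x hydrophobic) in *sequence*."""
    for i in range(len(sequence) - MOTIF_LENGTH + 1):
        window = sequence[i:i + MOTIF_LENGTH]
        if all(window[k] == aa for k, aa in MOTIF_CONSERVED.items()) and all(
            c in HYDROPHOBIC for c in window
        ):
            return i
    raise ValueError(f"no GVxxGVxxT motif found in {sequence!r}")


@dataclass(frozen=True)
class DimerTopology:
    """The two peptide chains of a dimer and their dimerization-motif anchors."""

    chain_a_id: str
    chain_b_id: str
    sequence_a: str
    sequence_b: str
    motif_start_a: int
    motif_start_b: int

    def __post_init__(self) -> None:
        for seq, start, label in (
            (self.sequence_a, self.motif_start_a, "A"),
            (self.sequence_b, self.motif_start_b, "B"),
        ):
            if start < 4:
                raise ValueError(f"chain {label}: motif_start must be >= 4")
            if start + MOTIF_LENGTH - 1 > len(seq) - 5:
                raise ValueError(
                    f"chain {label}: motif end must leave at least 4 trailing residues"
                )
            window = seq[start:start + MOTIF_LENGTH]
            if len(window) < MOTIF_LENGTH:
                raise ValueError(f"chain {label}: motif window out of bounds")
            for k, aa in MOTIF_CONSERVED.items():
                if window[k] != aa:
                    raise ValueError(
                        f"chain {label}: motif position {k} is {window[k]!r}, expected {aa!r}"
                    )
            for k in (2, 3, 6, 7):
                if window[k] not in HYDROPHOBIC:
                    raise ValueError(
                        f"chain {label}: motif x-position {k} ({window[k]!r}) not hydrophobic"
                    )

    def motif_span(self, chain: str) -> range:
        """Residue indices covered by the 9-residue motif of *chain* ('A'/'B' role or id)."""
        start = self._start_for(chain)
        return range(start, start + MOTIF_LENGTH)

    def _start_for(self, chain: str) -> int:
        if chain in (self.chain_a_id, "A"):
            return self.motif_start_a
        if chain in (self.chain_b_id, "B"):
            return self.motif_start_b
        raise KeyError(f"unknown chain {chain!r}")

    @property
    def chain_ids(self) -> tuple[str, str]:
        return (self.chain_a_id, self.chain_b_id)

    def swapped(self) -> "DimerTopology":
        return DimerTopology(
            chain_a_id=self.chain_b_id, chain_b_id=self.chain_a_id,
            sequence_a=self.sequence_b, sequence_b=self.sequence_a,
            motif_start_a=self.motif_start_b, motif_start_b=self.motif_start_a,
        )


# ----------------------------------------------------------------------------
# Readers
# ----------------------------------------------------------------------------

def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "ent"):
        return "pdb"
    if suffix == "gro":
        return "gro"
    raise ValueError(f"cannot resolve format from extension of {path}")


def read_structure(path: str | Path, format: str = "auto",
                   chain_map: dict[str, tuple[int, int]] | None = None) -> Trajectory:
    """Read a PDB or GRO file into a Trajectory (coordinates in Angstrom).

    Parameters
    ----------
    path : file path
    format : 'pdb', 'gro' or 'auto' (resolved from the extension)
    chain_map : optional {chain_id: (first, last)} mapping of global 0-based
        residue ordinals to chain labels, used for chain-less formats (GRO).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "gro":
        return _read_gro(path, chain_map)
    raise ValueError(f"unsupported format {fmt!r}")


def _read_pdb(path: Path) -> Trajectory:
    frames: list[Frame] = []
    atoms: list[Atom] = []
    box = None
    chain_res_map: dict[tuple[str, int], int] = {}
    chain_counts: dict[str, int] = {}
    in_model = False
    n_expected: int | None = None

    def finish_frame(lineno: int) -> None:
        nonlocal atoms, chain_res_map, chain_counts, n_expected
        if not atoms:
            return
        nonlocal frames
        b = box if box is not None else _box_from_extent(atoms)
        frames.append(Frame(atoms=atoms, box=b, time=float(len(frames))))
        if n_expected is None:
            n_expected = len(atoms)
        elif len(atoms) != n_expected:
            raise TopologyError(
                f"{path}:{lineno}: model has {len(atoms)} atoms, expected {n_expected}"
            )
        atoms = []
        chain_res_map = {}
        chain_counts = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]),
                                    float(line[24:33])])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad CRYST1 record") from exc
            elif rec == "MODEL ":
                in_model = True
            elif rec == "ENDMDL":
                finish_frame(lineno)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    chain = line[21].strip() or "A"
                    resseq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed ATOM record") from exc
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = element_from_name(name)
                key = (chain, resseq)
                if key not in chain_res_map:
                    chain_res_map[key] = chain_counts.get(chain, 0)
                    chain_counts[chain] = chain_res_map[key] + 1
                atoms.append(Atom(name=name, element=element,
                                  residue_index=chain_res_map[key],
                                  residue_name=resname, chain_id=chain,
                                  position=np.array([x, y, z])))
    finish_frame(lineno if atoms else 0)
    if not frames:
        raise ParseError(f"{path}: no coordinate records found")
    for i, fr in enumerate(frames):
        fr.time = float(i)
    return Trajectory(frames=frames)


def _box_from_extent(atoms: list[Atom]) -> np.ndarray:
    pos = np.array([a.position for a in atoms])
    span = pos.max(axis=0) - pos.min(axis=0)
    return np.maximum(span + 10.0, 1.0)


def _read_gro(path: Path, chain_map: dict[str, tuple[int, int]] | None) -> Trajectory:
    frames: list[Frame] = []
    n_expected: int | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        # title line, atom-count line
        if i + 1 >= len(lines):
            raise ParseError(f"{path}:{i + 1}: truncated GRO block")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 2}: bad atom count") from exc
        start = i + 2
        if start + natoms >= len(lines) + 1 and start + natoms > len(lines):
            raise ParseError(f"{path}:{len(lines)}: truncated GRO block")
        atoms: list[Atom] = []
        res_ordinal: dict[int, int] = {}
        for k in range(natoms):
            lineno = start + k + 1
            line = lines[start + k]
            try:
                resid = int(line[0:5])
                resname = line[5:10].strip()
                name = line[10:15].strip()
                x = float(line[20:28]) * 10.0
                y = float(line[28:36]) * 10.0
                z = float(line[36:44]) * 10.0
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed GRO atom line") from exc
            if resid not in res_ordinal:
                res_ordinal[resid] = len(res_ordinal)
            atoms.append((resid, resname, name, np.array([x, y, z])))  # type: ignore[arg-type]
        try:
            box_fields = [float(v) for v in lines[start + natoms].split()[:3]]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{start + natoms + 1}: malformed box line") from exc
        box = np.array(box_fields) * 10.0
        frame_atoms = _assign_gro_chains(atoms, res_ordinal, chain_map)
        if n_expected is None:
            n_expected = natoms
        elif natoms != n_expected:
            raise TopologyError(
                f"{path}:{lineno}: frame has {natoms} atoms, expected {n_expected}"
            )
        frames.append(Frame(atoms=frame_atoms, box=box, time=float(len(frames))))
        i = start + natoms + 1
    if not frames:
        raise ParseError(f"{path}: no coordinate records found")
    return Trajectory(frames=frames)


def _assign_gro_chains(raw, res_ordinal, chain_map) -> list[Atom]:
    atoms = []
    # per-chain 0-based residue renumbering
    chain_first_ord: dict[str, int] = {}
    for resid, resname, name, pos in raw:
        ordinal = res_ordinal[resid]
        chain = "A"
        if chain_map:
            for cid, (lo, hi) in chain_map.items():
                if lo <= ordinal <= hi:
                    chain = cid
                    break
        if chain not in chain_first_ord:
            chain_first_ord[chain] = ordinal
        atoms.append(Atom(name=name, element=element_from_name(name),
                          residue_index=ordinal - chain_first_ord[chain],
                          residue_name=resname, chain_id=chain, position=pos))
    return atoms


# ----------------------------------------------------------------------------
# Writers
# ----------------------------------------------------------------------------

def write_structure(traj: Trajectory, path: str | Path, format: str = "auto") -> None:
    """Write a trajectory to PDB (multi-model) or GRO (concatenated blocks)."""
    path = Path(path)
    if not traj.frames:
        raise ValueError("no frames")
    fmt = _resolve_format(path, format)
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "gro":
        _write_gro(traj, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def _residue_serials(atoms: Iterable[Atom]) -> list[int]:
    """Global 1-based residue serials in order of appearance."""
    serials = []
    seen: dict[tuple[str, int], int] = {}
    for a in atoms:
        key = (a.chain_id, a.residue_index)
        if key not in seen:
            seen[key] = len(seen) + 1
        serials.append(seen[key])
    return serials


def _write_pdb(traj: Trajectory, path: Path) -> None:
    multi = len(traj.frames) > 1
    with open(path, "w") as fh:
        box = traj.frames[0].box
        fh.write(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for imodel, frame in enumerate(traj.frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for serial, atom in enumerate(frame.atoms, start=1):
                name = atom.name
                # PDB convention: 1-3 letter names start in column 14
                fname = f" {name:<3s}" if len(name) < 4 else name[:4]
                resseq = atom.residue_index + 1
                x, y, z = atom.position
                fh.write(
                    f"ATOM  {serial % 100000:5d} {fname}"
                    f" {atom.residue_name:<3s} {atom.chain_id[0]}{resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_gro(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            serials = _residue_serials(frame.atoms)
            fh.write(f"frame t={frame.time:.3f} ps\n")
            fh.write(f"{frame.n_atoms:5d}\n")
            for i, atom in enumerate(frame.atoms):
                x, y, z = atom.position / 10.0
                fh.write(
                    f"{serials[i] % 100000:5d}{atom.residue_name:<5s}"
                    f"{atom.name:>5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = frame.box / 10.0
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ----------------------------------------------------------------------------
# Selections
# ----------------------------------------------------------------------------

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class _Tokens:
    def __init__(self, text: str):
        self.items = re.findall(r"\(|\)|[^\s()]+", text)
        self.pos = 0

    def peek(self) -> str | None:
        return self.items[self.pos] if self.pos < len(self.items) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok


def _parse_or(tokens: _Tokens, frame: Frame) -> np.ndarray:
    mask = _parse_and(tokens, frame)
    while tokens.peek() == "or":
        tokens.next()
        mask = mask | _parse_and(tokens, frame)
    return mask


def _parse_and(tokens: _Tokens, frame: Frame) -> np.ndarray:
    mask = _parse_unary(tokens, frame)
    while tokens.peek() == "and":
        tokens.next()
        mask = mask & _parse_unary(tokens, frame)
    return mask


def _parse_unary(tokens: _Tokens, frame: Frame) -> np.ndarray:
    tok = tokens.peek()
    if tok == "not":
        tokens.next()
        return ~_parse_unary(tokens, frame)
    if tok == "(":
        tokens.next()
        mask = _parse_or(tokens, frame)
        if tokens.next() != ")":
            raise SelectionError("unbalanced parenthesis in selection")
        return mask
    return _parse_primitive(tokens, frame)


_KEYWORDS = {"name", "chain", "resname", "resid", "backbone", "all",
             "and", "or", "not", "(", ")"}


def _collect_values(tokens: _Tokens) -> list[str]:
    values = []
    while tokens.peek() is not None and tokens.peek() not in _KEYWORDS:
        values.append(tokens.next())
    if not values:
        raise SelectionError("selection keyword expects at least one value")
    return values


def _parse_primitive(tokens: _Tokens, frame: Frame) -> np.ndarray:
    tok = tokens.next()
    n = frame.n_atoms
    if tok == "all":
        return np.ones(n, dtype=bool)
    if tok == "backbone":
        return np.array([a.name in _BACKBONE_NAMES for a in frame.atoms])
    if tok == "name":
        vals = set(_collect_values(tokens))
        return np.array([a.name in vals for a in frame.atoms])
    if tok == "chain":
        vals = set(_collect_values(tokens))
        return np.array([a.chain_id in vals for a in frame.atoms])
    if tok == "resname":
        vals = set(_collect_values(tokens))
        return np.array([a.residue_name in vals for a in frame.atoms])
    if tok == "resid":
        vals = _collect_values(tokens)
        wanted: set[int] = set()
        for v in vals:
            m = re.fullmatch(r"(-?\d+)(?::(-?\d+))?", v)
            if not m:
                raise SelectionError(f"bad resid value {v!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            wanted.update(range(lo, hi + 1))
        return np.array([a.residue_index in wanted for a in frame.atoms])
    raise SelectionError(f"unknown selection token {tok!r}")


def select(frame: Frame, query: str) -> np.ndarray:
    """Evaluate a selection expression on *frame*; returns atom indices in file order.

    Grammar: ``name``/``chain``/``resname``/``resid`` value lists (resid takes
    0-based indices or ``lo:hi`` ranges), ``backbone``, ``all``, combined with
    ``and``/``or``/``not`` and parentheses.
    """
    if not query or not query.strip():
        raise SelectionError("empty selection expression")
    tokens = _Tokens(query)
    mask = _parse_or(tokens, frame)
    if tokens.peek() is not None:
        raise SelectionError(f"trailing tokens in selection: {tokens.peek()!r}")
    return np.flatnonzero(mask)
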