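"""PDB structure and multi-model trajectory I/O with a small atom-selection language.

Trajectories are exchanged as multi-model PDB files (MODEL/ENDMDL blocks
sharing one topology) so that fixtures stay human-readable and diffable.
Binary MD formats are deliberately unsupported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "TopologyError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select",
]


class PDBParseError(ValueError):
    """A fixed-column record could not be parsed; message names the line."""


class TopologyError(ValueError):
    """Models of a multi-model file disagree on the atom list."""


class SelectionError(ValueError):
    """Selection expression is syntactically invalid."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology (coordinates live in Frame)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    b_factor: float = 0.0
    altloc: str = ""

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.res_seq)


@dataclass
class Frame:
    """Coordinates (N, 3) in Angstrom for one snapshot, with a time stamp in ps."""

    coords: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.time < 0:
            raise ValueError("frame time must be non-negative")


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    Invariants: at least one frame, strictly increasing times, every frame
    matching the topology length.
    """

    topology: list[AtomRecord]
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise TopologyError(
                    f"frame {i} has {fr.coords.shape[0]} atoms, topology has {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        seen: set[tuple] = set()
        for a in self.topology:
            key = (a.chain_id, a.res_seq, a.name)
            if key in seen:
                raise TopologyError(f"duplicate atom {key} in topology")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def coords(self, frame: int) -> np.ndarray:
        return self.frames[frame].coords

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        for i, a in enumerate(self.topology):
            if a.chain_id == chain_id and a.res_seq == res_seq and a.name == name:
                return i
        raise KeyError(f"no atom {name} in residue {chain_id}:{res_seq}")

    def residue_ids(self) -> list[tuple[str, int]]:
        """Distinct residues in topology order."""
        out: list[tuple[str, int]] = []
        for a in self.topology:
            if not out or out[-1] != a.residue_id:
                if a.residue_id not in out:
                    out.append(a.residue_id)
        return out


# --------------------------------------------------------------------------
# PDB reading/writing (fixed columns, ATOM/HETATM/MODEL/ENDMDL)
# --------------------------------------------------------------------------

_RECORD_HEAD = ("ATOM  ", "HETATM")


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray, bool]:
    """Parse one ATOM/HETATM line. Returns (record, xyz, is_het)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        b_str = line[60:66].strip()
        b_factor = float(b_str) if b_str else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    if not element:
        # PDB convention: element is the first letter of the atom name, with
        # a leading digit (e.g. 1HB) or greek-position suffix stripped.
        element = re.sub(r"^\d+", "", name)[:1].upper()
    rec = AtomRecord(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        b_factor=b_factor,
        altloc=altloc,
    )
    return rec, np.array([x, y, z]), line.startswith("HETATM")


def read_pdb(
    path,
    *,
    keep_hetatm: bool = False,
    keep_waters: bool = False,
    frame_dt: float = 1.0,
) -> Trajectory:
    """Read a single- or multi-model PDB file into a Trajectory.

    Each MODEL block becomes one frame (a file with no MODEL records yields a
    single frame).  HETATM records and waters are skipped unless requested,
    and only blank/'A' alternate locations are kept (single-conformer
    analysis).  Frame times are ``i * frame_dt`` ps since the format carries
    no time stamps.
    """
    models: list[list[tuple[AtomRecord, np.ndarray]]] = []
    current: list[tuple[AtomRecord, np.ndarray]] = []
    in_model = False
    saw_model = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            head = line[:6]
            if head == "MODEL ":
                saw_model = True
                in_model = True
                current = []
            elif head == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif head in _RECORD_HEAD:
                rec, xyz, is_het = _parse_atom_line(line.rstrip("\n"), lineno)
                if is_het and not keep_hetatm:
                    continue
                if rec.res_name in ("HOH", "WAT") and not keep_waters:
                    continue
                if rec.altloc not in ("", "A"):
                    continue
                current.append((replace(rec, altloc=""), xyz))
    if current and (not saw_model or in_model):
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError("no ATOM records found")

    topology = [rec for rec, _ in models[0]]
    key = [(a.chain_id, a.res_seq, a.name) for a in topology]
    frames = []
    for i, m in enumerate(models):
        k = [(a.chain_id, a.res_seq, a.name) for a, _ in m]
        if k != key:
            raise TopologyError(
                f"model {i + 1} atom list differs from model 1 "
                f"({len(k)} vs {len(key)} atoms)"
            )
        frames.append(Frame(np.array([xyz for _, xyz in m]), time=i * frame_dt))
    return Trajectory(topology=topology, frames=frames)


def write_pdb(traj: Trajectory, path) -> None:
    """Write a Trajectory as (multi-model) PDB; coordinates to 3 decimals."""
    for fr in traj.frames:
        if np.any(fr.coords > 9999.999) or np.any(fr.coords < -999.999):
            raise ValueError("coordinate does not fit PDB 8.3 column width")
    multi = traj.n_frames > 1
    with open(path, "w") as fh:
        for imodel, fr in enumerate(traj.frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for a, xyz in zip(traj.topology, fr.coords):
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.serial:5d} {name}{'':1s}{a.res_name:>3s} "
                    f"{a.chain_id:1s}{a.res_seq:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{a.b_factor:6.2f}          {a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# Selection mini-language
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """Atom selection expression.

    Grammar (keywords bind their following value tokens; ``and`` binds
    tighter than ``or``)::

        expr     := conj ('or' conj)*
        conj     := clause ('and' clause)*
        clause   := 'chain' ID+ | 'resid' RANGE+ | 'resname' NAME+
                  | 'name' NAME+ | 'all'
        RANGE    := INT | INT '-' INT
    """

    expression: str


_KEYWORDS = {"chain", "resid", "resname", "name", "all", "and", "or"}


def _tokenize(expr: str) -> list[str]:
    tokens = expr.replace("\t", " ").split()
    if not tokens:
        raise SelectionError("empty selection expression")
    return tokens


def _parse_clause(tokens: list[str], pos: int, traj: Trajectory) -> tuple[set[int], int]:
    kw = tokens[pos]
    n = len(tokens)
    if kw == "all":
        return set(range(traj.n_atoms)), pos + 1
    if kw not in ("chain", "resid", "resname", "name"):
        raise SelectionError(f"unexpected token {kw!r}")
    pos += 1
    values: list[str] = []
    while pos < n and tokens[pos] not in _KEYWORDS:
        values.append(tokens[pos])
        pos += 1
    if not values:
        raise SelectionError(f"keyword {kw!r} needs at least one value")
    idx: set[int] = set()
    if kw == "resid":
        spans: list[tuple[int, int]] = []
        for v in values:
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
            if not m:
                raise SelectionError(f"bad residue range {v!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            spans.append((lo, hi))
        for i, a in enumerate(traj.topology):
            if any(lo <= a.res_seq <= hi for lo, hi in spans):
                idx.add(i)
    else:
        attr = {"chain": "chain_id", "resname": "res_name", "name": "name"}[kw]
        vals = set(values)
        for i, a in enumerate(traj.topology):
            if getattr(a, attr) in vals:
                idx.add(i)
    return idx, pos


def _parse_conj(tokens: list[str], pos: int, traj: Trajectory) -> tuple[set[int], int]:
    acc, pos = _parse_clause(tokens, pos, traj)
    while pos < len(tokens) and tokens[pos] == "and":
        rhs, pos = _parse_clause(tokens, pos + 1, traj)
        acc &= rhs
    return acc, pos


def select(traj: Trajectory, sel: Selection | str) -> list[int]:
    """Evaluate a selection; returns atom indices ordered by topology position.

    An empty result is valid (e.g. a residue number absent from the
    structure); only syntax errors raise.
    """
    expr = sel.expression if isinstance(sel, Selection) else sel
    tokens = _tokenize(expr)
    acc, pos = _parse_conj(tokens, 0, traj)
    while pos < len(tokens):
        if tokens[pos] != "or":
            raise SelectionError(f"unexpected token {tokens[pos]!r}")
        rhs, pos = _parse_conj(tokens, pos + 1, traj)
        acc |= rhs
    return sorted(acc)
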