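"""Structure/trajectory I/O, atom metadata, and a small selection grammar.

Coordinates are held in nm internally (PDB Angstroms are converted on read
and write); times are in ps at the frame level, matching trajectory-format
convention.  File parsing is delegated to MDAnalysis; this module adds the
atom flag model used by all analyses (heavy / sidechain / backbone / water /
sheet) and a deterministic boolean selection grammar:

    keyword     := protein | water | sheet | heavy | sidechain | backbone
    resid A-B, resid A, resname XXX
    combinators: and, or, not, parentheses

Residue numbering is preserved verbatim from the input file (HP35 from PDB
1YRF runs 42-76), so residue labels used in the adsorption literature
(Arg-55, Trp-64, ...) map directly onto ``resid`` selections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Topology",
    "Frame",
    "TrajectoryHandle",
    "load_structure",
    "load_trajectory",
    "select",
    "write_structure",
    "write_trajectory",
    "SelectionError",
]

#: residue names recognized as water
WATER_RESNAMES = {"SOL", "HOH", "WAT", "TIP3", "TIP3P", "SPC", "T3P"}
#: residue name of the MoS2 sheet
SHEET_RESNAMES = {"MOS"}
#: the 20 standard amino acids
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL",
}
#: atom names counted as protein backbone (heavy + amide/alpha hydrogens)
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "OT1", "OT2", "H", "HN", "HA", "H1", "H2", "H3"}

_TWO_LETTER_ELEMENTS = {"MO", "CL", "NA", "MG", "ZN", "FE", "BR", "SE", "MN", "CU"}


def infer_element(atom_name: str, resname: str = "") -> str:
    """Infer the element from an atom name.

    Rules (documented output convention): digits are stripped; within the
    ``MOS`` sheet residue, names starting with ``MO`` are molybdenum and
    ``S`` sulfur; otherwise a leading two-letter match against common
    non-CHONPS elements (Cl, Na, Mg, ...) wins, else the first letter is the
    element (the PDB convention for protein/water atoms, where e.g. ``CA``
    is an alpha-carbon, not calcium).
    """
    name = "".join(c for c in atom_name if c.isalpha()).upper()
    if not name:
        return "X"
    if resname.upper() in SHEET_RESNAMES:
        return "Mo" if name.startswith("MO") else "S"
    if name[:2] in _TWO_LETTER_ELEMENTS and resname.upper() not in PROTEIN_RESNAMES | WATER_RESNAMES:
        return name[:2].capitalize()
    return name[0]


@dataclass
class Topology:
    """Per-atom metadata shared by all frames of a system."""

    names: np.ndarray        # (N,) str
    elements: np.ndarray     # (N,) str
    resids: np.ndarray       # (N,) int, preserved from the source file
    resnames: np.ndarray     # (N,) str
    chains: np.ndarray       # (N,) str
    charges: np.ndarray = None    # (N,) float, e
    lj_types: np.ndarray = None   # (N,) str; defaults to the element

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("names", "elements", "resnames", "chains"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        self.resids = np.asarray(self.resids, dtype=int)
        if self.charges is None:
            self.charges = np.zeros(n)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.lj_types is None:
            self.lj_types = self.elements.copy()
        self.lj_types = np.asarray(self.lj_types, dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    # -- derived flags ------------------------------------------------------
    @property
    def heavy(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])

    @property
    def water(self) -> np.ndarray:
        return np.array([r.upper() in WATER_RESNAMES for r in self.resnames])

    @property
    def sheet(self) -> np.ndarray:
        return np.array([r.upper() in SHEET_RESNAMES for r in self.resnames])

    @property
    def protein(self) -> np.ndarray:
        return np.array([r.upper() in PROTEIN_RESNAMES for r in self.resnames])

    @property
    def backbone(self) -> np.ndarray:
        prot = self.protein
        return prot & np.array([n.upper() in BACKBONE_NAMES for n in self.names])

    @property
    def sidechain(self) -> np.ndarray:
        # sidechain and backbone are mutually exclusive by construction
        return self.protein & ~self.backbone

    # -- residue helpers ----------------------------------------------------
    def residue_atoms(self, resid: int, chain: str | None = None) -> np.ndarray:
        mask = self.resids == resid
        if chain is not None:
            mask &= self.chains == chain
        return np.flatnonzero(mask)

    def protein_resids(self) -> np.ndarray:
        """Sorted unique residue ids of protein residues."""
        return np.unique(self.resids[self.protein])

    def resname_of(self, resid: int) -> str:
        idx = np.flatnonzero(self.protein & (self.resids == resid))
        if len(idx) == 0:
            idx = np.flatnonzero(self.resids == resid)
        if len(idx) == 0:
            raise KeyError(f"no residue with id {resid}")
        return str(self.resnames[idx[0]])

    def subset(self, indices: np.ndarray) -> "Topology":
        indices = np.asarray(indices)
        return Topology(
            names=self.names[indices],
            elements=self.elements[indices],
            resids=self.resids[indices],
            resnames=self.resnames[indices],
            chains=self.chains[indices],
            charges=self.charges[indices],
            lj_types=self.lj_types[indices],
        )


@dataclass
class Frame:
    """One set of coordinates: positions (nm), time (ps), optional box (nm)."""

    positions: np.ndarray
    time: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (N, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in frame")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)[:3]
            if np.all(self.box == 0):
                self.box = None

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.time, None if self.box is None else self.box.copy())


class TrajectoryHandle:
    """Ordered frame access over an in-memory frame list or a trajectory file.

    Iteration yields :class:`Frame` objects in time order, honoring ``stride``
    and an optional ``[start, stop)`` frame range (indices before striding).
    """

    def __init__(self, topology: Topology, frames=None, reader=None, stride: int = 1,
                 start: int = 0, stop: int | None = None):
        if stride < 1:
            raise ValueError(f"stride must be >= 1, got {stride}")
        self.topology = topology
        self._frames = frames          # list[Frame] or None
        self._reader = reader          # MDAnalysis Universe or None
        self.stride = stride
        self.start = start
        self.stop = stop

    def _n_source_frames(self) -> int:
        if self._frames is not None:
            return len(self._frames)
        return len(self._reader.trajectory)

    @property
    def n_frames(self) -> int:
        stop = self._n_source_frames() if self.stop is None else min(self.stop, self._n_source_frames())
        span = max(0, stop - self.start)
        return (span + self.stride - 1) // self.stride

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        stop = self._n_source_frames() if self.stop is None else self.stop
        last_t = -np.inf
        for i in range(self.start, min(stop, self._n_source_frames()), self.stride):
            frame = self._get(i)
            if frame.time < last_t:
                raise ValueError(f"frame times not monotone increasing at frame {i} (t={frame.time} ps)")
            last_t = frame.time
            yield frame

    def _get(self, i: int) -> Frame:
        if self._frames is not None:
            return self._frames[i]
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Reader has no dt")
            ts = self._reader.trajectory[i]
            box = None
            if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                box = ts.dimensions[:3] / 10.0
            return Frame(positions=ts.positions / 10.0, time=float(ts.time), box=box)

    def times(self) -> np.ndarray:
        """Frame times in ps, in iteration order."""
        return np.array([f.time for f in self])


# ---------------------------------------------------------------------------
# reading

def _universe_to_topology(u) -> Topology:
    names = [a.name for a in u.atoms]
    resnames = [a.resname for a in u.atoms]
    try:
        elements = [str(e) if str(e).strip() else infer_element(n, r)
                    for e, n, r in zip(u.atoms.elements, names, resnames)]
        elements = [e.capitalize() for e in elements]
    except Exception:
        elements = [infer_element(n, r) for n, r in zip(names, resnames)]
    try:
        chains = list(u.atoms.chainIDs)
        chains = [c if str(c).strip() else "A" for c in chains]
    except Exception:
        try:
            chains = [str(s) for s in u.atoms.segids]
        except Exception:
            chains = ["A"] * len(names)
    return Topology(
        names=names,
        elements=elements,
        resids=u.atoms.resids,
        resnames=resnames,
        chains=chains,
    )


def load_structure(path) -> tuple[Topology, Frame]:
    """Read a PDB or GRO file into a topology plus one coordinate frame.

    Residue numbering is preserved exactly as in the file; elements come from
    the element column when present and are inferred from atom names
    otherwise (see :func:`infer_element`).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # surface parse failures with the file named
            raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Reader has no dt")
        top = _universe_to_topology(u)
        ts = u.trajectory.ts
        box = None
        if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
            box = ts.dimensions[:3] / 10.0
        return top, Frame(positions=u.atoms.positions / 10.0, time=float(getattr(ts, "time", 0.0)), box=box)


def load_trajectory(topology: Topology, path, stride: int = 1,
                    start: int = 0, stop: int | None = None) -> TrajectoryHandle:
    """Open an XTC/TRR/DCD/multi-model-PDB trajectory against a topology.

    The file's atom count must match the topology; frames are validated to be
    in increasing time order during iteration.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms=topology.n_atoms, trajectory=True)
        try:
            u.load_new(str(path))
        except ValueError as exc:
            # MDAnalysis reports its own count mismatch; restate both counts
            raise ValueError(
                f"trajectory {path} does not match topology with {topology.n_atoms} atoms: {exc}"
            ) from exc
    n_file = u.trajectory.n_atoms
    if n_file != topology.n_atoms:
        raise ValueError(f"atom count mismatch: trajectory has {n_file}, topology has {topology.n_atoms}")
    return TrajectoryHandle(topology, reader=u, stride=stride, start=start, stop=stop)


# ---------------------------------------------------------------------------
# writing

def _to_mda_universe(topology: Topology, frames: Sequence[Frame]):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    res_keys = []
    seen = {}
    atom_resindex = np.empty(topology.n_atoms, dtype=int)
    for i, (chain, resid) in enumerate(zip(topology.chains, topology.resids)):
        key = (chain, int(resid))
        if key not in seen:
            seen[key] = len(seen)
            res_keys.append(key)
        atom_resindex[i] = seen[key]
    n_res = len(res_keys)
    first_atom = {}
    for i in range(topology.n_atoms - 1, -1, -1):
        first_atom[atom_resindex[i]] = i

    u = mda.Universe.empty(
        n_atoms=topology.n_atoms, n_residues=n_res, n_segments=1,
        atom_resindex=atom_resindex, residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in topology.names])
    u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
    u.add_TopologyAttr("resids", [rk[1] for rk in res_keys])
    u.add_TopologyAttr("resnames", [str(topology.resnames[first_atom[r]]) for r in range(n_res)])
    u.add_TopologyAttr("chainIDs", [str(c)[:1] for c in topology.chains])
    u.add_TopologyAttr("occupancies", np.ones(topology.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(topology.n_atoms))

    coords = np.stack([f.positions * 10.0 for f in frames])
    if frames[0].box is not None:
        dims = np.stack([np.concatenate([f.box * 10.0, [90.0, 90.0, 90.0]]) for f in frames])
    else:
        dims = None
    u.load_new(coords, format=MemoryReader, dimensions=dims)
    for ts, f in zip(u.trajectory, frames):
        ts.time = f.time
    u.trajectory[0]
    return u


def write_structure(topology: Topology, frame: Frame, path) -> None:
    """Write a single frame as PDB or GRO (suffix decides)."""
    write_trajectory(topology, [frame], path)


def write_trajectory(topology: Topology, frames: Sequence[Frame], path) -> None:
    """Write frames to XTC/TRR/DCD or multi-model PDB / GRO (suffix decides)."""
    import MDAnalysis as mda

    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    path = Path(path)
    u = _to_mda_universe(topology, frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms, multiframe=len(frames) > 1) as w:
            for ts, f in zip(u.trajectory, frames):
                ts.time = f.time
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selection grammar

class SelectionError(ValueError):
    """Selection expression syntax error, carrying the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_KEYWORDS = ("protein", "water", "sheet", "heavy", "sidechain", "backbone")


def _tokenize(expr: str):
    tokens = []
    i, n = 0, len(expr)
    while i < n:
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, c, i))
            i += 1
            continue
        j = i
        while j < n and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        word = expr[i:j]
        tokens.append(("word", word, i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser: or-expr > and-expr > not-expr > atom."""

    def __init__(self, tokens, topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", self._end())
        self.pos += 1
        return tok

    def _end(self) -> int:
        return self.tokens[-1][2] + len(str(self.tokens[-1][1])) if self.tokens else 0

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        if self.peek() is not None:
            tok = self.peek()
            raise SelectionError(f"unexpected token {tok[1]!r}", tok[2])
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() is not None and self.peek()[0] == "word" and self.peek()[1] == "or":
            self.next()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek() is not None and self.peek()[0] == "word" and self.peek()[1] == "and":
            self.next()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        tok = self.peek()
        if tok is not None and tok[0] == "word" and tok[1] == "not":
            self.next()
            return ~self.parse_not()
        return self.parse_atom()

    def parse_atom(self) -> np.ndarray:
        tok = self.next()
        kind, word, pos = tok
        if kind == "(":
            mask = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise SelectionError("missing closing parenthesis", pos)
            self.next()
            return mask
        if kind == ")":
            raise SelectionError("unmatched closing parenthesis", pos)
        if word in _KEYWORDS:
            return getattr(self.top, word)
        if word == "resid":
            arg = self.next()
            if arg[0] != "word":
                raise SelectionError("resid expects a number or range", arg[2])
            text = arg[1]
            try:
                if "-" in text[1:]:
                    k = text.index("-", 1)
                    lo, hi = int(text[:k]), int(text[k + 1:])
                else:
                    lo = hi = int(text)
            except ValueError:
                raise SelectionError(f"invalid resid argument {text!r}", arg[2]) from None
            return (self.top.resids >= lo) & (self.top.resids <= hi)
        if word == "resname":
            arg = self.next()
            if arg[0] != "word":
                raise SelectionError("resname expects a residue name", arg[2])
            target = arg[1].upper()
            return np.array([r.upper() == target for r in self.top.resnames])
        raise SelectionError(f"unknown keyword {word!r}", pos)


def select(topology: Topology, expression: str) -> np.ndarray:
    """Evaluate a selection expression; returns sorted atom indices.

    ``select(top, "protein and sidechain and heavy")`` yields the atom set
    used for protein-sheet contact counting.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression", 0)
    mask = _Parser(tokens, topology).parse()
    return np.flatnonzero(mask)
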