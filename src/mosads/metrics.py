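"""Structural observables for protein adsorption trajectories.

Implements the observables used to quantify adsorption-driven denaturation:

* heavy-atom contact counts between protein sidechains and the sheet
  (an atom of the first set is "in contact" when any atom of the second set
  lies within the cutoff, 0.6 nm by default);
* the native-contact set of a reference structure (residue pairs at sequence
  separation >= 3 whose heavy atoms come within the same cutoff) and the
  native-contact fraction Q(t), the fraction of those pairs still formed at
  time t;
* an alpha-helix ratio from backbone phi/psi dihedrals (a residue is helical
  when both angles fall in a window around the ideal helix and it belongs to
  a run of at least four such residues);
* a geometric hydrogen-bond count and its ratio to a reference frame;
* salt-bridge and cation-pi detectors for specific residue pairs;
* the hydrophobic fraction of a residue set.

Counting conventions are deliberately explicit keyword arguments so output
headers can echo them; correctness of every pair-based metric is defined by
an exhaustive O(N^2) scan (the implementation is vectorized but algorithmically
identical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mosads._geom import angle, delta, dihedral, distance_matrix
from mosads.trajio import Frame, Topology, TrajectoryHandle, select

logger = logging.getLogger(__name__)

__all__ = [
    "NativeContactSet",
    "HelixSpans",
    "heavy_atom_contacts",
    "native_contacts",
    "q_fraction",
    "q_series",
    "contact_series",
    "per_residue_contact_series",
    "phi_psi",
    "helix_ratio",
    "hbond_count",
    "hbond_ratio",
    "salt_bridge",
    "cation_pi",
    "hydrophobic_fraction",
    "HYDROPHOBIC_RESIDUES",
]

#: default hydrophobic classification (aromatic Phe/Trp included)
HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"})

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class HelixSpans:
    """Residue-id spans of the three helices of the HP35 fold (inclusive)."""

    helix1: tuple[int, int] = (43, 52)
    helix2: tuple[int, int] = (54, 61)
    helix3: tuple[int, int] = (62, 74)

    def __post_init__(self) -> None:
        spans = self.as_dict()
        for name, (lo, hi) in spans.items():
            if lo > hi:
                raise ValueError(f"{name} span ({lo}, {hi}) is reversed")
        items = sorted(spans.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(items, items[1:]):
            if b_lo <= a_hi:
                raise ValueError(f"helix spans overlap: ({a_lo},{a_hi}) and ({b_lo},{b_hi})")

    def as_dict(self) -> dict:
        return {"helix1": self.helix1, "helix2": self.helix2, "helix3": self.helix3}

    def residues(self) -> np.ndarray:
        out = []
        for lo, hi in (self.helix1, self.helix2, self.helix3):
            out.extend(range(lo, hi + 1))
        return np.array(sorted(out))

    def helix_of(self, resid: int) -> int | None:
        for k, (lo, hi) in enumerate((self.helix1, self.helix2, self.helix3), start=1):
            if lo <= resid <= hi:
                return k
        return None


@dataclass(frozen=True)
class NativeContactSet:
    """Residue pairs in contact in a reference structure.

    ``pairs`` are unique ordered (i, j) residue-id tuples with j - i >= the
    minimum sequence separation; ``rc`` and ``part`` record the defining
    heavy-atom criterion; ``reference`` labels the source structure.
    """

    pairs: tuple
    rc: float = 0.6
    min_sep: int = 3
    part: str = "heavy"
    reference: str = ""

    def __post_init__(self) -> None:
        pairs = tuple(sorted({(int(i), int(j)) for i, j in self.pairs}))
        for i, j in pairs:
            if j - i < self.min_sep:
                raise ValueError(f"pair ({i}, {j}) violates minimum separation {self.min_sep}")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# contacts

def heavy_atom_contacts(frame: Frame, set_a: np.ndarray, set_b: np.ndarray,
                        rc: float = 0.6, pairs: bool = False) -> int:
    """Count set-A atoms with at least one set-B atom within ``rc`` nm.

    With ``pairs=True`` the symmetric variant (number of A-B pairs within
    ``rc``) is returned instead.  Minimum image is applied when the frame
    carries a box.  The sets must be disjoint.
    """
    set_a = np.asarray(set_a)
    set_b = np.asarray(set_b)
    if rc <= 0:
        raise ValueError(f"contact cutoff rc must be > 0, got {rc}")
    if np.intersect1d(set_a, set_b).size:
        raise ValueError("contact sets overlap; they must be disjoint")
    if set_a.size == 0 or set_b.size == 0:
        return 0
    d = distance_matrix(frame.positions[set_a], frame.positions[set_b], frame.box)
    hit = d <= rc
    return int(hit.sum()) if pairs else int(hit.any(axis=1).sum())


def _residue_part_indices(topology: Topology, part: str) -> dict:
    """Map protein resid -> atom indices of the requested part ('heavy'|'sidechain')."""
    if part == "heavy":
        mask = topology.protein & topology.heavy
    elif part == "sidechain":
        mask = topology.sidechain & topology.heavy
    else:
        raise ValueError(f"part must be 'heavy' or 'sidechain', got {part!r}")
    out = {}
    for resid in topology.protein_resids():
        idx = np.flatnonzero(mask & (topology.resids == resid))
        if idx.size:
            out[int(resid)] = idx
    return out


def native_contacts(topology: Topology, reference: Frame, rc: float = 0.6,
                    min_sep: int = 3, part: str = "heavy", label: str = "") -> NativeContactSet:
    """Identify native residue-pair contacts in a reference structure.

    A pair (i, j) with j - i >= ``min_sep`` is native when the minimum
    distance between the residues' atoms of the selected part (all heavy
    atoms by default) is <= ``rc``.
    """
    res_atoms = _residue_part_indices(topology, part)
    resids = sorted(res_atoms)
    if not resids:
        raise ValueError("no protein residues with heavy atoms in topology")
    found = []
    for a, i in enumerate(resids):
        for j in resids[a + 1:]:
            if j - i < min_sep:
                continue
            d = distance_matrix(reference.positions[res_atoms[i]],
                                reference.positions[res_atoms[j]], reference.box)
            if d.min() <= rc:
                found.append((i, j))
    return NativeContactSet(pairs=tuple(found), rc=rc, min_sep=min_sep, part=part, reference=label)


def q_fraction(frame: Frame, topology: Topology, ncs: NativeContactSet,
               rc: float | None = None) -> float:
    """Fraction of native contacts still formed in ``frame`` (Q in [0, 1])."""
    if len(ncs) == 0:
        raise ValueError("empty native contact set: Q is undefined")
    rc = ncs.rc if rc is None else rc
    res_atoms = _residue_part_indices(topology, ncs.part)
    formed = 0
    for i, j in ncs.pairs:
        d = distance_matrix(frame.positions[res_atoms[i]], frame.positions[res_atoms[j]], frame.box)
        if d.min() <= rc:
            formed += 1
    return formed / len(ncs)


def q_series(traj: TrajectoryHandle, ncs: NativeContactSet) -> pd.DataFrame:
    """Q(t) over a trajectory; columns ``time_ns``, ``q``."""
    rows = [(f.time / 1000.0, q_fraction(f, traj.topology, ncs)) for f in traj]
    return pd.DataFrame(rows, columns=["time_ns", "q"])


def contact_series(traj: TrajectoryHandle, rc: float = 0.6,
                   selection: str = "protein and sidechain and heavy",
                   target: str = "sheet", pairs: bool = False) -> pd.DataFrame:
    """Protein-sheet contact count per frame; columns ``time_ns``, ``contacts``."""
    top = traj.topology
    set_a = select(top, selection)
    set_b = select(top, target)
    rows = [(f.time / 1000.0, heavy_atom_contacts(f, set_a, set_b, rc=rc, pairs=pairs)) for f in traj]
    return pd.DataFrame(rows, columns=["time_ns", "contacts"])


def per_residue_contact_series(traj: TrajectoryHandle, rc: float = 0.6,
                               part: str = "sidechain", target: str = "sheet") -> pd.DataFrame:
    """Per-residue contact counts over time.

    Returns a DataFrame indexed by ``time_ns`` with one column per protein
    residue id, holding the number of that residue's heavy atoms (of the
    selected part) in contact with the target group.
    """
    top = traj.topology
    res_atoms = _residue_part_indices(top, part)
    set_b = select(top, target)
    times, rows = [], []
    for f in traj:
        times.append(f.time / 1000.0)
        row = {}
        for resid, idx in res_atoms.items():
            d = distance_matrix(f.positions[idx], f.positions[set_b], f.box)
            row[resid] = int((d.min(axis=1) <= rc).sum())
        rows.append(row)
    out = pd.DataFrame(rows, index=pd.Index(times, name="time_ns"))
    return out[sorted(out.columns)]


# ---------------------------------------------------------------------------
# secondary structure

def phi_psi(frame: Frame, topology: Topology) -> pd.DataFrame:
    """Backbone (phi, psi) per protein residue, degrees; NaN where undefined.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i), psi(i) = N(i)-CA(i)-C(i)-N(i+1); chain
    termini and residues with missing backbone atoms yield NaN (and a logged
    warning for the latter).
    """
    prot = topology.protein
    resids = topology.protein_resids()
    atom_of = {}
    for resid in resids:
        sel = prot & (topology.resids == resid)
        names = topology.names[sel]
        idx = np.flatnonzero(sel)
        entry = {}
        for nm in ("N", "CA", "C"):
            hits = idx[np.array([str(x).upper() == nm for x in names])]
            entry[nm] = int(hits[0]) if hits.size else None
        atom_of[int(resid)] = entry

    rows = []
    pos = frame.positions
    for k, resid in enumerate(resids):
        e = atom_of[int(resid)]
        if None in e.values():
            logger.warning("residue %d missing backbone atoms; marked unassignable", resid)
            rows.append((int(resid), np.nan, np.nan))
            continue
        phi = psi = np.nan
        if k > 0 and resids[k - 1] == resid - 1:
            prev_c = atom_of[int(resid) - 1]["C"]
            if prev_c is not None:
                phi = dihedral(pos[prev_c], pos[e["N"]], pos[e["CA"]], pos[e["C"]])
        if k < len(resids) - 1 and resids[k + 1] == resid + 1:
            next_n = atom_of[int(resid) + 1]["N"]
            if next_n is not None:
                psi = dihedral(pos[e["N"]], pos[e["CA"]], pos[e["C"]], pos[next_n])
        rows.append((int(resid), phi, psi))
    return pd.DataFrame(rows, columns=["resid", "phi", "psi"]).set_index("resid")


def _helical_flags(dihedrals: pd.DataFrame, phi0: float = -57.0, psi0: float = -47.0,
                   window: float = 30.0, min_run: int = 4) -> pd.Series:
    in_window = (
        dihedrals["phi"].sub(phi0).abs().le(window)
        & dihedrals["psi"].sub(psi0).abs().le(window)
    )
    vals = in_window.to_numpy()
    resids = dihedrals.index.to_numpy()
    flags = np.zeros(len(vals), dtype=bool)
    i = 0
    while i < len(vals):
        if not vals[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(vals) and vals[j + 1] and resids[j + 1] == resids[j] + 1:
            j += 1
        if j - i + 1 >= min_run:
            flags[i : j + 1] = True
        i = j + 1
    return pd.Series(flags, index=dihedrals.index)


def helix_ratio(frame: Frame, topology: Topology, spans: HelixSpans | None = None,
                phi0: float = -57.0, psi0: float = -47.0, window: float = 30.0,
                min_run: int = 4) -> float:
    """Fraction of assignable residues in the alpha-helical state.

    A residue is helical when (phi, psi) lie within ``window`` degrees of
    (phi0, psi0) and it belongs to a run of at least ``min_run`` consecutive
    such residues.  Residues without both dihedrals (termini, missing
    backbone) are excluded from the denominator.  When ``spans`` is given,
    both numerator and denominator are restricted to the span residues.
    """
    dihedrals = phi_psi(frame, topology)
    assignable = dihedrals.dropna()
    flags = _helical_flags(dihedrals, phi0, psi0, window, min_run)
    if spans is not None:
        keep = np.isin(assignable.index.to_numpy(), spans.residues())
        assignable = assignable[keep]
    if len(assignable) == 0:
        raise ValueError("no assignable residues for helix ratio")
    return float(flags.loc[assignable.index].sum() / len(assignable))


# ---------------------------------------------------------------------------
# hydrogen bonds

def hbond_count(frame: Frame, topology: Topology, selection: str | None = None,
                rc: float = 0.35, angle_min: float = 150.0) -> int:
    """Geometric hydrogen-bond count among N/O atoms.

    A donor-acceptor pair (N or O atoms in different residues) is bonded when
    the heavy-atom distance is <= ``rc`` (0.35 nm) and, if hydrogens are
    present in the topology, some H covalently bound to either partner makes
    an X-H...Y angle >= ``angle_min`` degrees.  Without hydrogens the
    distance-only criterion is used (logged).
    """
    if selection is None:
        mask = np.ones(topology.n_atoms, dtype=bool)
    else:
        mask = np.zeros(topology.n_atoms, dtype=bool)
        mask[select(topology, selection)] = True
    is_no = mask & np.array([e.upper() in ("N", "O") for e in topology.elements])
    cand = np.flatnonzero(is_no)
    if cand.size == 0:
        return 0
    hydrogens = np.flatnonzero(mask & ~topology.heavy)

    pos = frame.positions
    # H attached to a candidate heavy atom: within covalent range 0.12 nm
    attached: dict[int, list[int]] = {int(i): [] for i in cand}
    if hydrogens.size:
        dh = distance_matrix(pos[cand], pos[hydrogens], frame.box)
        for a, i in enumerate(cand):
            for b in np.flatnonzero(dh[a] <= 0.12):
                attached[int(i)].append(int(hydrogens[b]))
    use_angle = any(attached.values())
    if not use_angle:
        logger.info("no hydrogens found; hydrogen bonds use the distance-only criterion")

    d = distance_matrix(pos[cand], pos[cand], frame.box)
    count = 0
    for a in range(len(cand)):
        for b in range(a + 1, len(cand)):
            i, j = int(cand[a]), int(cand[b])
            if topology.resids[i] == topology.resids[j] and topology.chains[i] == topology.chains[j]:
                continue
            if d[a, b] > rc:
                continue
            if not use_angle:
                count += 1
                continue
            ok = False
            for donor, acceptor in ((i, j), (j, i)):
                for h in attached[donor]:
                    if angle(pos[donor], pos[h], pos[acceptor]) >= angle_min:
                        ok = True
                        break
                if ok:
                    break
            if ok:
                count += 1
    return count


def hbond_ratio(count: int, reference_count: int) -> float:
    """Hydrogen-bond count normalized by the reference-structure count."""
    if reference_count <= 0:
        raise ValueError("reference hydrogen-bond count must be positive")
    return count / reference_count


# ---------------------------------------------------------------------------
# specific interactions

_BASIC_N = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
_ACIDIC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
}
_CATION_CENTER = {"ARG": "CZ", "LYS": "NZ"}


def _named_atoms(topology: Topology, resid: int, names: tuple) -> np.ndarray:
    idx = topology.residue_atoms(resid)
    hits = [int(i) for i in idx if str(topology.names[i]).upper() in names]
    return np.array(hits, dtype=int)


def salt_bridge(frame: Frame, topology: Topology, basic_resid: int, acidic_resid: int,
                rc: float = 0.4) -> bool:
    """True when a basic sidechain N comes within ``rc`` of a carboxylate O."""
    bname = topology.resname_of(basic_resid).upper()
    aname = topology.resname_of(acidic_resid).upper()
    if bname not in _BASIC_N:
        raise ValueError(f"residue {basic_resid} ({bname}) is not basic (Arg/Lys)")
    if aname not in _ACIDIC_O:
        raise ValueError(f"residue {acidic_resid} ({aname}) is not acidic (Asp/Glu)")
    n_idx = _named_atoms(topology, basic_resid, _BASIC_N[bname])
    o_idx = _named_atoms(topology, acidic_resid, _ACIDIC_O[aname])
    if n_idx.size == 0 or o_idx.size == 0:
        raise ValueError("charged-group atoms missing for salt-bridge test")
    d = distance_matrix(frame.positions[n_idx], frame.positions[o_idx], frame.box)
    return bool(d.min() <= rc)


def cation_pi(frame: Frame, topology: Topology, cation_resid: int, aromatic_resid: int,
              rc: float = 0.5) -> bool:
    """True when the cation center is within ``rc`` of the aromatic ring centroid.

    The cation center is the guanidinium carbon (Arg CZ) or the ammonium
    nitrogen (Lys NZ); the ring centroid is the mean of the ring heavy atoms.
    """
    cname = topology.resname_of(cation_resid).upper()
    aname = topology.resname_of(aromatic_resid).upper()
    if cname not in _CATION_CENTER:
        raise ValueError(f"residue {cation_resid} ({cname}) is not cationic (Arg/Lys)")
    if aname not in _RING_ATOMS:
        raise ValueError(f"residue {aromatic_resid} ({aname}) is not aromatic (Phe/Tyr/Trp)")
    c_idx = _named_atoms(topology, cation_resid, (_CATION_CENTER[cname],))
    ring_idx = _named_atoms(topology, aromatic_resid, _RING_ATOMS[aname])
    if c_idx.size == 0 or ring_idx.size == 0:
        raise ValueError("cation or ring atoms missing for cation-pi test")
    centroid = frame.positions[ring_idx].mean(axis=0)
    d = distance_matrix(frame.positions[c_idx], centroid[None, :], frame.box)
    return bool(d.min() <= rc)


# ---------------------------------------------------------------------------
# composition

def hydrophobic_fraction(residues, classification=HYDROPHOBIC_RESIDUES) -> float:
    """Percentage of residues classified hydrophobic (aromatics included).

    ``residues`` is a list of residue names (three-letter like ``"TRP"`` or
    one-letter like ``"W"``; an optional ``-id`` suffix such as ``"TRP-64"``
    is accepted).  Unknown codes raise.
    """
    if len(residues) == 0:
        raise ValueError("empty residue list")
    names = []
    for r in residues:
        code = str(r).split("-")[0].strip().upper()
        if len(code) == 1:
            if code not in _ONE_TO_THREE:
                raise ValueError(f"unknown residue code {r!r}")
            code = _ONE_TO_THREE[code]
        if code not in _ONE_TO_THREE.values():
            raise ValueError(f"unknown residue code {r!r}")
        names.append(code)
    table = {c.upper() for c in classification}
    n_hydro = sum(1 for n in names if n in table)
    return 100.0 * n_hydro / len(names)
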