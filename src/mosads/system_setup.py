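"""Assemble protein + sheet into an engine-ready, solvatable system.

The module performs the geometric and bookkeeping steps of system
preparation: rigid placement of the protein above the monolayer at a
prescribed minimum heavy-atom gap (0.8 nm in the reference setup), box-size
suggestion, and formal-charge / counterion accounting.  Water insertion and
topology generation for a specific MD engine are left to external tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from mosads._geom import distance_matrix
from mosads.nanosheet import SheetModel
from mosads.trajio import Frame, Topology

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSystem",
    "place_protein",
    "formal_charge",
    "counterions",
    "suggest_box",
    "combine_system",
]

#: sidechain charges at pH 7: Asp/Glu -1, Lys/Arg +1, His neutral
RESIDUE_CHARGES = {
    "ALA": 0, "ARG": +1, "ASN": 0, "ASP": -1, "CYS": 0, "GLN": 0, "GLU": -1,
    "GLY": 0, "HIS": 0, "ILE": 0, "LEU": 0, "LYS": +1, "MET": 0, "PHE": 0,
    "PRO": 0, "SER": 0, "THR": 0, "TRP": 0, "TYR": 0, "VAL": 0,
}
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class SimulationSystem:
    """A placed protein-sheet system with its realized gap and box."""

    protein_topology: Topology
    protein_frame: Frame
    sheet: SheetModel
    gap: float                     # realized min protein-heavy to sheet distance, nm
    box: np.ndarray | None = None  # nm
    counterions: tuple | None = None  # (species, count)


def _min_gap(protein_top: Topology, positions: np.ndarray, sheet: SheetModel) -> float:
    heavy = positions[protein_top.heavy]
    return float(distance_matrix(heavy, sheet.positions).min())


def place_protein(protein_topology: Topology, protein_frame: Frame, sheet: SheetModel,
                  gap: float = 0.8, tol: float = 1e-4) -> SimulationSystem:
    """Rigidly place the protein above the sheet at the requested gap.

    The protein's xy centroid is aligned to the sheet's xy center, then the
    protein is translated along +z until the minimum distance from any
    protein heavy atom to any sheet atom (S or Mo; the logged gap definition)
    equals ``gap`` within ``tol`` nm.  Internal protein geometry is untouched.
    """
    if gap <= 0:
        raise ValueError(f"gap must be > 0, got {gap}")
    if protein_topology.n_atoms == 0 or sheet.n_atoms == 0:
        raise ValueError("protein and sheet must be non-empty")

    pos = protein_frame.positions.copy()
    heavy = protein_topology.heavy
    if not heavy.any():
        raise ValueError("protein has no heavy atoms")

    sheet_min = sheet.positions.min(axis=0)
    sheet_max = sheet.positions.max(axis=0)
    sheet_center_xy = 0.5 * (sheet_min[:2] + sheet_max[:2])
    centroid_xy = pos[heavy, :2].mean(axis=0)
    pos[:, :2] += sheet_center_xy - centroid_xy

    span_xy = pos[heavy].max(axis=0)[:2] - pos[heavy].min(axis=0)[:2]
    if np.any(span_xy > np.array(sheet.extents)):
        logger.warning("protein xy span %s nm exceeds sheet extents %s nm", span_xy, sheet.extents)

    # start with the lowest heavy atom one gap above the top sulfur plane,
    # then bisect the vertical shift until the realized 3D min distance = gap
    top_z = sheet.positions[:, 2].max()
    pos[:, 2] += (top_z + gap) - pos[heavy, 2].min()

    def realized(shift: float) -> float:
        test = pos.copy()
        test[:, 2] += shift
        return _min_gap(protein_topology, test, sheet)

    lo, hi = -gap * 0.5, 0.0
    for _ in range(60):
        if realized(hi) >= gap:
            break
        hi += gap
    for _ in range(60):
        if realized(lo) <= gap:
            break
        lo -= gap * 0.5
    else:
        raise RuntimeError(f"cannot bracket requested gap {gap} nm (too small for the lattice spacing)")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if realized(mid) < gap:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * 0.25:
            break
    pos[:, 2] += hi
    achieved = _min_gap(protein_topology, pos, sheet)
    if abs(achieved - gap) > 1e-3:
        raise RuntimeError(f"placement did not converge: realized gap {achieved:.6f} nm vs requested {gap}")
    logger.info("placed protein: realized heavy-atom gap %.4f nm (requested %.4f)", achieved, gap)
    placed = Frame(pos, time=protein_frame.time, box=None)
    return SimulationSystem(protein_topology=protein_topology, protein_frame=placed,
                            sheet=sheet, gap=achieved)


def formal_charge(sequence, termini: str = "zwitterionic") -> int:
    """Formal charge (e) of a sequence at pH 7.

    ``sequence`` is a one-letter string or an iterable of one/three-letter
    codes.  Charge = (#Lys + #Arg) - (#Asp + #Glu) + terminal term
    (zwitterionic: +1 - 1 = 0; neutral caps: 0); His counts 0.
    """
    if termini not in ("zwitterionic", "neutral"):
        raise ValueError(f"termini must be 'zwitterionic' or 'neutral', got {termini!r}")
    if isinstance(sequence, str):
        codes = list(sequence)
    else:
        codes = [str(c) for c in sequence]
    total = 0
    for code in codes:
        c = code.strip().upper()
        if len(c) == 1:
            if c not in _ONE_TO_THREE:
                raise ValueError(f"unknown residue code {code!r}")
            c = _ONE_TO_THREE[c]
        if c not in RESIDUE_CHARGES:
            raise ValueError(f"unknown residue code {code!r}")
        total += RESIDUE_CHARGES[c]
    # both termini conventions contribute net zero; the tag records the assumption
    return total


def counterions(charge: int) -> tuple:
    """Counterion species and count neutralizing a net formal charge."""
    if charge > 0:
        return ("CL", charge)
    if charge < 0:
        return ("NA", -charge)
    return ("", 0)


def suggest_box(system: SimulationSystem, margin_z: float = 1.0, pad_xy: float = 0.1) -> np.ndarray:
    """Suggest an orthorhombic box (nm) enclosing the placed system.

    x and y come from the sheet extents plus ``pad_xy`` per side; z is the
    total atom z-span plus ``margin_z``.  All atoms fit inside the box after
    shifting the origin to the minimum corner.
    """
    if margin_z < 0:
        raise ValueError(f"margin_z must be >= 0, got {margin_z}")
    if pad_xy < 0:
        raise ValueError(f"pad_xy must be >= 0, got {pad_xy}")
    all_pos = np.vstack([system.protein_frame.positions, system.sheet.positions])
    zspan = all_pos[:, 2].max() - all_pos[:, 2].min()
    lx, ly = system.sheet.extents
    box = np.array([lx + 2 * pad_xy, ly + 2 * pad_xy, zspan + margin_z])
    system.box = box
    return box


def combine_system(system: SimulationSystem) -> tuple[Topology, Frame]:
    """Merge protein and sheet into one topology + frame (protein first)."""
    sheet = system.sheet
    n_s = sheet.n_atoms
    top = system.protein_topology
    names = np.concatenate([top.names, np.where(sheet.species == "Mo", "MO", "S")])
    elements = np.concatenate([top.elements, sheet.species])
    resids = np.concatenate([top.resids, np.full(n_s, 1, dtype=int)])
    resnames = np.concatenate([top.resnames, np.full(n_s, "MOS", dtype=object)])
    chains = np.concatenate([top.chains, np.full(n_s, "M", dtype=object)])
    charges = np.concatenate([top.charges, np.zeros(n_s)])
    if sheet.params is not None:
        charges[top.n_atoms:] = [sheet.params[s].charge for s in sheet.species]
    lj_types = np.concatenate([top.lj_types, sheet.species])
    combined = Topology(names=names, elements=elements, resids=resids,
                        resnames=resnames, chains=chains, charges=charges, lj_types=lj_types)
    positions = np.vstack([system.protein_frame.positions, sheet.positions])
    box = system.box if system.box is not None else None
    return combined, Frame(positions, time=system.protein_frame.time, box=box)
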