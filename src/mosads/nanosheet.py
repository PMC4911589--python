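"""Orthorhombic 2H-MoS2 monolayer patches with nonbonded parameters.

A 2H-MoS2 monolayer is a tri-atomic S-Mo-S sandwich: the Mo atoms form a
hexagonal lattice and every Mo is trigonal-prismatically coordinated by six
sulfurs, three in the plane above and three below.  The builder works in an
orthorhombic supercell with in-plane vectors ``(a, 0)`` and ``(0, a*sqrt(3))``
containing 2 Mo and 4 S (x is the zigzag direction), which tiles into the
rectangular patches used in adsorption simulations.

All coordinates are in nm.  Nonbonded parameters (per-species Lennard-Jones
sigma/epsilon and partial charge) are configuration data, not code: the
shipped defaults in ``data/mos2_params.yml`` are provisional literature-style
values and are meant to be replaced by the force field actually in use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "LatticeSpec",
    "SpeciesParams",
    "NonbondedParams",
    "SheetModel",
    "build_monolayer",
    "repeats_for_target",
    "sheet_extents",
    "mo_s_bond_lengths",
    "write_sheet",
    "write_index_group",
    "load_params",
    "default_params",
]

#: default in-plane hexagonal lattice constant of 2H-MoS2 (nm)
DEFAULT_A = 0.316
#: default vertical offset of each sulfur plane from the Mo plane (nm)
DEFAULT_DZ = 0.1564

_DATA_DIR = Path(__file__).parent / "data"


class SheetValidationError(ValueError):
    """Raised when a lattice or parameter field violates its invariant."""


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of an orthorhombic monolayer patch.

    Parameters
    ----------
    a : float
        In-plane hexagonal lattice constant (nm).
    dz : float
        Vertical offset of each S plane from the Mo plane (nm).
    nx, ny : int
        Integer repeats of the orthorhombic cell along x and y.
    origin : tuple of float
        Cartesian origin of the patch (nm).
    """

    a: float = DEFAULT_A
    dz: float = DEFAULT_DZ
    nx: int = 1
    ny: int = 1
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise SheetValidationError(f"lattice constant a must be > 0, got a={self.a}")
        if not self.dz > 0:
            raise SheetValidationError(f"S-plane offset dz must be > 0, got dz={self.dz}")
        for name in ("nx", "ny"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise SheetValidationError(f"repeat count {name} must be an integer >= 1, got {name}={v}")

    @property
    def cell(self) -> tuple[float, float]:
        """Orthorhombic cell vectors' lengths ``(a, a*sqrt(3))``."""
        return (self.a, self.a * math.sqrt(3.0))

    @property
    def bond_length(self) -> float:
        """Mo-S nearest-neighbor distance ``sqrt(a^2/3 + dz^2)`` (nm)."""
        return math.sqrt(self.a**2 / 3.0 + self.dz**2)


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species nonbonded parameters: LJ sigma (nm), epsilon (kcal/mol), charge (e)."""

    sigma: float
    epsilon: float
    charge: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise SheetValidationError(f"sigma must be > 0, got {self.sigma}")
        if self.epsilon < 0:
            raise SheetValidationError(f"epsilon must be >= 0, got {self.epsilon}")


@dataclass(frozen=True)
class NonbondedParams:
    """Per-species nonbonded parameter table plus the LJ combination rule."""

    species: dict
    combination_rule: str = "lorentz-berthelot"

    def __post_init__(self) -> None:
        if self.combination_rule not in ("lorentz-berthelot", "geometric"):
            raise SheetValidationError(
                f"combination_rule must be 'lorentz-berthelot' or 'geometric', got {self.combination_rule!r}"
            )
        coerced = {}
        for name, entry in self.species.items():
            if not isinstance(entry, SpeciesParams):
                entry = SpeciesParams(**entry) if isinstance(entry, dict) else SpeciesParams(*entry)
            coerced[str(name)] = entry
        object.__setattr__(self, "species", coerced)

    def __getitem__(self, name: str) -> SpeciesParams:
        return self.species[name]

    def sheet_cell_charge(self) -> float:
        """Net charge per orthorhombic cell, ``2*(q_Mo + 2*q_S)`` in e."""
        return 2.0 * (self.species["Mo"].charge + 2.0 * self.species["S"].charge)


@dataclass
class SheetModel:
    """A built monolayer patch: species, positions, layer tags, parameters."""

    species: np.ndarray            # (N,) str, "Mo" or "S"
    positions: np.ndarray          # (N, 3) nm
    layers: np.ndarray             # (N,) str in {"S_top", "Mo", "S_bottom"}
    extents: tuple[float, float]   # periodic (Lx, Ly), nm
    spec: LatticeSpec
    params: NonbondedParams | None = None
    frozen: bool = True            # metadata only: sheet held rigid in MD

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def top_s_z(self) -> float:
        """z of the upper sulfur plane (nm)."""
        return float(self.positions[self.layers == "S_top", 2][0])

    def translated(self, shift: Iterable[float]) -> "SheetModel":
        shift = np.asarray(list(shift), dtype=float)
        return SheetModel(
            species=self.species.copy(),
            positions=self.positions + shift,
            layers=self.layers.copy(),
            extents=self.extents,
            spec=self.spec,
            params=self.params,
            frozen=self.frozen,
        )


def build_monolayer(spec: LatticeSpec, params: NonbondedParams | None = None) -> SheetModel:
    """Build an ``nx`` x ``ny`` orthorhombic 2H-MoS2 monolayer patch.

    Each cell contributes atoms in the fixed order Mo, Mo, S_top, S_top,
    S_bottom, S_bottom.  The Mo plane sits at the origin z; the sulfur planes
    at z +- dz.  Periodic extents are ``(nx*a, ny*a*sqrt(3))``.
    """
    a, dz = spec.a, spec.dz
    ly = a * math.sqrt(3.0)
    # fractional in-cell sites: Mo honeycomb sublattice A, S columns on sublattice B
    mo_xy = np.array([[0.0, 0.0], [0.5 * a, 0.5 * ly]])
    s_xy = np.array([[0.5 * a, ly / 6.0], [0.0, 2.0 * ly / 3.0]])

    species, layers, pos = [], [], []
    for ix in range(spec.nx):
        for iy in range(spec.ny):
            shift = np.array([ix * a, iy * ly])
            for xy in mo_xy:
                pos.append([*(xy + shift), 0.0])
                species.append("Mo")
                layers.append("Mo")
            for xy in s_xy:
                pos.append([*(xy + shift), dz])
                species.append("S")
                layers.append("S_top")
            for xy in s_xy:
                pos.append([*(xy + shift), -dz])
                species.append("S")
                layers.append("S_bottom")

    positions = np.asarray(pos, dtype=float) + np.asarray(spec.origin, dtype=float)
    return SheetModel(
        species=np.asarray(species, dtype=object),
        positions=positions,
        layers=np.asarray(layers, dtype=object),
        extents=(spec.nx * a, spec.ny * ly),
        spec=spec,
        params=params,
    )


def repeats_for_target(target_lx: float, target_ly: float, a: float = DEFAULT_A) -> tuple[int, int]:
    """Integer repeats minimizing |extent - target| per axis (at least 1 each)."""
    if target_lx <= 0 or target_ly <= 0:
        raise SheetValidationError(f"target extents must be > 0, got ({target_lx}, {target_ly})")
    ly_cell = a * math.sqrt(3.0)
    nx = max(1, round(target_lx / a))
    ny = max(1, round(target_ly / ly_cell))
    return nx, ny


def sheet_extents(sheet: SheetModel) -> tuple[float, float]:
    """Periodic in-plane extents ``(Lx, Ly) = (nx*a, ny*a*sqrt(3))`` in nm.

    This is the coordinate span plus one lattice spacing per axis (the patch
    tiles seamlessly at this period); it is invariant under translation.
    """
    if sheet.n_atoms == 0:
        raise SheetValidationError("empty sheet has no extents")
    return sheet.extents


def mo_s_bond_lengths(sheet: SheetModel) -> np.ndarray:
    """Nearest-neighbor Mo-S distances, six per Mo, under in-plane periodicity.

    Returns an ``(n_Mo, 6)`` array of the six shortest Mo-S distances per Mo
    (minimum image in x and y at the sheet extents).
    """
    mo = sheet.positions[sheet.species == "Mo"]
    s = sheet.positions[sheet.species == "S"]
    lx, ly = sheet.extents
    # explicit image expansion (not minimum image) so single-cell patches
    # still count all six trigonal-prismatic neighbors with multiplicity
    images = []
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            images.append(s + np.array([ix * lx, iy * ly, 0.0]))
    s_all = np.vstack(images)
    d = mo[:, None, :] - s_all[None, :, :]
    r = np.sqrt((d**2).sum(axis=-1))
    r.sort(axis=1)
    return r[:, :6]


# ---------------------------------------------------------------------------
# file output

def _sheet_to_atom_array(sheet: SheetModel):
    import biotite.structure as struc

    n = sheet.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = sheet.positions * 10.0  # nm -> Angstrom (biotite native unit)
    arr.chain_id = np.full(n, "M")
    arr.res_id = np.full(n, 1, dtype=int)
    arr.res_name = np.full(n, "MOS")
    arr.atom_name = np.where(sheet.species == "Mo", "MO", "S")
    arr.element = np.where(sheet.species == "Mo", "MO", "S")
    arr.hetero = np.full(n, True)
    return arr


def write_sheet(sheet: SheetModel, path, fmt: str | None = None) -> None:
    """Write the sheet as PDB or GRO (residue name ``MOS``, element columns set).

    ``fmt`` defaults to the file suffix.  Reading the file back reproduces the
    species sequence and positions to format precision (PDB: 1e-3 A columns;
    GRO: 1e-3 nm columns).
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    arr = _sheet_to_atom_array(sheet)
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    elif fmt == "gro":
        from biotite.structure.io.gro import GROFile

        f = GROFile()
        f.set_structure(arr)
        f.write(str(path))
    else:
        raise ValueError(f"unsupported sheet format {fmt!r}; supported formats: pdb, gro")


def write_index_group(sheet: SheetModel, path, group: str = "MOS_frozen", offset: int = 0) -> None:
    """Write a GROMACS-style index (.ndx) group of the sheet's (frozen) atoms.

    ``offset`` is the number of atoms preceding the sheet in the combined
    system; indices in the file are 1-based as per the ndx convention.
    """
    idx = np.arange(1 + offset, 1 + offset + sheet.n_atoms)
    lines = [f"[ {group} ]"]
    for start in range(0, len(idx), 15):
        lines.append(" ".join(f"{i:d}" for i in idx[start : start + 15]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# parameter configuration

def load_params(path) -> NonbondedParams:
    """Load a nonbonded parameter config (YAML: species -> sigma/epsilon/charge)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    species = {
        name: SpeciesParams(
            sigma=float(entry["sigma"]),
            epsilon=float(entry["epsilon"]),
            charge=float(entry["charge"]),
        )
        for name, entry in raw["species"].items()
    }
    return NonbondedParams(species=species, combination_rule=raw.get("combination_rule", "lorentz-berthelot"))


def default_params() -> NonbondedParams:
    """The shipped provisional MoS2 parameter set (see ``data/mos2_params.yml``)."""
    return load_params(_DATA_DIR / "mos2_params.yml")


def sheet_from_structure(topology, frame, a: float = DEFAULT_A,
                         params: NonbondedParams | None = None) -> SheetModel:
    """Reconstruct a :class:`SheetModel` from a loaded sheet structure file.

    Layers are assigned from the three distinct z planes; extents are the
    coordinate span completed by one lattice spacing per axis (a/2 along the
    zigzag x axis, a*sqrt(3)/3 along y), the period at which the patch tiles.
    """
    mask = topology.sheet
    if not mask.any():
        raise SheetValidationError("structure contains no MOS sheet atoms")
    species = np.where(np.array([e == "Mo" for e in topology.elements[mask]]), "Mo", "S").astype(object)
    positions = frame.positions[mask]
    z = positions[:, 2]
    z_lvls = np.sort(np.unique(np.round(z, 4)))
    if len(z_lvls) != 3:
        raise SheetValidationError(f"expected 3 z planes in sheet, found {len(z_lvls)}")
    layers = np.empty(len(z), dtype=object)
    layers[np.isclose(z, z_lvls[0], atol=1e-3)] = "S_bottom"
    layers[np.isclose(z, z_lvls[1], atol=1e-3)] = "Mo"
    layers[np.isclose(z, z_lvls[2], atol=1e-3)] = "S_top"
    dz = float(z_lvls[2] - z_lvls[1])
    span = positions.max(axis=0) - positions.min(axis=0)
    lx = span[0] + a / 2.0
    ly = span[1] + a * math.sqrt(3.0) / 3.0
    nx = max(1, round(lx / a))
    ny = max(1, round(ly / (a * math.sqrt(3.0))))
    spec = LatticeSpec(a=a, dz=dz, nx=nx, ny=ny)
    return SheetModel(species=species, positions=positions, layers=layers,
                      extents=(nx * a, ny * a * math.sqrt(3.0)), spec=spec, params=params)
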