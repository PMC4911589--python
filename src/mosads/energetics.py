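"""Protein-sheet nonbonded interaction energies with per-residue decomposition.

Pair energies are the 12-6 Lennard-Jones potential and truncated Coulomb:

    E_LJ(r)   = 4*eps_ij * [ (sig_ij/r)^12 - (sig_ij/r)^6 ]
    E_elec(r) = f * q_i * q_j / r,     f = 138.935458 kJ nm / (mol e^2)

summed over cross pairs within a cutoff (1.0 nm default, minimum image when
a box is present), with Lorentz-Berthelot or geometric combination rules.
Electrostatics are plain truncated Coulomb rather than a lattice-sum method:
the package evaluates interaction energies on stored frames, not forces for
dynamics.  An optional reaction-field correction is available for systems
where the truncation bias matters.

Energies are reported in kcal/mol (negative = attractive); an exact 4.184
kJ/kcal conversion is used internally.  Per-residue maps partition the group
totals exactly: each pair term is assigned to the group-A atom's residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mosads._geom import delta
from mosads.nanosheet import NonbondedParams
from mosads.trajio import Frame, Topology, TrajectoryHandle

__all__ = [
    "COULOMB_CONSTANT_KJ",
    "KCAL_PER_KJ",
    "EnergyBreakdown",
    "TailAverage",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "combine_lj",
    "interaction_energy",
    "energy_series",
    "per_residue_tail_means",
    "tail_average",
    "favorable_residues",
]

#: Coulomb prefactor 1/(4 pi eps0) in kJ nm / (mol e^2)
COULOMB_CONSTANT_KJ = 138.935458
#: exact thermochemical conversion
KCAL_PER_KJ = 1.0 / 4.184


@dataclass
class EnergyBreakdown:
    """Cross-group LJ and Coulomb energies (kcal/mol) for one frame."""

    e_vdw: float
    e_elec: float
    per_residue_vdw: dict
    per_residue_elec: dict
    cutoff: float
    time: float = 0.0  # ps

    def check_partition(self, tol: float = 1e-6) -> None:
        if abs(sum(self.per_residue_vdw.values()) - self.e_vdw) > tol:
            raise AssertionError("per-residue vdW terms do not sum to total")
        if abs(sum(self.per_residue_elec.values()) - self.e_elec) > tol:
            raise AssertionError("per-residue Coulomb terms do not sum to total")


@dataclass(frozen=True)
class TailAverage:
    """Mean and block-average standard error over a trailing time window."""

    mean: float
    uncertainty: float
    window_ns: float
    estimator: str = "block-se(5)"
    n_frames: int = 0


def lj_pair_energy(r: float, sigma_ij: float, eps_ij: float) -> float:
    """12-6 Lennard-Jones pair energy (kcal/mol) at separation r (nm)."""
    if r <= 0:
        raise ValueError(f"pair distance must be > 0, got r={r}")
    sr6 = (sigma_ij / r) ** 6
    return 4.0 * eps_ij * (sr6 * sr6 - sr6)


def coulomb_pair_energy(r: float, qi: float, qj: float) -> float:
    """Truncated-Coulomb pair energy (kcal/mol) at separation r (nm), charges in e."""
    if r <= 0:
        raise ValueError(f"pair distance must be > 0, got r={r}")
    return COULOMB_CONSTANT_KJ * qi * qj / r * KCAL_PER_KJ


def combine_lj(sigma_i, sigma_j, eps_i, eps_j, rule: str = "lorentz-berthelot"):
    """Cross LJ parameters: arithmetic/geometric sigma, geometric epsilon."""
    if rule == "lorentz-berthelot":
        sigma = 0.5 * (np.asarray(sigma_i) + np.asarray(sigma_j))
    elif rule == "geometric":
        sigma = np.sqrt(np.asarray(sigma_i) * np.asarray(sigma_j))
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    eps = np.sqrt(np.asarray(eps_i) * np.asarray(eps_j))
    return sigma, eps


def _atom_params(topology: Topology, indices: np.ndarray, params: NonbondedParams):
    sig = np.empty(len(indices))
    eps = np.empty(len(indices))
    q = np.empty(len(indices))
    for k, i in enumerate(indices):
        key = str(topology.lj_types[i])
        entry = params.species.get(key) or params.species.get(str(topology.elements[i]))
        if entry is None:
            raise KeyError(f"no nonbonded parameters for atom type {key!r} (atom {i}, {topology.names[i]})")
        sig[k], eps[k], q[k] = entry.sigma, entry.epsilon, entry.charge
    return sig, eps, q


def interaction_energy(frame: Frame, topology: Topology, group_a: np.ndarray,
                       group_b: np.ndarray, params: NonbondedParams, rc: float = 1.0,
                       reaction_field: bool = False, eps_rf: float = 78.5) -> EnergyBreakdown:
    """Cross-group LJ + Coulomb energies within cutoff, per-residue resolved.

    ``group_a`` and ``group_b`` are disjoint atom index arrays (conventionally
    protein and sheet).  Per-residue maps are keyed by the residue ids of
    group-A atoms and partition the totals exactly.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("energy groups overlap; they must be disjoint")
    sig_a, eps_a, q_a = _atom_params(topology, group_a, params)
    sig_b, eps_b, q_b = _atom_params(topology, group_b, params)

    d = delta(frame.positions[group_a], frame.positions[group_b], frame.box)
    r = np.sqrt((d * d).sum(axis=-1))
    within = r <= rc
    sig_ij, eps_ij = combine_lj(sig_a[:, None], sig_b[None, :], eps_a[:, None],
                                eps_b[None, :], params.combination_rule)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (sig_ij / r) ** 6
        e_lj = np.where(within, 4.0 * eps_ij * (sr6 * sr6 - sr6), 0.0)
        inv_r = np.where(within, 1.0 / r, 0.0)
    qq = q_a[:, None] * q_b[None, :]
    e_el = COULOMB_CONSTANT_KJ * qq * inv_r * KCAL_PER_KJ
    if reaction_field:
        # reaction-field correction: E = f q q (1/r + k_rf r^2 - c_rf), applied within rc
        k_rf = (eps_rf - 1.0) / (2.0 * eps_rf + 1.0) / rc**3
        c_rf = 1.0 / rc + k_rf * rc**2
        e_el = e_el + COULOMB_CONSTANT_KJ * qq * np.where(within, k_rf * r**2 - c_rf, 0.0) * KCAL_PER_KJ

    per_vdw: dict[int, float] = {}
    per_elec: dict[int, float] = {}
    row_vdw = e_lj.sum(axis=1)
    row_elec = e_el.sum(axis=1)
    for k, i in enumerate(group_a):
        resid = int(topology.resids[i])
        per_vdw[resid] = per_vdw.get(resid, 0.0) + float(row_vdw[k])
        per_elec[resid] = per_elec.get(resid, 0.0) + float(row_elec[k])
    return EnergyBreakdown(
        e_vdw=float(e_lj.sum()), e_elec=float(e_el.sum()),
        per_residue_vdw=per_vdw, per_residue_elec=per_elec,
        cutoff=rc, time=frame.time,
    )


def energy_series(traj: TrajectoryHandle, group_a: np.ndarray, group_b: np.ndarray,
                  params: NonbondedParams, rc: float = 1.0,
                  per_residue: bool = False, **kwargs) -> pd.DataFrame:
    """Interaction energies over a trajectory.

    Columns: ``time_ns``, ``e_vdw``, ``e_elec`` and, with ``per_residue=True``,
    one ``vdw_<resid>`` column per group-A residue.
    """
    rows = []
    for frame in traj:
        eb = interaction_energy(frame, traj.topology, group_a, group_b, params, rc=rc, **kwargs)
        row = {"time_ns": eb.time / 1000.0, "e_vdw": eb.e_vdw, "e_elec": eb.e_elec}
        if per_residue:
            row.update({f"vdw_{rid}": v for rid, v in sorted(eb.per_residue_vdw.items())})
        rows.append(row)
    return pd.DataFrame(rows)


def tail_average(times_ns: np.ndarray, values: np.ndarray, window_ns: float = 100.0,
                 n_blocks: int = 5) -> TailAverage:
    """Mean over the trailing ``window_ns`` with block-average standard error.

    Frames with t >= t_end - window are split into ``n_blocks`` contiguous
    blocks; the uncertainty is the standard error of the block means.  A
    window exceeding the trajectory span raises.
    """
    times_ns = np.asarray(times_ns, dtype=float)
    values = np.asarray(values, dtype=float)
    span = times_ns[-1] - times_ns[0]
    if window_ns > span + 1e-12:
        raise ValueError(f"tail window {window_ns} ns exceeds trajectory span {span:.6g} ns")
    mask = times_ns >= times_ns[-1] - window_ns
    tail = values[mask]
    mean = float(tail.mean())
    blocks = [b for b in np.array_split(tail, n_blocks) if len(b)]
    if len(blocks) > 1:
        bm = np.array([b.mean() for b in blocks])
        unc = float(bm.std(ddof=1) / math.sqrt(len(bm)))
    else:
        unc = 0.0
    return TailAverage(mean=mean, uncertainty=unc, window_ns=window_ns,
                       estimator=f"block-se({n_blocks})", n_frames=int(mask.sum()))


def per_residue_tail_means(series: pd.DataFrame, window_ns: float = 100.0,
                           n_blocks: int = 5) -> dict:
    """Tail averages of the ``vdw_<resid>`` columns of an energy series."""
    out = {}
    t = series["time_ns"].to_numpy()
    for col in series.columns:
        if col.startswith("vdw_"):
            resid = int(col.split("_", 1)[1])
            out[resid] = tail_average(t, series[col].to_numpy(), window_ns, n_blocks)
    return out


def favorable_residues(per_residue_means: dict, threshold: float = -20.0) -> list:
    """Residues with mean vdW energy below ``threshold`` kcal/mol, most favorable first."""
    vals = {rid: (m.mean if isinstance(m, TailAverage) else float(m))
            for rid, m in per_residue_means.items()}
    hits = [rid for rid, v in vals.items() if v < threshold]
    return sorted(hits, key=lambda rid: vals[rid])
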