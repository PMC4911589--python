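"""Interfacial hydration and adsorption kinetics.

First-solvation-shell (FSS) water counts track nanoscale drying: expulsion
of water from between a hydrophobic residue and the sheet surface signals
the dewetting that accelerates adsorption.  The FSS of a residue is the set
of water molecules whose oxygen lies within a cutoff (0.45 nm default) of
any heavy atom of the residue (sidechain-only by default).  The module also
derives per-residue first-contact (onset) times with a persistence
criterion, the helix anchoring order, and the correlation between surface
adsorption and loss of native structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mosads._geom import distance_matrix
from mosads.metrics import HelixSpans
from mosads.trajio import Frame, Topology, TrajectoryHandle

logger = logging.getLogger(__name__)

__all__ = [
    "ContactOnset",
    "fss_water_count",
    "fss_series",
    "interfacial_water_count",
    "first_contact_time",
    "anchoring_order",
    "adsorption_denaturation_correlation",
]


@dataclass(frozen=True)
class ContactOnset:
    """First persistent surface-contact time of one residue (ns; None if never)."""

    resid: int
    onset_ns: float | None
    persistence_k: int


def _water_oxygens(topology: Topology) -> np.ndarray:
    return np.flatnonzero(topology.water & np.array([e.upper() == "O" for e in topology.elements]))


def _residue_part(topology: Topology, resid: int, part: str) -> np.ndarray:
    if part == "sidechain":
        mask = topology.sidechain & topology.heavy
    elif part == "all":
        mask = topology.protein & topology.heavy
    else:
        raise ValueError(f"part must be 'sidechain' or 'all', got {part!r}")
    return np.flatnonzero(mask & (topology.resids == resid))


def fss_water_count(frame: Frame, topology: Topology, resid: int,
                    rc_fss: float = 0.45, part: str = "sidechain") -> int:
    """Number of waters in the first solvation shell of a residue.

    Counts water oxygens within ``rc_fss`` of any heavy atom of the residue's
    selected part (minimum image if the frame has a box).
    """
    if rc_fss <= 0:
        raise ValueError(f"rc_fss must be > 0, got {rc_fss}")
    idx = _residue_part(topology, resid, part)
    if idx.size == 0:
        raise ValueError(
            f"residue {resid} has no heavy atoms in part {part!r} "
            "(glycine has no sidechain heavy atoms; use part='all')"
        )
    ox = _water_oxygens(topology)
    if ox.size == 0:
        return 0
    d = distance_matrix(frame.positions[ox], frame.positions[idx], frame.box)
    return int((d.min(axis=1) <= rc_fss).sum())


def fss_series(traj: TrajectoryHandle, resid: int, rc_fss: float = 0.45,
               part: str = "sidechain") -> pd.DataFrame:
    """FSS water count over time for one residue; columns time_ns, n_water."""
    rows = [(f.time / 1000.0, fss_water_count(f, traj.topology, resid, rc_fss, part)) for f in traj]
    return pd.DataFrame(rows, columns=["time_ns", "n_water"])


def interfacial_water_count(frame: Frame, topology: Topology, resid: int,
                            top_s_z: float, pad_xy: float = 0.3) -> int:
    """Waters in the prism between the sheet's top S plane and a residue.

    Counts water oxygens with z between ``top_s_z`` and the residue's lowest
    heavy-atom z, and with xy inside the residue's heavy-atom bounding box
    expanded by ``pad_xy`` per side.  A residue entirely below the plane is a
    geometry violation and raises.
    """
    idx = _residue_part(topology, resid, "all")
    if idx.size == 0:
        raise ValueError(f"residue {resid} has no heavy atoms")
    res_pos = frame.positions[idx]
    z_low = float(res_pos[:, 2].min())
    if z_low <= top_s_z:
        raise ValueError(
            f"residue {resid} lies below the top S plane (z={z_low:.3f} <= {top_s_z:.3f} nm)"
        )
    xy_min = res_pos[:, :2].min(axis=0) - pad_xy
    xy_max = res_pos[:, :2].max(axis=0) + pad_xy
    ox = _water_oxygens(topology)
    if ox.size == 0:
        return 0
    w = frame.positions[ox]
    inside = (
        (w[:, 2] > top_s_z) & (w[:, 2] < z_low)
        & (w[:, 0] >= xy_min[0]) & (w[:, 0] <= xy_max[0])
        & (w[:, 1] >= xy_min[1]) & (w[:, 1] <= xy_max[1])
    )
    return int(inside.sum())


def first_contact_time(contact_series: pd.DataFrame, persistence_k: int = 5) -> list:
    """Per-residue onset times from a per-residue contact-count table.

    ``contact_series`` is indexed by ``time_ns`` with one column per residue
    id (as produced by :func:`mosads.metrics.per_residue_contact_series`).
    The onset is the earliest time t such that the count is positive for at
    least ``persistence_k`` consecutive frames starting at t; residues that
    never satisfy this get ``None``.
    """
    if len(contact_series) == 0:
        raise ValueError("empty contact series")
    if persistence_k < 1:
        raise ValueError(f"persistence_k must be >= 1, got {persistence_k}")
    times = contact_series.index.to_numpy(dtype=float)
    out = []
    for col in contact_series.columns:
        vals = contact_series[col].to_numpy() > 0
        onset = None
        run = 0
        for i, v in enumerate(vals):
            run = run + 1 if v else 0
            if run >= persistence_k:
                onset = float(times[i - persistence_k + 1])
                break
        out.append(ContactOnset(resid=int(col), onset_ns=onset, persistence_k=persistence_k))
    return out


def anchoring_order(onsets, spans: HelixSpans | None = None) -> list:
    """Helices ordered by earliest residue onset; no-onset helices last.

    Returns helix indices (1, 2, 3).  Ties are broken by helix index
    (lower index first).  Helices whose residues never make persistent
    contact sort after all contacting helices.
    """
    spans = spans or HelixSpans()
    first: dict[int, float | None] = {1: None, 2: None, 3: None}
    for o in onsets:
        h = spans.helix_of(o.resid)
        if h is None or o.onset_ns is None:
            continue
        if first[h] is None or o.onset_ns < first[h]:
            first[h] = o.onset_ns
    if all(v is None for v in first.values()):
        raise ValueError("no helix has a contact onset")
    return sorted(first, key=lambda h: (first[h] is None, first[h] if first[h] is not None else 0.0, h))


def adsorption_denaturation_correlation(contact_counts, q_values) -> float | None:
    """Pearson correlation between surface contacts and native-structure loss.

    Computes corr(contacts, 1 - Q) on a shared time grid.  Returns None (with
    a warning) when either series is constant, where the coefficient is
    undefined.
    """
    c = np.asarray(contact_counts, dtype=float)
    q = np.asarray(q_values, dtype=float)
    if c.shape != q.shape:
        raise ValueError(f"series lengths differ: {c.shape} vs {q.shape}")
    loss = 1.0 - q
    if np.ptp(c) == 0 or np.ptp(loss) == 0:
        warnings.warn("constant series: adsorption-denaturation correlation undefined")
        return None
    from scipy.stats import pearsonr

    return float(pearsonr(c, loss).statistic)
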