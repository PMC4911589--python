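"""Deterministic toy adsorption trajectories with exact ground truth.

Production adsorption trajectories (hundreds of ns of all-atom MD) are not
reproducible at desk scale, so every analysis stage in this package is
validated against synthetic trajectories whose answers are known by
construction.  The generator emulates the phenomenology of a three-helix
mini-protein adsorbing onto a flat monolayer:

* a rigid-body vertical approach following a programmed gap(t) schedule
  (the gap never drops below the contact cutoff, so no residue touches the
  sheet except by design);
* per-residue contact onsets: at its onset time a residue's pseudo-sidechain
  is displaced to 0.45 nm above the top sulfur plane, guaranteeing a heavy
  atom within the 0.6 nm contact cutoff, and stays there;
* progressive helix melting: at its melt time a residue's backbone (phi,
  psi) switch from the ideal helix (-57, -47) to coil (-120, +120) by
  rotating all downstream atoms, leaving every other residue's internal
  geometry untouched;
* explicitly placed first-solvation-shell waters (single-site oxygens) with
  exact per-residue counts, re-sampled each frame from a stream seeded by
  (seed, frame) so access order cannot change results.

The protein scaffold is built by internal-coordinate (NeRF) chain extension
with ideal backbone geometry; sidechains are a C-beta plus a pseudo-atom
cluster sized to the residue's true heavy-atom count, which is all the
contact, energy and hydration metrics need.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from mosads._geom import dihedral, rotate_about_axis
from mosads.metrics import HelixSpans
from mosads.nanosheet import SheetModel
from mosads.trajio import Frame, Topology, TrajectoryHandle

__all__ = [
    "HP35_SEQUENCE",
    "HP35_START_RESID",
    "ScenarioSpec",
    "GroundTruth",
    "build_ideal_bundle",
    "melt_helix",
    "generate_trajectory",
    "melt_times_from_fraction",
    "random_scenario",
]

#: villin headpiece subdomain, residues 42-76 of PDB entry 1YRF
HP35_SEQUENCE = "LSDEDFKAVFGMTRSAFANLPLWKQQNLKKEKGLF"
HP35_START_RESID = 42

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
#: sidechain heavy-atom counts (C-beta included)
SIDECHAIN_HEAVY = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 0, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}

# ideal backbone internal coordinates (nm, degrees)
_R_N_CA, _R_CA_C, _R_C_N, _R_C_O, _R_CA_CB = 0.1458, 0.1525, 0.1329, 0.1231, 0.1530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.5
HELIX_PHI, HELIX_PSI = -57.0, -47.0
COIL_PHI, COIL_PSI = -120.0, 120.0


def _wrap(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _place(a, b, c, r, theta_deg, chi_deg):
    """NeRF: position of D with |CD| = r, angle(BCD) = theta, torsion(ABCD) = chi."""
    theta = math.radians(theta_deg)
    chi = -math.radians(chi_deg)  # sign matched to the IUPAC torsion convention
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -r * math.cos(theta),
        r * math.sin(theta) * math.cos(chi),
        r * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _pseudo_directions(k: int) -> np.ndarray:
    """k deterministic unit vectors (golden-spiral points on a sphere)."""
    idx = np.arange(k) + 0.5
    phi = np.arccos(1.0 - 2.0 * idx / k)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * idx
    return np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def build_ideal_bundle(sequence: str = HP35_SEQUENCE, start_resid: int = HP35_START_RESID,
                       spans: HelixSpans | None = None) -> tuple[Topology, Frame]:
    """Build an all-heavy-atom scaffold with ideal helix geometry inside the spans.

    Backbone N/CA/C/O are chain-extended with (phi, psi) = (-57, -47) inside
    the helix spans and extended-coil (-120, +120) elsewhere; sidechains are
    C-beta plus a pseudo-atom cluster ("X2", "X3", ...) sized so each residue
    carries its true sidechain heavy-atom count.
    """
    spans = spans or HelixSpans()
    n = len(sequence)
    resids = np.arange(start_resid, start_resid + n)
    span_set = set(spans.residues())
    for r in span_set:
        if r < start_resid or r >= start_resid + n:
            raise ValueError(f"helix span residue {r} outside sequence range {start_resid}-{start_resid + n - 1}")
    phis = [HELIX_PHI if r in span_set else COIL_PHI for r in resids]
    psis = [HELIX_PSI if r in span_set else COIL_PSI for r in resids]

    n_pos = np.zeros((n, 3))
    ca_pos = np.zeros((n, 3))
    c_pos = np.zeros((n, 3))
    # residue 0 seeded in the xy-plane
    n_pos[0] = (0.0, 0.0, 0.0)
    ca_pos[0] = (_R_N_CA, 0.0, 0.0)
    th = math.radians(_A_N_CA_C)
    c_pos[0] = ca_pos[0] + _R_CA_C * np.array([math.cos(math.pi - th), math.sin(math.pi - th), 0.0])
    for i in range(1, n):
        n_pos[i] = _place(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1], _R_C_N, _A_CA_C_N, psis[i - 1])
        ca_pos[i] = _place(ca_pos[i - 1], c_pos[i - 1], n_pos[i], _R_N_CA, _A_C_N_CA, 180.0)
        c_pos[i] = _place(c_pos[i - 1], n_pos[i], ca_pos[i], _R_CA_C, _A_N_CA_C, phis[i])

    names, elements, res_ids, resnames, coords = [], [], [], [], []
    for i, (resid, aa) in enumerate(zip(resids, sequence)):
        res3 = _THREE.get(aa.upper())
        if res3 is None:
            raise ValueError(f"unknown residue code {aa!r}")
        atoms = [("N", "N", n_pos[i]), ("CA", "C", ca_pos[i]), ("C", "C", c_pos[i])]
        # carbonyl O anti to the next amide nitrogen
        o = _place(n_pos[i], ca_pos[i], c_pos[i], _R_C_O, _A_CA_C_O, psis[i] + 180.0)
        atoms.append(("O", "O", o))
        k = SIDECHAIN_HEAVY[res3]
        if k > 0:
            ref = c_pos[i - 1] if i > 0 else n_pos[i] + np.array([0.0, 0.0, 1.0])
            cb = _place(ref, n_pos[i], ca_pos[i], _R_CA_CB, _A_N_CA_CB, phis[i] - 122.5)
            atoms.append(("CB", "C", cb))
            if k > 1:
                for j, u in enumerate(_pseudo_directions(k - 1), start=2):
                    atoms.append((f"X{j}", "C", cb + 0.125 * u))
        for name, elem, xyz in atoms:
            names.append(name)
            elements.append(elem)
            res_ids.append(int(resid))
            resnames.append(res3)
            coords.append(xyz)

    top = Topology(names=names, elements=elements, resids=res_ids,
                   resnames=resnames, chains=["A"] * len(names))
    return top, Frame(np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# dihedral manipulation

def _backbone_index(topology: Topology):
    """resid -> {'N': i, 'CA': i, 'C': i, 'O': i or None}."""
    out = {}
    prot = topology.protein
    for resid in topology.protein_resids():
        sel = np.flatnonzero(prot & (topology.resids == resid))
        entry = {}
        for nm in ("N", "CA", "C", "O"):
            hits = [int(i) for i in sel if str(topology.names[i]).upper() == nm]
            entry[nm] = hits[0] if hits else None
        out[int(resid)] = entry
    return out


def _set_dihedral(pos, i_a, i_b, i_c, i_d, moving, target: float) -> None:
    start = pos[moving].copy()
    delta = _wrap(target - dihedral(pos[i_a], pos[i_b], pos[i_c], pos[i_d]))
    for sign in (1.0, -1.0):  # rotation sense probed, not assumed
        pos[moving] = rotate_about_axis(start, pos[i_b], pos[i_c] - pos[i_b], sign * delta)
        if abs(_wrap(dihedral(pos[i_a], pos[i_b], pos[i_c], pos[i_d]) - target)) < 1e-6:
            return
    pos[moving] = start
    raise RuntimeError("dihedral rotation did not reach target angle")


def melt_helix(frame: Frame, topology: Topology, residues,
               phi: float = COIL_PHI, psi: float = COIL_PSI) -> Frame:
    """Set listed residues' backbone (phi, psi) to coil by rotating downstream atoms.

    Each rotation leaves all bond lengths and angles unchanged; only the
    targeted residue's own dihedrals change (phi(i) rotates everything past
    the alpha carbon, psi(i) rotates the carbonyl O and all later residues).
    """
    bb = _backbone_index(topology)
    resids_sorted = topology.protein_resids()
    pos = frame.positions.copy()
    prot_idx = np.flatnonzero(topology.protein)
    for resid in sorted(int(r) for r in residues):
        if resid not in bb:
            raise ValueError(f"residue {resid} not in topology")
        e = bb[resid]
        if e["N"] is None or e["CA"] is None or e["C"] is None:
            raise ValueError(f"residue {resid} lacks backbone atoms")
        later = prot_idx[topology.resids[prot_idx] > resid]
        # phi: needs C of the previous residue
        prev = resid - 1
        if prev in bb and bb[prev]["C"] is not None:
            own = np.flatnonzero(topology.protein & (topology.resids == resid)
                                 & (topology.names != "N"))
            moving = np.concatenate([own, later])
            _set_dihedral(pos, bb[prev]["C"], e["N"], e["CA"], e["C"], moving, phi)
        # psi: needs N of the next residue
        nxt = resid + 1
        if nxt in bb and bb[nxt]["N"] is not None:
            own_o = np.flatnonzero(topology.protein & (topology.resids == resid)
                                   & (topology.names == "O"))
            moving = np.concatenate([own_o, later])
            _set_dihedral(pos, e["N"], e["CA"], e["C"], bb[nxt]["N"], moving, psi)
    return Frame(pos, time=frame.time, box=None if frame.box is None else frame.box.copy())


# ---------------------------------------------------------------------------
# scenario specification

@dataclass
class ScenarioSpec:
    """Recipe for one synthetic adsorption trajectory.

    ``gap_schedule`` is a piecewise-linear table of (time ns, gap nm); every
    gap must exceed the 0.6 nm contact cutoff so that surface contacts are
    created only by the programmed onsets.  ``onsets`` maps residue id to
    first-contact time (ns); ``melt_times`` maps residue id to the time its
    backbone switches to coil; ``shell_waters`` maps residue id to
    (water count, placement radius nm).
    """

    sequence: str = HP35_SEQUENCE
    start_resid: int = HP35_START_RESID
    spans: HelixSpans = field(default_factory=HelixSpans)
    n_frames: int = 120
    frame_spacing_ps: float = 20.0
    gap_schedule: tuple = ((0.0, 1.6), (0.4, 0.8))
    onsets: dict = field(default_factory=lambda: {
        55: 0.40, 58: 0.50, 60: 0.45, 61: 0.55,   # helix 2 anchors first
        47: 1.00, 50: 1.20,                        # then helix 1
        64: 1.60, 62: 1.70,                        # then helix 3
    })
    melt_times: dict = field(default_factory=lambda: {
        **{r: 1.2 for r in range(54, 62)},         # helix 2 melts first
        **{r: 1.8 for r in range(62, 75)},         # then helix 3; helix 1 stays
    })
    shell_waters: dict = field(default_factory=lambda: {64: (12, 0.42), 55: (10, 0.42)})
    fss_rc: float = 0.45
    contact_rc: float = 0.6
    seed: int = 0

    @property
    def t_end_ns(self) -> float:
        return (self.n_frames - 1) * self.frame_spacing_ps / 1000.0

    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_spacing_ps / 1000.0

    def gap_at(self, t_ns: float) -> float:
        pts = sorted(self.gap_schedule)
        ts = np.array([p[0] for p in pts])
        gs = np.array([p[1] for p in pts])
        return float(np.interp(t_ns, ts, gs))

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_spacing_ps <= 0:
            raise ValueError("frame_spacing_ps must be > 0")
        lo, hi = self.start_resid, self.start_resid + len(self.sequence) - 1
        for t in self.times_ns():
            if self.gap_at(float(t)) <= self.contact_rc + 0.05:
                raise ValueError(
                    f"gap schedule reaches {self.gap_at(float(t)):.3f} nm at t={t:.3f} ns; "
                    f"it must stay above the contact cutoff ({self.contact_rc} nm) plus margin"
                )
        for resid, t in self.onsets.items():
            if not (lo <= resid <= hi):
                raise ValueError(f"onset residue {resid} outside sequence {lo}-{hi}")
            if not (0.0 <= t <= self.t_end_ns):
                raise ValueError(f"onset time {t} ns for residue {resid} outside trajectory span")
        for resid, t in self.melt_times.items():
            if not (lo <= resid <= hi):
                raise ValueError(f"melt residue {resid} outside sequence {lo}-{hi}")
            if t < 0:
                raise ValueError(f"negative melt time for residue {resid}")
        for resid, (count, radius) in self.shell_waters.items():
            if count < 0 or radius <= 0.30:
                raise ValueError(f"invalid shell-water spec for residue {resid}: ({count}, {radius})")
        # onsets and shells act on pseudo-sidechains: glycine has none
        for resid in list(self.onsets) + list(self.shell_waters):
            aa = self.sequence[resid - self.start_resid]
            if aa.upper() == "G":
                raise ValueError(f"residue {resid} is glycine: no sidechain to pin or hydrate")


@dataclass
class GroundTruth:
    """Exact per-frame answers for every analysis stage of a scenario."""

    times_ns: np.ndarray
    helix_fraction: np.ndarray         # per frame, run-scan over span residues
    helix_denominator: int
    q: np.ndarray                      # per frame, exhaustive recount
    n_native: int
    onsets: dict                       # resid -> ns (programmed)
    anchoring_order: list              # helix ids, earliest first
    fss_counts: dict                   # resid -> count (constant per frame)
    contact_residues: dict             # frame index -> sorted resid list in contact

    def to_json(self, path) -> None:
        payload = {
            "times_ns": self.times_ns.tolist(),
            "helix_fraction": self.helix_fraction.tolist(),
            "helix_denominator": self.helix_denominator,
            "q": self.q.tolist(),
            "n_native": self.n_native,
            "onsets": {str(k): v for k, v in self.onsets.items()},
            "anchoring_order": self.anchoring_order,
            "fss_counts": {str(k): v for k, v in self.fss_counts.items()},
            "contact_residues": {str(k): v for k, v in self.contact_residues.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def melt_times_from_fraction(fraction_schedule, spans: HelixSpans | None = None) -> dict:
    """Convert a global melt-fraction schedule m(t) into per-residue melt times.

    ``fraction_schedule`` is a list of (time ns, fraction) pairs with
    non-decreasing fractions.  At fraction m the first ``round(m * n_span)``
    span residues melt, in the fixed order helix 2, then helix 3, then
    helix 1 (each N- to C-terminal) — the unfolding order observed for this
    fold on the sheet.
    """
    spans = spans or HelixSpans()
    order = (
        list(range(spans.helix2[0], spans.helix2[1] + 1))
        + list(range(spans.helix3[0], spans.helix3[1] + 1))
        + list(range(spans.helix1[0], spans.helix1[1] + 1))
    )
    n = len(order)
    melt: dict[int, float] = {}
    prev_m = 0.0
    for t, m in sorted(fraction_schedule):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"melt fraction {m} outside [0, 1]")
        if m < prev_m:
            raise ValueError("melt fraction schedule must be non-decreasing")
        k = round(m * n)
        for resid in order[:k]:
            melt.setdefault(resid, float(t))
        prev_m = m
    return melt


# ---------------------------------------------------------------------------
# generation

def _sheet_layer_reduction(protein_xy, sheet: SheetModel):
    """Per protein atom: min squared xy-distance to each sheet layer, plus layer z."""
    layer_names = ("S_top", "Mo", "S_bottom")
    zs, dxy2 = [], []
    for layer in layer_names:
        pts = sheet.positions[sheet.layers == layer]
        zs.append(float(pts[0, 2]))
        d = protein_xy[:, None, :] - pts[None, :, :2]
        dxy2.append((d * d).sum(axis=-1).min(axis=1))
    return np.array(zs), np.stack(dxy2, axis=1)  # (3,), (n_atoms, 3)


def _rigid_place_z(positions, heavy_mask, sheet: SheetModel, gap: float) -> np.ndarray:
    """Translate positions along z so the min heavy-atom/sheet distance equals gap."""
    pos = positions.copy()
    zs, dxy2 = _sheet_layer_reduction(pos[heavy_mask, :2], sheet)
    pz = pos[heavy_mask, 2]

    def realized(shift):
        dz = pz[:, None] + shift - zs[None, :]
        return math.sqrt(float((dxy2 + dz * dz).min()))

    top_z = zs.max()
    base = (top_z + gap) - pz.min()
    lo, hi = base - gap, base
    for _ in range(200):
        if realized(hi) >= gap:
            break
        hi += 0.5 * gap
    for _ in range(200):
        if realized(lo) <= gap:
            break
        lo -= 0.25 * gap
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if realized(mid) < gap:
            lo = mid
        else:
            hi = mid
    pos[:, 2] += hi
    return pos


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    """Deterministic per-frame stream from a stable hash of (seed, frame)."""
    digest = hashlib.sha256(f"{seed}:{frame_index}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _brute_native_pairs(topology: Topology, frame: Frame, rc: float, min_sep: int):
    """Exhaustive residue-pair contact scan over all heavy atoms (oracle code path)."""
    heavy = topology.heavy & topology.protein
    resids = topology.protein_resids()
    atoms = {int(r): np.flatnonzero(heavy & (topology.resids == r)) for r in resids}
    pairs = []
    for a, i in enumerate(resids):
        for j in resids[a + 1:]:
            if j - i < min_sep:
                continue
            pi = frame.positions[atoms[int(i)]]
            pj = frame.positions[atoms[int(j)]]
            dmin = np.sqrt(((pi[:, None, :] - pj[None, :, :]) ** 2).sum(-1)).min()
            if dmin <= rc:
                pairs.append((int(i), int(j)))
    return pairs, atoms


def _truth_helix_fraction(spans: HelixSpans, melted: set) -> tuple[float, int]:
    """Run-scan oracle: fraction of span residues in >=4-long unmelted runs.

    Runs are chain-wide: adjacent spans (helix 2 ends at 61, helix 3 starts
    at 62) form one contiguous helical stretch when both are intact.
    """
    span_res = sorted(int(r) for r in spans.residues())
    flags = [r not in melted for r in span_res]
    denom = len(span_res)
    helical = 0
    i = 0
    while i < denom:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < denom and flags[j + 1] and span_res[j + 1] == span_res[j] + 1:
            j += 1
        if j - i + 1 >= 4:
            helical += j - i + 1
        i = j + 1
    return helical / denom, denom


def generate_trajectory(spec: ScenarioSpec, sheet: SheetModel) -> tuple[TrajectoryHandle, GroundTruth]:
    """Generate a synthetic adsorption trajectory and its exact ground truth.

    Returns an in-memory :class:`TrajectoryHandle` over protein + sheet +
    shell-water frames, and a :class:`GroundTruth` whose Q(t) was computed by
    an exhaustive residue-pair recount at generation time.
    """
    spec.validate()
    bundle_top, bundle_frame = build_ideal_bundle(spec.sequence, spec.start_resid, spec.spans)

    # combined topology: protein, sheet (one MOS residue), shell waters
    n_w = sum(c for c, _ in spec.shell_waters.values())
    n_s = sheet.n_atoms
    names = list(bundle_top.names) + list(np.where(sheet.species == "Mo", "MO", "S")) + ["OW"] * n_w
    elements = list(bundle_top.elements) + list(sheet.species) + ["O"] * n_w
    resids = list(bundle_top.resids) + [1] * n_s + list(range(1, n_w + 1))
    resnames = list(bundle_top.resnames) + ["MOS"] * n_s + ["SOL"] * n_w
    chains = list(bundle_top.chains) + ["M"] * n_s + ["W"] * n_w
    charges = np.zeros(len(names))
    if sheet.params is not None:
        charges[bundle_top.n_atoms: bundle_top.n_atoms + n_s] = [sheet.params[s].charge for s in sheet.species]
    topology = Topology(names=names, elements=elements, resids=resids,
                        resnames=resnames, chains=chains, charges=charges)

    n_p = bundle_top.n_atoms
    heavy_mask = bundle_top.heavy
    prot_resids = bundle_top.protein_resids()
    sc_heavy = {
        int(r): np.flatnonzero(bundle_top.sidechain & heavy_mask & (bundle_top.resids == r))
        for r in prot_resids
    }
    # waters of one hydrated residue must stay outside the FSS of every other
    # hydrated residue, so the per-residue counts are unambiguous
    shell_res = sorted(spec.shell_waters)
    other_heavy = {
        int(r): np.flatnonzero(
            bundle_top.protein & heavy_mask
            & np.isin(bundle_top.resids, [s for s in shell_res if s != r])
        )
        for r in shell_res
    }
    top_s_z = sheet.top_s_z
    sheet_pos = sheet.positions
    sheet_center = 0.5 * (sheet_pos.min(axis=0)[:2] + sheet_pos.max(axis=0)[:2])
    box = np.array([
        max(sheet.extents[0], sheet.extents[1]) * 3.0 + 2.0,
        max(sheet.extents[0], sheet.extents[1]) * 3.0 + 2.0,
        20.0,
    ])  # generous: minimum image never engages at these separations

    # native-contact reference: the un-melted bundle itself
    native_pairs, _ = _brute_native_pairs(bundle_top, bundle_frame, spec.contact_rc, 3)
    if not native_pairs:
        raise RuntimeError("ideal bundle has no native contacts; cannot define Q")

    times = spec.times_ns()
    frames, q_truth, helix_truth, contact_truth = [], [], [], {}
    denom = len(spec.spans.residues())
    for fi, t in enumerate(times):
        melted = {r for r, mt in spec.melt_times.items() if mt <= t}
        conf = melt_helix(bundle_frame, bundle_top, melted) if melted else bundle_frame.copy()
        pos = conf.positions

        # rigid placement: center over the sheet, set the heavy-atom gap
        centroid_xy = pos[heavy_mask, :2].mean(axis=0)
        pos[:, :2] += sheet_center - centroid_xy
        pos = _rigid_place_z(pos, heavy_mask, sheet, spec.gap_at(float(t)))

        # pin onset residues: move the sidechain so its lowest atom sits
        # 0.45 nm above the nearest top-sulfur site (contact guaranteed)
        in_contact = []
        s_top_pos = sheet_pos[sheet.layers == "S_top"]
        for resid, onset in sorted(spec.onsets.items()):
            if onset <= t and sc_heavy[resid].size:
                idx = sc_heavy[resid]
                low = idx[np.argmin(pos[idx, 2])]
                near = s_top_pos[np.argmin(((s_top_pos[:, :2] - pos[low, :2]) ** 2).sum(axis=1))]
                pos[idx] += (near + [0.0, 0.0, 0.45]) - pos[low]
                in_contact.append(resid)
        contact_truth[fi] = sorted(in_contact)

        # exhaustive Q recount on the placed protein conformation
        prot_frame = Frame(pos, time=float(t) * 1000.0)
        formed = 0
        heavy_atoms = {int(r): np.flatnonzero(bundle_top.protein & heavy_mask & (bundle_top.resids == r))
                       for r in prot_resids}
        for i, j in native_pairs:
            pi = pos[heavy_atoms[i]]
            pj = pos[heavy_atoms[j]]
            if np.sqrt(((pi[:, None, :] - pj[None, :, :]) ** 2).sum(-1)).min() <= spec.contact_rc:
                formed += 1
        q_truth.append(formed / len(native_pairs))
        helix_truth.append(_truth_helix_fraction(spec.spans, melted)[0])

        # shell waters: exact counts, rejection-sampled, per-frame stream
        rng = _frame_rng(spec.seed, fi)
        water_pos = []
        placed_all = [pos, sheet_pos]
        for resid in sorted(spec.shell_waters):
            count, radius = spec.shell_waters[resid]
            anchors = pos[sc_heavy[resid]]
            if anchors.shape[0] == 0:
                raise ValueError(f"shell-water residue {resid} has no sidechain heavy atoms")
            guard = pos[other_heavy[resid]]
            r_hi = min(radius, spec.fss_rc - 0.02)
            for _ in range(count):
                for attempt in range(4000):
                    anchor = anchors[rng.integers(len(anchors))]
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    cand = anchor + rng.uniform(0.28, r_hi) * u
                    near = np.vstack(placed_all + ([np.array(water_pos)] if water_pos else []))
                    d2 = ((near - cand) ** 2).sum(axis=1)
                    if d2.min() < 0.25**2:
                        continue
                    gd2 = ((guard - cand) ** 2).sum(axis=1)
                    if gd2.size and gd2.min() <= (spec.fss_rc + 0.005) ** 2:
                        continue
                    water_pos.append(cand)
                    break
                else:
                    raise RuntimeError(
                        f"could not place shell water near residue {resid} at frame {fi}; "
                        "reduce the count or enlarge the radius"
                    )
        water_arr = np.array(water_pos) if water_pos else np.zeros((0, 3))
        full = np.vstack([pos, sheet_pos, water_arr])
        frames.append(Frame(full, time=float(t) * 1000.0, box=box.copy()))

    order = _programmed_order(spec)
    truth = GroundTruth(
        times_ns=times,
        helix_fraction=np.array(helix_truth),
        helix_denominator=denom,
        q=np.array(q_truth),
        n_native=len(native_pairs),
        onsets=dict(spec.onsets),
        anchoring_order=order,
        fss_counts={r: c for r, (c, _) in spec.shell_waters.items()},
        contact_residues=contact_truth,
    )
    return TrajectoryHandle(topology, frames=frames), truth


def _programmed_order(spec: ScenarioSpec) -> list:
    # onsets become observable at the first frame at or after the programmed
    # time, so the order is defined on the frame grid (ties -> helix index)
    times = spec.times_ns()
    first: dict[int, float] = {}
    for resid, t in spec.onsets.items():
        h = spec.spans.helix_of(resid)
        if h is None:
            continue
        t_q = float(times[np.searchsorted(times, t)])
        if h not in first or t_q < first[h]:
            first[h] = t_q
    with_onset = sorted(first, key=lambda h: (first[h], h))
    without = [h for h in (1, 2, 3) if h not in first]
    return with_onset + without


def random_scenario(seed: int, n_frames: int = 30, frame_spacing_ps: float = 20.0) -> ScenarioSpec:
    """A randomized but always-valid scenario (for property and closure tests)."""
    rng = np.random.default_rng(seed)
    spans = HelixSpans()
    t_end = (n_frames - 1) * frame_spacing_ps / 1000.0
    seq, start = HP35_SEQUENCE, HP35_START_RESID
    all_res = np.array([r for r in spans.residues() if seq[r - start] != "G"])
    n_onset = int(rng.integers(2, 7))
    onset_res = rng.choice(all_res, size=n_onset, replace=False)
    onsets = {int(r): float(np.round(rng.uniform(0.05, 0.9) * t_end, 3)) for r in onset_res}
    melt = {}
    for lo, hi in (spans.helix2, spans.helix3, spans.helix1):
        if rng.random() < 0.7:
            mt = float(np.round(rng.uniform(0.2, 1.2) * t_end, 3))
            for r in range(lo, hi + 1):
                melt[r] = mt
    # hydrated residues kept >= 6 apart in sequence so their shells (guarded
    # to stay mutually exclusive) have room on the helical scaffold
    n_shell = int(rng.integers(1, 4))
    shell_res: list[int] = []
    for r in rng.permutation([int(x) for x in all_res]):
        if all(abs(r - s) >= 6 for s in shell_res):
            shell_res.append(int(r))
        if len(shell_res) == n_shell:
            break
    shell = {int(r): (int(rng.integers(2, 9)), 0.42) for r in shell_res}
    gap_hi = float(np.round(rng.uniform(1.2, 2.0), 2))
    gap_lo = float(np.round(rng.uniform(0.75, 1.0), 2))
    return ScenarioSpec(
        n_frames=n_frames,
        frame_spacing_ps=frame_spacing_ps,
        gap_schedule=((0.0, gap_hi), (0.3 * t_end, gap_lo)),
        onsets=onsets,
        melt_times=melt,
        shell_waters=shell,
        seed=int(seed),
    )
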