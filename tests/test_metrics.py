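"""Contact, native-contact/Q, helix, H-bond, bridge and composition metrics."""

import numpy as np
import pytest

from mosads.metrics import (
    HelixSpans,
    NativeContactSet,
    cation_pi,
    heavy_atom_contacts,
    helix_ratio,
    hbond_count,
    hydrophobic_fraction,
    native_contacts,
    q_fraction,
    salt_bridge,
)
from mosads.synthetic import melt_helix, melt_times_from_fraction
from mosads.trajio import Frame, Topology


def _point_frame(points, box=None):
    return Frame(np.asarray(points, dtype=float), box=box)


def _plain_topology(n, resid_of=None, resname="ALA"):
    resids = resid_of if resid_of is not None else [1] * n
    return Topology(names=["CB"] * n, elements=["C"] * n, resids=resids,
                    resnames=[resname] * n, chains=["A"] * n)


# ---------------------------------------------------------------------------
# heavy-atom contacts

def test_contact_cutoff_boundary():
    f = _point_frame([[0, 0, 0], [0.59, 0, 0]])
    assert heavy_atom_contacts(f, [0], [1], rc=0.6) == 1
    f2 = _point_frame([[0, 0, 0], [0.61, 0, 0]])
    assert heavy_atom_contacts(f2, [0], [1], rc=0.6) == 0


def test_contact_far_field_and_errors():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    f = _point_frame(np.vstack([pts, pts + 10.0]))
    assert heavy_atom_contacts(f, np.arange(10), np.arange(10, 20), rc=0.6) == 0
    with pytest.raises(ValueError, match="disjoint"):
        heavy_atom_contacts(f, [0, 1], [1, 2])
    with pytest.raises(ValueError, match="rc"):
        heavy_atom_contacts(f, [0], [1], rc=0.0)


@pytest.mark.parametrize("use_box", [False, True])
@pytest.mark.parametrize("pairs", [False, True])
def test_contacts_match_exhaustive_double_loop(use_box, pairs):
    rng = np.random.default_rng(42)
    for _ in range(25):
        n_a, n_b = rng.integers(5, 30, size=2)
        box = np.array([2.0, 2.0, 2.0]) if use_box else None
        pos = rng.uniform(0, 2.0, size=(n_a + n_b, 3))
        f = _point_frame(pos, box=box)
        got = heavy_atom_contacts(f, np.arange(n_a), np.arange(n_a, n_a + n_b),
                                  rc=0.6, pairs=pairs)
        count = 0
        for i in range(n_a):
            hit = 0
            for j in range(n_a, n_a + n_b):
                d = pos[i] - pos[j]
                if use_box:
                    d -= box * np.round(d / box)
                if np.linalg.norm(d) <= 0.6:
                    hit += 1
            count += hit if pairs else int(hit > 0)
        assert got == count


def test_contacts_rigid_motion_invariant():
    rng = np.random.default_rng(3)
    pos = rng.uniform(0, 2, size=(40, 3))
    f = _point_frame(pos)
    base = heavy_atom_contacts(f, np.arange(20), np.arange(20, 40), rc=0.6)
    # random rotation + translation applied to both sets together
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    moved = pos @ q + np.array([3.0, -1.0, 2.0])
    assert heavy_atom_contacts(_point_frame(moved), np.arange(20), np.arange(20, 40), rc=0.6) == base


# ---------------------------------------------------------------------------
# native contacts and Q

def test_two_residue_peptide_has_no_native_contacts():
    top = _plain_topology(2, resid_of=[1, 2])
    f = _point_frame([[0, 0, 0], [0.2, 0, 0]])
    assert len(native_contacts(top, f).pairs) == 0


def test_spread_chain_has_no_native_contacts():
    # residues on a line 0.7 nm apart: min distance for separation >= 3 is 2.1 nm
    n = 8
    top = _plain_topology(n, resid_of=list(range(1, n + 1)))
    f = _point_frame([[0.7 * i, 0, 0] for i in range(n)])
    assert len(native_contacts(top, f).pairs) == 0


def test_native_contacts_match_exhaustive_scan(bundle):
    top, frame = bundle
    ncs = native_contacts(top, frame, rc=0.6, min_sep=3)
    heavy = top.protein & top.heavy
    resids = top.protein_resids()
    atoms = {int(r): np.flatnonzero(heavy & (top.resids == r)) for r in resids}
    expected = []
    for a, i in enumerate(resids):
        for j in resids[a + 1:]:
            if j - i < 3:
                continue
            pi, pj = frame.positions[atoms[int(i)]], frame.positions[atoms[int(j)]]
            if np.sqrt(((pi[:, None] - pj[None]) ** 2).sum(-1)).min() <= 0.6:
                expected.append((int(i), int(j)))
    assert list(ncs.pairs) == expected
    assert len(ncs) > 0


def test_pair_separation_invariant():
    with pytest.raises(ValueError, match="separation"):
        NativeContactSet(pairs=((5, 7),), min_sep=3)


def test_q_is_one_at_reference_and_zero_when_blown_apart(bundle):
    top, frame = bundle
    ncs = native_contacts(top, frame)
    assert q_fraction(frame, top, ncs) == 1.0
    exploded = Frame(frame.positions * 10.0)
    assert q_fraction(exploded, top, ncs) == 0.0
    with pytest.raises(ValueError, match="empty"):
        q_fraction(frame, top, NativeContactSet(pairs=()))


def test_q_partial_melt_matches_brute_recount(bundle):
    top, frame = bundle
    ncs = native_contacts(top, frame)
    melted = melt_helix(frame, top, range(54, 62))
    q = q_fraction(melted, top, ncs)
    heavy = top.protein & top.heavy
    atoms = {int(r): np.flatnonzero(heavy & (top.resids == r)) for r in top.protein_resids()}
    formed = 0
    for i, j in ncs.pairs:
        pi, pj = melted.positions[atoms[i]], melted.positions[atoms[j]]
        if np.sqrt(((pi[:, None] - pj[None]) ** 2).sum(-1)).min() <= 0.6:
            formed += 1
    assert q == pytest.approx(formed / len(ncs), abs=1e-12)
    assert q < 1.0


# ---------------------------------------------------------------------------
# helix ratio

def test_ideal_helix_scores_one(bundle, spans):
    top, frame = bundle
    assert helix_ratio(frame, top, spans) == 1.0


def test_fully_melted_scores_zero(bundle, spans):
    top, frame = bundle
    melted = melt_helix(frame, top, spans.residues())
    assert helix_ratio(melted, top, spans) == 0.0


@pytest.mark.parametrize("m", [0.0, 0.25, 0.5, 0.75, 1.0])
def test_melt_fraction_recovered_within_one_residue(bundle, spans, m):
    top, frame = bundle
    melt = melt_times_from_fraction([(0.0, m)], spans)
    melted_frame = melt_helix(frame, top, melt) if melt else frame
    denom = len(spans.residues())
    got = helix_ratio(melted_frame, top, spans)
    assert abs(got - (1.0 - m)) <= 1.0 / denom + 1e-12


def test_short_runs_are_not_helical(bundle, spans):
    # keeping only the first 3 residues of helix 2 leaves an isolated run
    # below the length-4 rule (the loop at 53 breaks contiguity with helix 1)
    top, frame = bundle
    keep = {54, 55, 56}
    melted = melt_helix(frame, top, [r for r in range(54, 62) if r not in keep])
    got = helix_ratio(melted, top, spans)
    denom = len(spans.residues())
    expected = (denom - 8) / denom  # entire helix 2 counts as lost
    assert got == pytest.approx(expected, abs=1e-12)


def test_adjacent_spans_merge_into_one_run(bundle, spans):
    # helices 2 and 3 are sequence-adjacent (61|62): the tail of helix 2 stays
    # helical when it continues into an intact helix 3
    top, frame = bundle
    melted_frame = melt_helix(frame, top, [54, 55, 56, 57, 58])
    got = helix_ratio(melted_frame, top, spans)
    denom = len(spans.residues())
    assert got == pytest.approx((denom - 5) / denom, abs=1e-12)


# ---------------------------------------------------------------------------
# hydrogen bonds

def _water_pair(d, angle_linear=True):
    """Two waters: O-H...O with adjustable O-O distance."""
    o1 = np.array([0.0, 0.0, 0.0])
    o2 = np.array([d, 0.0, 0.0])
    h_dir = np.array([1.0, 0.0, 0.0]) if angle_linear else np.array([0.0, 1.0, 0.0])
    h = o1 + 0.096 * h_dir
    top = Topology(names=["OW", "HW1", "OW"], elements=["O", "H", "O"],
                   resids=[1, 1, 2], resnames=["SOL"] * 3, chains=["W"] * 3)
    return Frame(np.array([o1, h, o2])), top


def test_hbond_geometric_criterion():
    f, top = _water_pair(0.30)
    assert hbond_count(f, top) == 1
    f, top = _water_pair(0.40)
    assert hbond_count(f, top) == 0
    f, top = _water_pair(0.30, angle_linear=False)  # ~90 degree D-H-A angle
    assert hbond_count(f, top) == 0


def test_hbond_distance_only_without_hydrogens():
    top = Topology(names=["OW", "OW"], elements=["O", "O"], resids=[1, 2],
                   resnames=["SOL"] * 2, chains=["W"] * 2)
    assert hbond_count(Frame(np.array([[0, 0, 0], [0.3, 0, 0.0]])), top) == 1
    assert hbond_count(Frame(np.array([[0, 0, 0], [0.4, 0, 0.0]])), top) == 0


def test_hbond_matches_exhaustive_scan():
    rng = np.random.default_rng(11)
    for _ in range(10):
        n = 20
        top = Topology(names=["O"] * n, elements=["O"] * n, resids=list(range(1, n + 1)),
                       resnames=["SOL"] * n, chains=["W"] * n)
        pos = rng.uniform(0, 1.2, size=(n, 3))
        got = hbond_count(Frame(pos), top)
        want = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if np.linalg.norm(pos[i] - pos[j]) <= 0.35
        )
        assert got == want


# ---------------------------------------------------------------------------
# salt bridges and cation-pi

def _arg_asp_pair(d):
    names = ["CB", "CZ", "NE", "NH1", "NH2", "CB", "OD1", "OD2"]
    elements = ["C", "C", "N", "N", "N", "C", "O", "O"]
    resids = [55] * 5 + [44] * 3
    resnames = ["ARG"] * 5 + ["ASP"] * 3
    pos = np.zeros((8, 3))
    pos[1] = [0.1, 0, 0]
    pos[2] = [0.0, 0.1, 0]
    pos[3] = [0.05, -0.1, 0]
    pos[4] = [0.0, 0.0, 0.1]   # NH2: closest N
    pos[5] = [d + 0.3, 0, 0]
    pos[6] = [d, 0, 0.1]       # OD1 at distance d from NH2 (z offset matches)
    pos[7] = [d + 0.1, 0.2, 0]
    top = Topology(names=names, elements=elements, resids=resids,
                   resnames=resnames, chains=["A"] * 8)
    return Frame(pos), top


def test_salt_bridge_distance_criterion():
    f, top = _arg_asp_pair(0.35)
    assert salt_bridge(f, top, 55, 44, rc=0.4) is True
    f, top = _arg_asp_pair(0.45)
    assert salt_bridge(f, top, 55, 44, rc=0.4) is False


def test_salt_bridge_wrong_residue_types(bundle):
    top, frame = bundle
    with pytest.raises(ValueError, match="not basic"):
        salt_bridge(frame, top, 64, 44)  # Trp-64 is not basic
    with pytest.raises(ValueError, match="not acidic"):
        salt_bridge(frame, top, 55, 64)


def _arg_phe_pair(d):
    ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    names = ["CZ"] + ring_names
    elements = ["C"] * 7
    resids = [55] + [47] * 6
    resnames = ["ARG"] + ["PHE"] * 6
    theta = np.linspace(0, 2 * np.pi, 7)[:-1]
    ring = np.stack([0.14 * np.cos(theta) + d, 0.14 * np.sin(theta), np.zeros(6)], axis=1)
    pos = np.vstack([[0.0, 0.0, 0.0], ring])
    top = Topology(names=names, elements=elements, resids=resids,
                   resnames=resnames, chains=["A"] * 7)
    return Frame(pos), top


def test_cation_pi_centroid_criterion():
    f, top = _arg_phe_pair(0.45)
    assert cation_pi(f, top, 55, 47, rc=0.5) is True
    f, top = _arg_phe_pair(0.55)
    assert cation_pi(f, top, 55, 47, rc=0.5) is False
    # centroid equals the mean of the ring atoms
    centroid = f.positions[1:].mean(axis=0)
    assert np.linalg.norm(centroid - [0.55, 0, 0]) < 1e-12


def test_cation_pi_wrong_residue_types(bundle):
    top, frame = bundle
    with pytest.raises(ValueError, match="not aromatic"):
        cation_pi(frame, top, 55, 60)  # Asn-60 is not aromatic


# ---------------------------------------------------------------------------
# hydrophobic fraction

def test_first_contact_residue_set_is_two_thirds_hydrophobic():
    """The six first-anchoring residues of helix 2 are 4/6 ~ 67% hydrophobic."""
    residues = ["ARG-55", "PHE-58", "ASN-60", "LEU-61", "LEU-63", "TRP-64"]
    frac = hydrophobic_fraction(residues)
    assert frac == pytest.approx(100.0 * 4 / 6, abs=1e-9)
    assert round(frac) == 67


def test_hydrophobic_fraction_edge_cases():
    assert hydrophobic_fraction(["ASN", "ASN", "N"]) == 0.0
    assert hydrophobic_fraction(["W"]) == 100.0
    with pytest.raises(ValueError, match="unknown"):
        hydrophobic_fraction(["XYZ"])
    with pytest.raises(ValueError, match="empty"):
        hydrophobic_fraction([])


def test_hydrophobic_fraction_matches_recount():
    rng = np.random.default_rng(9)
    table = ["ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"]
    all_res = list("ARNDCQEGHILKMFPSTWYV")
    for _ in range(20):
        sample = [all_res[i] for i in rng.integers(0, 20, size=rng.integers(1, 30))]
        got = hydrophobic_fraction(sample)
        from mosads.metrics import _ONE_TO_THREE

        want = 100.0 * sum(_ONE_TO_THREE[c] in table for c in sample) / len(sample)
        assert got == pytest.approx(want, abs=1e-12)


def test_helix_spans_validation():
    with pytest.raises(ValueError, match="overlap"):
        HelixSpans(helix1=(43, 55), helix2=(54, 61))
    with pytest.raises(ValueError, match="reversed"):
        HelixSpans(helix1=(52, 43))
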