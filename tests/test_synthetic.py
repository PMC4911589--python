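"""Generator correctness: scaffold geometry, melting, ground-truth closure."""

import numpy as np
import pytest

from mosads import metrics
from mosads.hydration import anchoring_order, first_contact_time, fss_water_count
from mosads.metrics import HelixSpans, helix_ratio, phi_psi
from mosads.nanosheet import LatticeSpec, build_monolayer
from mosads.synthetic import (
    HP35_SEQUENCE,
    SIDECHAIN_HEAVY,
    ScenarioSpec,
    build_ideal_bundle,
    generate_trajectory,
    melt_helix,
    melt_times_from_fraction,
    random_scenario,
)
from mosads.trajio import load_structure, load_trajectory, write_structure, write_trajectory


# ---------------------------------------------------------------------------
# scaffold

def test_bundle_bookkeeping(bundle):
    top, _ = bundle
    resids = top.protein_resids()
    assert len(resids) == 35 and resids[0] == 42 and resids[-1] == 76
    # every residue carries its full sidechain heavy-atom count
    for resid in resids:
        res3 = top.resname_of(int(resid))
        idx = top.residue_atoms(int(resid))
        n_side = int((top.sidechain & top.heavy)[idx].sum())
        assert n_side == SIDECHAIN_HEAVY[res3]


def test_bundle_dihedrals_are_ideal(bundle, spans):
    top, frame = bundle
    pp = phi_psi(frame, top).loc[list(spans.residues())]
    assert np.abs(pp.phi + 57.0).max() < 0.5
    assert np.abs(pp.psi + 47.0).max() < 0.5
    assert helix_ratio(frame, top, spans) == 1.0


def test_bundle_span_validation():
    with pytest.raises(ValueError, match="outside"):
        build_ideal_bundle("AAAA", start_resid=1, spans=HelixSpans())


# ---------------------------------------------------------------------------
# melting

def test_melt_none_is_identity(bundle):
    top, frame = bundle
    out = melt_helix(frame, top, [])
    assert np.abs(out.positions - frame.positions).max() < 1e-12


def test_melt_changes_only_targeted_dihedrals(bundle):
    top, frame = bundle
    out = melt_helix(frame, top, [57])
    pp0 = phi_psi(frame, top)
    pp1 = phi_psi(out, top)
    assert pp1.loc[57, "phi"] == pytest.approx(-120.0, abs=1e-6)
    assert pp1.loc[57, "psi"] == pytest.approx(120.0, abs=1e-6)
    others = [r for r in pp0.index if r != 57]
    assert np.nanmax(np.abs(pp0.loc[others] - pp1.loc[others]).to_numpy()) < 1e-6


def test_melt_preserves_other_residue_geometry(bundle):
    top, frame = bundle
    out = melt_helix(frame, top, range(54, 62))
    for resid in (45, 50, 65, 70):
        idx = top.residue_atoms(resid)
        d0 = np.linalg.norm(frame.positions[idx][:, None] - frame.positions[idx][None], axis=-1)
        d1 = np.linalg.norm(out.positions[idx][:, None] - out.positions[idx][None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9


def test_melt_run_length_oracle(bundle, spans):
    """Melting k residues yields exactly the helix ratio of an independent run scan."""
    top, frame = bundle
    rng = np.random.default_rng(6)
    span_res = list(spans.residues())
    for _ in range(5):
        k = int(rng.integers(1, len(span_res)))
        melted = set(int(r) for r in rng.choice(span_res, size=k, replace=False))
        out = melt_helix(frame, top, melted)
        got = helix_ratio(out, top, spans)
        # independent chain-wide run scan (adjacent spans are contiguous)
        ordered = sorted(span_res)
        helical = run = 0
        for k, r in enumerate(ordered + [None]):
            alive = r is not None and r not in melted and (
                run == 0 or ordered[k - 1] == r - 1
            )
            if alive:
                run += 1
            else:
                if run >= 4:
                    helical += run
                run = 1 if (r is not None and r not in melted) else 0
        assert got == pytest.approx(helical / len(span_res), abs=1e-12)


def test_melt_fraction_schedule():
    melt = melt_times_from_fraction([(0.0, 0.0), (1.0, 0.5), (2.0, 1.0)])
    assert len([r for r, t in melt.items() if t <= 1.0]) == round(0.5 * 31)
    assert len(melt) == 31
    # helix 2 melts first
    assert all(melt[r] <= 1.0 for r in range(54, 62))
    with pytest.raises(ValueError, match="non-decreasing"):
        melt_times_from_fraction([(0.0, 0.5), (1.0, 0.2)])


# ---------------------------------------------------------------------------
# trajectory generation

def test_same_seed_is_byte_identical(wide_sheet):
    spec = ScenarioSpec(n_frames=6, frame_spacing_ps=400.0, seed=3)
    t1, _ = generate_trajectory(spec, wide_sheet)
    t2, _ = generate_trajectory(ScenarioSpec(n_frames=6, frame_spacing_ps=400.0, seed=3), wide_sheet)
    for f1, f2 in zip(t1, t2):
        assert f1.positions.tobytes() == f2.positions.tobytes()


def test_different_seed_differs(wide_sheet):
    spec_a = ScenarioSpec(n_frames=4, frame_spacing_ps=600.0, seed=1)
    spec_b = ScenarioSpec(n_frames=4, frame_spacing_ps=600.0, seed=2)
    fa = next(iter(generate_trajectory(spec_a, wide_sheet)[0]))
    fb = next(iter(generate_trajectory(spec_b, wide_sheet)[0]))
    assert not np.array_equal(fa.positions, fb.positions)  # water placement differs


def test_gap_schedule_realized(reference_scenario, wide_sheet):
    spec, traj, _ = reference_scenario
    top = traj.topology
    heavy_prot = top.protein & top.heavy
    sheet_idx = top.sheet
    frames = list(traj)
    for fi in (0, 5):
        t = frames[fi].time / 1000.0
        pinned = [r for r, onset in spec.onsets.items() if onset <= t]
        mask = heavy_prot & ~np.isin(top.resids, pinned)
        d = np.linalg.norm(
            frames[fi].positions[mask][:, None] - frames[fi].positions[sheet_idx][None], axis=-1
        ).min()
        assert d == pytest.approx(spec.gap_at(t), abs=1e-6)


def test_ground_truth_closure(reference_scenario):
    """Every analysis stage recovers the generator's programmed answers."""
    spec, traj, truth = reference_scenario
    top = traj.topology
    frames = list(traj)

    # Q: reference frame scores 1, every frame matches the exhaustive recount
    ncs = metrics.native_contacts(top, frames[0], rc=0.6)
    assert len(ncs) == truth.n_native
    q = np.array([metrics.q_fraction(f, top, ncs) for f in frames])
    assert q[0] == 1.0
    assert np.abs(q - truth.q).max() < 1e-12

    # helix ratio within one residue of the programmed melt state
    hr = np.array([metrics.helix_ratio(f, top, spec.spans) for f in frames])
    assert np.abs(hr - truth.helix_fraction).max() <= 1.0 / truth.helix_denominator

    # onsets exact at persistence 1; anchoring order exact
    series = metrics.per_residue_contact_series(traj, rc=0.6)
    onsets = first_contact_time(series, persistence_k=1)
    recovered = {o.resid: o.onset_ns for o in onsets if o.onset_ns is not None}
    times = truth.times_ns
    expected = {r: float(times[np.searchsorted(times, t)]) for r, t in truth.onsets.items()}
    assert recovered == expected
    assert anchoring_order(onsets, spec.spans) == truth.anchoring_order

    # FSS counts exact on every frame
    for f in frames:
        for resid, count in truth.fss_counts.items():
            assert fss_water_count(f, top, resid, rc_fss=spec.fss_rc) == count


def test_io_transparency(tmp_path, wide_sheet):
    """Writing to XTC / multi-model PDB and re-reading reproduces the analyses."""
    spec = ScenarioSpec(n_frames=8, frame_spacing_ps=300.0, seed=5)
    traj, _ = generate_trajectory(spec, wide_sheet)
    frames = list(traj)
    write_structure(traj.topology, frames[0], tmp_path / "top.pdb")
    rtop, _ = load_structure(tmp_path / "top.pdb")
    ncs = metrics.native_contacts(traj.topology, frames[0])
    q_direct = [metrics.q_fraction(f, traj.topology, ncs) for f in frames]
    for suffix in ("xtc", "pdb"):
        path = tmp_path / f"traj.{suffix}"
        write_trajectory(traj.topology, frames, path)
        back = load_trajectory(rtop, path)
        ncs2 = metrics.native_contacts(rtop, next(iter(back)))
        assert ncs2.pairs == ncs.pairs
        q_back = [metrics.q_fraction(f, rtop, ncs2) for f in back]
        assert q_back == q_direct
        for resid in spec.shell_waters:
            got = [fss_water_count(f, rtop, resid, rc_fss=spec.fss_rc) for f in back]
            assert got == [spec.shell_waters[resid][0]] * len(frames)


# ---------------------------------------------------------------------------
# validation

def test_scenario_validation_errors(wide_sheet):
    with pytest.raises(ValueError, match="onset time"):
        ScenarioSpec(n_frames=5, frame_spacing_ps=20.0, onsets={55: 99.0}).validate()
    with pytest.raises(ValueError, match="glycine"):
        ScenarioSpec(onsets={52: 0.1}).validate()
    with pytest.raises(ValueError, match="cutoff"):
        ScenarioSpec(gap_schedule=((0.0, 0.5),)).validate()
    with pytest.raises(ValueError, match="outside"):
        ScenarioSpec(onsets={200: 0.1}).validate()


def test_random_scenarios_are_valid():
    for seed in range(10):
        random_scenario(seed).validate()
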