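"""Shared fixtures: small sheets, the ideal bundle, and a reference scenario."""

import numpy as np
import pytest

from mosads.metrics import HelixSpans
from mosads.nanosheet import LatticeSpec, build_monolayer, default_params
from mosads.synthetic import ScenarioSpec, build_ideal_bundle, generate_trajectory


@pytest.fixture(scope="session")
def mos2_params():
    return default_params()


@pytest.fixture(scope="session")
def small_sheet(mos2_params):
    """A 4x3 monolayer patch (72 atoms)."""
    return build_monolayer(LatticeSpec(nx=4, ny=3), mos2_params)


@pytest.fixture(scope="session")
def wide_sheet(mos2_params):
    """A patch wide enough to hold the elongated bundle (10x6, 360 atoms)."""
    return build_monolayer(LatticeSpec(nx=10, ny=6), mos2_params)


@pytest.fixture(scope="session")
def bundle():
    """The ideal HP35 scaffold: (topology, frame)."""
    return build_ideal_bundle()


@pytest.fixture(scope="session")
def spans():
    return HelixSpans()


@pytest.fixture(scope="session")
def reference_scenario(wide_sheet):
    """One moderately sized scenario and its trajectory + ground truth."""
    spec = ScenarioSpec(n_frames=40, frame_spacing_ps=70.0, seed=7)
    traj, truth = generate_trajectory(spec, wide_sheet)
    return spec, traj, truth
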