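import math
import warnings

import numpy as np
import pytest

from hepasim.boundary import OutletBC, build_territories, outlet_flow_rates
from hepasim.hemodynamics import WaveformParams, solve_branch_flows
from hepasim.vasculature import (
    ArterialTree,
    VesselNode,
    generate_liver_phantom,
    generate_tree,
    map_outlets_to_segments,
)


def make_bifurcation_tree(radius=2.5e-3, theta=math.radians(30.0),
                          length=0.02, daughter_length=0.015) -> ArterialTree:
    """Single symmetric bifurcation in the x-z plane, root along +x."""
    axis = np.array([1.0, 0.0, 0.0])
    r_d = radius * 2.0 ** (-1.0 / 3.0)
    d1 = np.array([math.cos(theta), 0.0, math.sin(theta)])
    d2 = np.array([math.cos(theta), 0.0, -math.sin(theta)])
    nodes = {
        "v": VesselNode("v", None, length, radius, axis, ("v0", "v1"), False),
        "v0": VesselNode("v0", "v", daughter_length, r_d, d1, (), True),
        "v1": VesselNode("v1", "v", daughter_length, r_d, d2, (), True),
    }
    return ArterialTree(nodes=nodes, root_id="v", outlet_ids=["v0", "v1"])


def make_single_branch_tree(radius=2e-3, length=0.02) -> ArterialTree:
    node = VesselNode("v", None, length, radius, np.array([1.0, 0.0, 0.0]),
                      (), True)
    return ArterialTree(nodes={"v": node}, root_id="v", outlet_ids=["v"])


def small_study(seed, depth=4, n_tumors=2, root_radius=2e-3, asymmetry=0.7,
                length_ratio=6.0):
    """Phantom + tree + BCs + constant-waveform flow field for quick runs."""
    tree = generate_tree(depth=depth, root_radius=root_radius,
                         asymmetry=asymmetry, seed=seed,
                         length_ratio=length_ratio)
    segments, tumors, perfusion = generate_liver_phantom(n_tumors, seed=seed)
    mapping = map_outlets_to_segments(tree, segments, seed=seed)
    territories = build_territories(mapping, segments, tumors)
    bcs = outlet_flow_rates(territories, perfusion, tumors)
    flow = solve_branch_flows(tree, bcs, waveform=WaveformParams.constant())
    return tree, segments, tumors, perfusion, mapping, territories, bcs, flow


@pytest.fixture
def y_tree():
    return make_bifurcation_tree()


@pytest.fixture
def y_flow(y_tree):
    bcs = [OutletBC("v0", 55.0, 0.55), OutletBC("v1", 45.0, 0.45)]
    return bcs, solve_branch_flows(y_tree, bcs,
                                   waveform=WaveformParams.constant())


@pytest.fixture(autouse=True)
def _silence_exit_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*injected microspheres exited.*")
        yield
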