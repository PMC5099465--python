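"""Network flow solver: Poiseuille, Kirchhoff, occlusion handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import retcap as rc
from retcap.errors import ConfigurationError
from retcap.geometry import CAPILLARY, Node, VascularNetwork, VesselSegment
from retcap.hemodynamics import (conductance, max_capillary_velocity,
                                 min_large_vessel_velocity, occlude_segment,
                                 solve_flow)

MU = 2.0e-3


def simple_network(segments, pressures):
    nodes = {}
    for s in segments:
        for nid in (s.node_a, s.node_b):
            nodes.setdefault(nid, Node(nid, 0.0, 0.0))
    inlets, outlets = set(), set()
    for nid, p in pressures.items():
        nodes[nid].pressure = p
        (inlets if p == max(pressures.values()) else outlets).add(nid)
    return VascularNetwork(nodes, segments, inlets, outlets)


def dense_reference_solve(network, boundary, viscosity=MU):
    """Independent dense linear-algebra oracle for node pressures/flows."""
    ids = sorted(network.nodes)
    idx = {n: i for i, n in enumerate(ids)}
    n = len(ids)
    lap = np.zeros((n, n))
    for s in network.segments:
        if s.occluded:
            continue
        g = np.pi * s.diameter**4 / (128 * viscosity * s.hydraulic_length) * 133.322
        a, b = idx[s.node_a], idx[s.node_b]
        lap[a, a] += g
        lap[b, b] += g
        lap[a, b] -= g
        lap[b, a] -= g
    rhs = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    p = np.zeros(n)
    for nid, val in boundary.items():
        i = idx[nid]
        fixed[i] = True
        p[i] = val
    free = ~fixed
    a_ff = lap[np.ix_(free, free)]
    rhs_f = -lap[np.ix_(free, fixed)] @ p[fixed]
    p[free] = np.linalg.solve(a_ff, rhs_f)
    return {nid: p[idx[nid]] for nid in ids}


def test_single_segment_poiseuille_closed_form():
    seg = VesselSegment("s", CAPILLARY, "a", "b", diameter=10.0, length=100.0)
    net = simple_network([seg], {"a": 1.0, "b": 0.0})
    flow = solve_flow(net, viscosity=MU)
    expected = np.pi * 10.0**4 / (128 * MU * 100.0) * 133.322
    assert flow.segment_flow["s"] == pytest.approx(expected, rel=1e-12)
    assert flow.segment_velocity["s"] == pytest.approx(
        expected / (np.pi * 25.0), rel=1e-12)


def test_parallel_identical_capillaries_split_equally():
    segs = [VesselSegment("s1", CAPILLARY, "a", "b", 10.0, 100.0),
            VesselSegment("s2", CAPILLARY, "a", "b", 10.0, 100.0)]
    net = simple_network(segs, {"a": 2.0, "b": 0.0})
    flow = solve_flow(net, viscosity=MU)
    assert flow.segment_flow["s1"] == pytest.approx(flow.segment_flow["s2"], rel=1e-12)


def test_occluding_parallel_branch_reduces_inflow_three_resistor():
    def build():
        return simple_network(
            [VesselSegment("feed", CAPILLARY, "a", "m", 12.0, 50.0),
             VesselSegment("c1", CAPILLARY, "m", "b", 10.0, 100.0),
             VesselSegment("c2", CAPILLARY, "m", "b", 10.0, 100.0)],
            {"a": 1.0, "b": 0.0})

    net = build()
    q_before = solve_flow(net, viscosity=MU).total_inflow(net)
    net2 = build()
    occlude_segment(net2, "c2")
    flow2 = solve_flow(net2, viscosity=MU)
    q_after = flow2.total_inflow(net2)
    assert q_after < q_before
    # hand-solved two-resistor series circuit
    g_feed = conductance(12.0, 50.0, MU)
    g_c = conductance(10.0, 100.0, MU)
    expected = 1.0 / (1.0 / g_feed + 1.0 / g_c)
    assert q_after == pytest.approx(expected, rel=1e-12)
    assert flow2.segment_flow["c2"] == 0.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_matches_dense_solve_on_random_networks(seed):
    rng = np.random.default_rng(seed)
    n_nodes = int(rng.integers(4, 20))
    names = [f"n{i}" for i in range(n_nodes)]
    segs = []
    for i in range(1, n_nodes):  # random spanning tree keeps it connected
        j = int(rng.integers(0, i))
        segs.append(VesselSegment(f"t{i}", CAPILLARY, names[i], names[j],
                                  float(rng.uniform(5, 25)),
                                  float(rng.uniform(20, 300))))
    for k in range(int(rng.integers(0, n_nodes))):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        segs.append(VesselSegment(f"x{k}", CAPILLARY, names[i], names[j],
                                  float(rng.uniform(5, 25)),
                                  float(rng.uniform(20, 300))))
    boundary = {names[0]: 40.0, names[-1]: 20.0}
    net = simple_network(segs, boundary)
    flow = solve_flow(net, viscosity=MU)
    ref = dense_reference_solve(net, boundary)
    for nid, p in ref.items():
        assert flow.node_pressure[nid] == pytest.approx(p, rel=1e-10, abs=1e-10)
    # Kirchhoff at interior nodes
    net_flow = {nid: 0.0 for nid in net.nodes}
    for s in segs:
        q = flow.segment_flow[s.id]
        net_flow[s.node_a] -= q
        net_flow[s.node_b] += q
    scale = max(abs(q) for q in flow.segment_flow.values()) or 1.0
    for nid in net.nodes:
        if nid not in boundary:
            assert abs(net_flow[nid]) / scale < 1e-9


def test_mass_conservation_on_default_network(default_geometry, default_flow):
    network, _ = default_geometry
    scale = max(abs(q) for q in default_flow.segment_flow.values())
    assert abs(default_flow.boundary_net_flow(network)) / scale < 1e-9


def test_capillaries_slower_than_large_vessels(default_geometry, default_flow):
    network, _ = default_geometry
    assert (min_large_vessel_velocity(network, default_flow)
            > max_capillary_velocity(network, default_flow))


def test_occlusion_zeroes_velocity_and_is_idempotent(default_cfg):
    network, _ = rc.build_geometry(default_cfg.geometry)
    occlude_segment(network, "cap_s1_r4")
    occlude_segment(network, "cap_s1_r4")  # no-op
    flow = solve_flow(network, viscosity=default_cfg.viscosity)
    assert flow.segment_velocity["cap_s1_r4"] == 0.0
    assert flow.segment_flow["cap_s1_r4"] == 0.0


def test_occluded_sector_keeps_shunt_flowing(default_cfg):
    network, _ = rc.build_geometry(default_cfg.geometry)
    for seg in network.capillaries:
        if seg.sector == 1:
            occlude_segment(network, seg.id)
    flow = solve_flow(network, viscosity=default_cfg.viscosity)
    for seg in network.capillaries:
        if seg.sector == 1:
            assert flow.segment_flow[seg.id] == 0.0
    shunt_flows = [abs(flow.segment_flow[s.id]) for s in network.segments
                   if s.kind == "shunt"]
    assert min(shunt_flows) > 0.0


def test_edge_removal_never_increases_inflow(default_cfg):
    network, _ = rc.build_geometry(default_cfg.geometry)
    base = solve_flow(network, viscosity=default_cfg.viscosity)
    q0 = base.total_inflow(network)
    for sid in ("cap_s0_r0", "cap_s1_r4", "cap_s3_r9"):
        net2, _ = rc.build_geometry(default_cfg.geometry)
        occlude_segment(net2, sid)
        q1 = solve_flow(net2, viscosity=default_cfg.viscosity).total_inflow(net2)
        assert q1 <= q0 * (1 + 1e-12)


def test_solution_invariant_under_node_relabelling():
    segs = [VesselSegment("s1", CAPILLARY, "a", "m", 10.0, 80.0),
            VesselSegment("s2", CAPILLARY, "m", "b", 10.0, 120.0)]
    net = simple_network(segs, {"a": 30.0, "b": 10.0})
    f1 = solve_flow(net, viscosity=MU)
    ren = {"a": "zz", "m": "qq", "b": "aa"}
    segs2 = [VesselSegment("s1", CAPILLARY, "zz", "qq", 10.0, 80.0),
             VesselSegment("s2", CAPILLARY, "qq", "aa", 10.0, 120.0)]
    net2 = simple_network(segs2, {"zz": 30.0, "aa": 10.0})
    f2 = solve_flow(net2, viscosity=MU)
    for old, new in ren.items():
        assert f1.node_pressure[old] == pytest.approx(f2.node_pressure[new], rel=1e-12)


def test_disconnected_island_gets_zero_flow():
    segs = [VesselSegment("main", CAPILLARY, "a", "b", 10.0, 100.0),
            VesselSegment("isle", CAPILLARY, "u", "v", 10.0, 100.0)]
    net = simple_network(segs, {"a": 1.0, "b": 0.0})
    flow = solve_flow(net, viscosity=MU)
    assert flow.segment_flow["isle"] == 0.0
    assert flow.segment_flow["main"] > 0.0


def test_errors():
    seg = VesselSegment("s", CAPILLARY, "a", "b", 10.0, 100.0)
    net = simple_network([seg], {"a": 1.0, "b": 0.0})
    with pytest.raises(ConfigurationError):
        solve_flow(net, boundary={})
    with pytest.raises(KeyError):
        occlude_segment(net, "nope")
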