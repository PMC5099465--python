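"""Steady laminar network blood flow.

Each open vessel segment is a Poiseuille conductor
``G = pi d^4 / (128 mu L)``; node pressures solve the Kirchhoff current law
with fixed pressures at arteriole inlets and venule outlets.  Occluded
segments carry exactly zero flow.  Components disconnected from every
boundary node are assigned the mean boundary pressure and zero flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, SolverError
from .geometry import CAPILLARY, VascularNetwork

MMHG_TO_PA = 133.322


def conductance(diameter: float, length: float, viscosity: float) -> float:
    """Poiseuille conductance in µm³/(s·mmHg) for d, L in µm and µ in Pa·s."""
    return np.pi * diameter**4 / (128.0 * viscosity * length) * MMHG_TO_PA


@dataclass
class FlowSolution:
    node_pressure: dict[str, float]          # mmHg
    segment_flow: dict[str, float]           # µm³/s, signed + from node_a to node_b
    segment_velocity: dict[str, float]       # µm/s, non-negative mean speed

    def boundary_net_flow(self, network: VascularNetwork) -> float:
        """Signed net inflow across all boundary nodes (mass-balance check)."""
        boundary = network.inlet_nodes | network.outlet_nodes
        total = 0.0
        for s in network.segments:
            if s.node_a in boundary:
                total -= self.segment_flow[s.id]
            if s.node_b in boundary:
                total += self.segment_flow[s.id]
        return total

    def total_inflow(self, network: VascularNetwork) -> float:
        total = 0.0
        for s in network.segments:
            if s.node_a in network.inlet_nodes:
                total += self.segment_flow[s.id]
            if s.node_b in network.inlet_nodes:
                total -= self.segment_flow[s.id]
        return total


def solve_flow(network: VascularNetwork,
               boundary: dict[str, float] | None = None,
               viscosity: float = 2.0e-3) -> FlowSolution:
    """Solve node pressures and per-segment flows/velocities.

    ``boundary`` maps node ids to fixed pressures (mmHg); by default the
    pressures stored on the network's inlet/outlet nodes are used.
    """
    if boundary is None:
        boundary = network.boundary_pressures()
    if not boundary:
        raise ConfigurationError("no boundary pressures fixed")
    unknown_bnd = set(boundary) - set(network.nodes)
    if unknown_bnd:
        raise ConfigurationError(f"boundary pressures for unknown nodes: {sorted(unknown_bnd)}")

    ids = sorted(network.nodes)
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)

    open_segs = [s for s in network.segments if not s.occluded]
    g = np.array([conductance(s.diameter, s.hydraulic_length, viscosity)
                  for s in open_segs])
    ia = np.array([index[s.node_a] for s in open_segs], dtype=int)
    ib = np.array([index[s.node_b] for s in open_segs], dtype=int)

    # connected components of the open subgraph, to isolate boundary-free islands
    if open_segs:
        adj = sp.coo_matrix((np.ones(len(open_segs)), (ia, ib)), shape=(n, n))
        n_comp, comp = sp.csgraph.connected_components(adj, directed=False)
    else:
        n_comp, comp = n, np.arange(n)
    bnd_idx = np.array([index[b] for b in boundary], dtype=int)
    bnd_val = np.array([boundary[b] for b in boundary])
    live_comps = set(comp[bnd_idx].tolist())

    pressure = np.full(n, float(np.mean(bnd_val)))
    is_bnd = np.zeros(n, dtype=bool)
    is_bnd[bnd_idx] = True
    pressure[bnd_idx] = bnd_val

    live = np.array([comp[i] in live_comps for i in range(n)])
    free = live & ~is_bnd
    free_idx = np.nonzero(free)[0]
    if len(free_idx) > 0:
        pos = -np.ones(n, dtype=int)
        pos[free_idx] = np.arange(len(free_idx))
        rows, cols, vals = [], [], []
        rhs = np.zeros(len(free_idx))
        for k, s in enumerate(open_segs):
            a, b = ia[k], ib[k]
            for u, v in ((a, b), (b, a)):
                if not free[u]:
                    continue
                rows.append(pos[u]); cols.append(pos[u]); vals.append(g[k])
                if free[v]:
                    rows.append(pos[u]); cols.append(pos[v]); vals.append(-g[k])
                else:
                    rhs[pos[u]] += g[k] * pressure[v]
        lap = sp.csr_matrix((vals, (rows, cols)),
                            shape=(len(free_idx), len(free_idx)))
        try:
            sol = spla.spsolve(lap.tocsc(), rhs)
        except Exception as exc:  # pragma: no cover - singular beyond island handling
            raise SolverError(f"pressure system singular: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise SolverError("pressure solve produced non-finite values")
        pressure[free_idx] = sol

    node_pressure = {nid: float(pressure[index[nid]]) for nid in ids}
    seg_flow: dict[str, float] = {}
    seg_vel: dict[str, float] = {}
    for s in network.segments:
        if s.occluded or comp[index[s.node_a]] not in live_comps:
            q = 0.0
        else:
            gk = conductance(s.diameter, s.hydraulic_length, viscosity)
            q = gk * (pressure[index[s.node_a]] - pressure[index[s.node_b]])
        seg_flow[s.id] = float(q)
        seg_vel[s.id] = float(abs(q) / (np.pi * s.diameter**2 / 4.0))
    return FlowSolution(node_pressure, seg_flow, seg_vel)


def occlude_segment(network: VascularNetwork, segment_id: str) -> VascularNetwork:
    """Mark a segment occluded, irreversibly (idempotent; in place)."""
    seg = network.segment(segment_id)
    seg.occluded = True
    return network


def min_large_vessel_velocity(network: VascularNetwork, flow: FlowSolution) -> float:
    v = [flow.segment_velocity[s.id] for s in network.segments
         if s.kind != CAPILLARY and not s.occluded]
    return min(v) if v else float("nan")


def max_capillary_velocity(network: VascularNetwork, flow: FlowSolution) -> float:
    v = [flow.segment_velocity[s.id] for s in network.segments
         if s.kind == CAPILLARY and not s.occluded]
    return max(v) if v else float("nan")


def flow_to_dataframe(network: VascularNetwork, flow: FlowSolution):
    import pandas as pd

    rows = [{"segment": s.id, "kind": s.kind, "occluded": s.occluded,
             "flow": flow.segment_flow[s.id], "velocity": flow.segment_velocity[s.id]}
            for s in network.segments]
    return pd.DataFrame(rows)
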