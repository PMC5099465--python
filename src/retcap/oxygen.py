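"""Steady-state oxygen tension field.

The field couples (i) 1-D advection with wall offloading along every flowing
vessel segment, (ii) diffusion, cellular consumption and choroidal burn
sources in the tissue, and (iii) Dirichlet clamping of vessel sites to the
local intravascular tension.  The coupled fixed point alternates a
vessel-march sweep (segments processed in descending node-pressure order,
which is a topological order of the flow) with a tissue diffusion solve,
until the maximum site change falls below ``tol``.

Tissue consumption is zeroth-order per viable cell with a linear ramp to
zero below ``cutoff_po2``, which keeps the discrete operator an M-matrix:
the converged tension obeys the maximum principle (non-negative, bounded by
the largest source tension).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import OxygenConfig
from .errors import SolverError
from .geometry import Label, TissueGrid, VascularNetwork
from .hemodynamics import FlowSolution

_EDGE_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _grid_edges(ny: int, nx: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed 4-neighbour edge arrays (u, v) and per-site degree."""
    key = (ny, nx)
    if key not in _EDGE_CACHE:
        idx = np.arange(ny * nx).reshape(ny, nx)
        pairs = []
        if nx > 1:
            pairs.append((idx[:, :-1].ravel(), idx[:, 1:].ravel()))
        if ny > 1:
            pairs.append((idx[:-1, :].ravel(), idx[1:, :].ravel()))
        eu = np.concatenate([p[0] for p in pairs] + [p[1] for p in pairs])
        ev = np.concatenate([p[1] for p in pairs] + [p[0] for p in pairs])
        deg = np.bincount(eu, minlength=ny * nx)
        _EDGE_CACHE[key] = (eu, ev, deg)
    return _EDGE_CACHE[key]


class TissueDiffusionSolver:
    """Linearised tissue diffusion solve with cached factorisation.

    Solves ``D lap(P) - c(x, P) + sources = 0`` with zero-flux outer
    boundaries and Dirichlet sites, where ``c`` is the ramped consumption.
    The sparse LU is refactorised only when the Dirichlet-site set or the
    below-cutoff set changes, so repeated calls inside a fixed-point loop
    cost one triangular solve each.
    """

    def __init__(self, shape: tuple[int, int], spacing: float, diffusivity: float):
        self.ny, self.nx = shape
        self.n = self.ny * self.nx
        self.h2 = spacing * spacing
        self.diff = diffusivity / self.h2
        self.eu, self.ev, self.deg = _grid_edges(self.ny, self.nx)
        self._pattern: tuple[bytes, bytes] | None = None
        self._lu = None
        self._bmat = None
        self._unknown: np.ndarray | None = None
        self._diag_extra: np.ndarray | None = None

    def _factor(self, dir_mask: np.ndarray, diag_extra: np.ndarray) -> None:
        unknown = ~dir_mask
        unk_idx = np.nonzero(unknown)[0]
        pos = np.full(self.n, -1, dtype=np.int64)
        pos[unk_idx] = np.arange(len(unk_idx))
        keep = unknown[self.eu]
        eu, ev = self.eu[keep], self.ev[keep]
        to_unknown = unknown[ev]
        rows = pos[eu[to_unknown]]
        cols = pos[ev[to_unknown]]
        vals = np.full(len(rows), -self.diff)
        diag = self.diff * self.deg[unk_idx] + diag_extra[unk_idx]
        m = len(unk_idx)
        a = sp.csc_matrix(
            (np.concatenate([vals, diag]),
             (np.concatenate([rows, np.arange(m)]),
              np.concatenate([cols, np.arange(m)]))),
            shape=(m, m))
        self._lu = spla.splu(a)
        # unknown-to-Dirichlet coupling for the right-hand side
        bd = ~to_unknown
        self._bmat = sp.csr_matrix(
            (np.full(bd.sum(), self.diff), (pos[eu[bd]], ev[bd])),
            shape=(m, self.n))
        self._unknown = unk_idx

    def solve_linear(self, dir_mask: np.ndarray, dir_val: np.ndarray,
                     diag_extra: np.ndarray, source: np.ndarray) -> np.ndarray:
        """One linear solve; ``diag_extra``/``source`` hold the consumption
        linearisation.  Returns the full field (Dirichlet sites included)."""
        pattern = (np.packbits(dir_mask).tobytes(),
                   diag_extra.tobytes())
        if pattern != self._pattern:
            self._factor(dir_mask, diag_extra)
            self._pattern = pattern
        rhs = self._bmat @ np.where(dir_mask, dir_val, 0.0) + source[self._unknown]
        out = np.array(dir_val, dtype=float)
        out[self._unknown] = self._lu.solve(rhs)
        return out


@dataclass
class OxygenField:
    tension: np.ndarray                       # mmHg, [ny, nx]
    intravascular: dict[str, float]           # segment id -> outlet pO2 (NaN if no flow)
    hypoxia_threshold: float
    node_po2: dict[str, float] = field(default_factory=dict)
    iterations: int = 0

    def hypoxic_fraction(self, grid: TissueGrid, treated_only: bool = True) -> float:
        mask = hypoxic_mask(self, grid)
        if treated_only:
            mask = mask & grid.treated_mask()
        return float(mask.sum() * grid.site_area / grid.region_area)


def hypoxic_mask(oxy: OxygenField, grid: TissueGrid) -> np.ndarray:
    """True on viable (Mueller/other) sites strictly below the threshold."""
    return (oxy.tension < oxy.hypoxia_threshold) & grid.viable_mask()


def _flowing_segments(network: VascularNetwork, flow: FlowSolution) -> list:
    qmax = max((abs(q) for q in flow.segment_flow.values()), default=0.0)
    q_eps = max(1e-12 * qmax, 1e-30)
    return [s for s in network.segments
            if not s.occluded and abs(flow.segment_flow[s.id]) > q_eps]


def _march(network: VascularNetwork, flow: FlowSolution, grid: TissueGrid,
           cfg: OxygenConfig, tissue: np.ndarray, flowing: list,
           site_po2: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
    """March intravascular pO2 downstream; fills per-site clamp values.

    Along a segment of flow Q, diameter d and length L the intravascular
    tension relaxes exponentially toward the perivascular tissue mean with
    rate ``wall_exchange * pi * d / Q`` per µm (wall flux scales with the
    wall perimeter), so it is non-increasing downstream wherever the tissue
    is cooler than the blood.
    """
    flat = tissue.ravel()
    ring_mean: dict[str, float] = {}
    for s in flowing:
        ring = grid.ring_sites[s.id]
        ring_mean[s.id] = float(flat[ring].mean()) if len(ring) else 0.0

    by_node: dict[str, list] = {}
    for s in flowing:
        q = flow.segment_flow[s.id]
        down = s.node_b if q > 0 else s.node_a
        by_node.setdefault(down, []).append(s)

    order = sorted(network.nodes,
                   key=lambda nid: (-flow.node_pressure[nid], nid))
    node_po2: dict[str, float] = {}
    seg_out: dict[str, float] = {}
    for nid in order:
        if nid in network.inlet_nodes:
            node_po2[nid] = cfg.inlet_po2
        else:
            wsum = psum = 0.0
            for s in by_node.get(nid, []):
                if s.id in seg_out and np.isfinite(seg_out[s.id]):
                    q = abs(flow.segment_flow[s.id])
                    wsum += q
                    psum += q * seg_out[s.id]
            node_po2[nid] = psum / wsum if wsum > 0 else np.nan
        # emit outlet values for segments fed by this node
        _emit(nid, flowing, flow, cfg, ring_mean, node_po2, seg_out, grid, site_po2)
    return seg_out, node_po2


def _emit(nid, flowing, flow, cfg, ring_mean, node_po2, seg_out, grid, site_po2):
    p_up = node_po2.get(nid, np.nan)
    for s in flowing:
        q = flow.segment_flow[s.id]
        up = s.node_a if q > 0 else s.node_b
        if up != nid or s.id in seg_out:
            continue
        if not np.isfinite(p_up):
            seg_out[s.id] = np.nan
            continue
        pt = ring_mean[s.id]
        kappa = cfg.wall_exchange * np.pi * s.diameter / abs(q)   # 1/µm
        arc = grid.segment_arc[s.id]
        arc_up = arc if q > 0 else (s.length - arc)
        decay = np.exp(-np.minimum(kappa * arc_up, 60.0))
        site_po2[grid.segment_sites[s.id]] = pt + (p_up - pt) * decay
        seg_out[s.id] = float(pt + (p_up - pt) * np.exp(-min(kappa * s.length, 60.0)))


def solve_oxygen(network: VascularNetwork, flow: FlowSolution, grid: TissueGrid,
                 cfg: OxygenConfig, warm: np.ndarray | None = None) -> OxygenField:
    """Fixed point of the coupled advection / diffusion / consumption system."""
    ny, nx = grid.shape
    n = ny * nx
    labels = grid.labels.ravel()
    viable = (labels == Label.MUELLER) | (labels == Label.OTHER)
    burned = labels == Label.BURNED

    flowing = _flowing_segments(network, flow)
    vessel_clamp = np.zeros(n, dtype=bool)
    for s in flowing:
        vessel_clamp[grid.segment_sites[s.id]] = True
    dir_mask = vessel_clamp | burned

    consume = np.where(viable, cfg.consumption, 0.0)
    solver = TissueDiffusionSolver(grid.shape, grid.spacing, cfg.diffusivity)

    p = np.full(n, 0.6 * cfg.inlet_po2) if warm is None else warm.ravel().copy()
    dir_val = np.zeros(n)
    dir_val[burned] = cfg.choroid_po2
    seg_out: dict[str, float] = {}
    node_po2: dict[str, float] = {}
    delta = np.inf
    frozen_low: np.ndarray | None = None
    for it in range(1, cfg.max_iter + 1):
        site_po2 = np.zeros(n)
        seg_out, node_po2 = _march(network, flow, grid, cfg,
                                   p.reshape(ny, nx), flowing, site_po2)
        dir_val[vessel_clamp] = site_po2[vessel_clamp]
        dir_val[burned] = cfg.choroid_po2
        if frozen_low is None:
            low = viable & (p < cfg.cutoff_po2)
            if it == cfg.max_iter // 2:
                frozen_low = low  # stop cutoff-set chatter near the iteration cap
        else:
            low = frozen_low
        diag_extra = np.where(low, consume / cfg.cutoff_po2, 0.0)
        source = np.where(viable & ~low, -consume, 0.0)
        p_new = solver.solve_linear(dir_mask, dir_val, diag_extra, source)
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < cfg.tol and it > 1:
            break
    else:
        raise SolverError(
            f"oxygen solve did not converge in {cfg.max_iter} iterations",
            residual=delta)

    # stagnant (no-flow) vessel segments carry no intravascular value
    for s in network.segments:
        if s.id not in seg_out:
            seg_out[s.id] = np.nan
    p = np.maximum(p, 0.0)
    return OxygenField(tension=p.reshape(ny, nx), intravascular=seg_out,
                       hypoxia_threshold=cfg.hypoxia_threshold,
                       node_po2=node_po2, iterations=it)
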