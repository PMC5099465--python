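"""Steady-state VEGF field from oxygen-gated Mueller-cell synthesis.

VEGF obeys the screened diffusion (linear Helmholtz) equation

    D_V lap(V) - k V + sigma(x) = 0,    zero-flux outer boundary,

with sigma = ``hypoxic_rate`` on hypoxic Mueller sites, ``basal_rate`` on
normoxic Mueller sites and zero elsewhere (burned and vessel sites
synthesise nothing).  Consumption by all cell types, endothelium included,
is folded into the uniform first-order decay ``k``; an optional extra sink
on the large-vessel (arteriole/venule/shunt) columns represents the denser
endothelial mass of their walls, which screens VEGF from crossing them.  The equation is linear, so the field scales
with the synthesis rates and is monotone in the hypoxic set.

Because only ratios enter the occlusion probability, the field is reported
normalised to the basal steady level ``basal_rate / k`` of a uniformly
normoxic all-Mueller tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import VegfConfig
from .geometry import Label, TissueGrid
from .oxygen import OxygenField, _grid_edges, hypoxic_mask

_LU_CACHE: dict[tuple, spla.SuperLU] = {}


def _helmholtz_lu(shape: tuple[int, int], spacing: float, diffusivity: float,
                  decay: np.ndarray | float):
    ny, nx = shape
    n = ny * nx
    if np.isscalar(decay):
        key = (ny, nx, spacing, diffusivity, float(decay))
        decay_arr = np.full(n, float(decay))
    else:
        decay_arr = np.asarray(decay, dtype=float)
        key = (ny, nx, spacing, diffusivity, decay_arr.tobytes())
    if key not in _LU_CACHE:
        eu, ev, deg = _grid_edges(ny, nx)
        d = diffusivity / spacing**2
        rows = np.concatenate([eu, np.arange(n)])
        cols = np.concatenate([ev, np.arange(n)])
        vals = np.concatenate([np.full(len(eu), -d), d * deg + decay_arr])
        if len(_LU_CACHE) > 8:
            _LU_CACHE.clear()
        _LU_CACHE[key] = spla.splu(sp.csc_matrix((vals, (rows, cols)), shape=(n, n)))
    return _LU_CACHE[key]


@dataclass
class VegfField:
    concentration: np.ndarray            # a.u., [ny, nx]
    normalized: np.ndarray               # concentration / (basal_rate / decay)
    basal_rate: float
    hypoxic_rate: float
    decay_rate: float
    diffusivity: float

    def perivascular_level(self, grid: TissueGrid, segment_id: str) -> float:
        """Mean basal-normalised VEGF over a segment's perivascular ring."""
        ring = grid.ring_sites[segment_id]
        if len(ring) == 0:
            return 0.0
        return float(self.normalized.ravel()[ring].mean())


def synthesis_map(grid: TissueGrid, oxy: OxygenField, cfg: VegfConfig) -> np.ndarray:
    """Per-site synthesis rate: hypoxia-gated for Mueller cells only."""
    mueller = grid.labels == Label.MUELLER
    hyp = hypoxic_mask(oxy, grid)
    sigma = np.zeros(grid.shape)
    sigma[mueller] = cfg.basal_rate
    sigma[mueller & hyp] = cfg.hypoxic_rate
    return sigma


def solve_vegf(grid: TissueGrid, oxy: OxygenField, cfg: VegfConfig) -> VegfField:
    ny, nx = grid.shape
    decay: np.ndarray | float = cfg.decay
    if cfg.vessel_sink > 0.0 and len(grid.large_vessel_sites):
        decay = np.full(ny * nx, cfg.decay)
        decay[grid.large_vessel_sites] += cfg.vessel_sink
    lu = _helmholtz_lu(grid.shape, grid.spacing, cfg.diffusivity, decay)
    sigma = synthesis_map(grid, oxy, cfg)
    v = lu.solve(sigma.ravel()).reshape(ny, nx)
    v = np.maximum(v, 0.0)
    basal_level = cfg.basal_rate / cfg.decay
    return VegfField(concentration=v, normalized=v / basal_level,
                     basal_rate=cfg.basal_rate, hypoxic_rate=cfg.hypoxic_rate,
                     decay_rate=cfg.decay, diffusivity=cfg.diffusivity)
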