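"""Photocoagulation burn patterns: dots, bands, and the PRP comparator.

Bands are rectangles perpendicular to the boundary vessels, spanning the
arteriole-venule distance (or centred mid-sector when shortened); dots are
squares placed alongside the arteriole and the venule of each treated
sector.  Patterns are rasterised with an overlap-majority rule: a lattice
site is burned when the pattern covers at least half of its area, so
realised burn sizes are close to, but not exactly, the requested ones.

The panretinal photocoagulation (PRP) comparator is not rasterised: typical
PRP spots and their spacing are larger than a whole modelled sector, so it
enters the evaluation as an arithmetic rule — 0.28 of the retina burned,
with the tissue between spots progressing as in the untreated case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GeometryConfig, PatternConfig
from .errors import ConfigurationError
from .geometry import Label, TissueGrid

PRP_BURN_FRACTION = 0.28

#: reference dot edge (µm): the N label counts 100 µm-wide bands, and the
#: equal-area dot pattern uses 100 x 100 µm dots, 3N of them per two sectors.
REFERENCE_DOT_EDGE = 100.0
REFERENCE_BAND_WIDTH = 100.0


@dataclass
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass
class BurnPattern:
    kind: str                            # none | dot | band | prp
    N: int
    S: float | None = None
    L: float | None = None
    W: float | None = None
    rects: list[Rect] = field(default_factory=list)
    mask: np.ndarray | None = None       # boolean [ny, nx], realised burn sites
    realized_area: float = 0.0           # µm²
    intended_area: float = 0.0           # µm²
    normalized_burn_area: float = 0.0    # realised / treated-region area
    gap: float | None = None             # µm: inter-dot gap, or band-to-vessel gap

    def describe(self) -> str:
        bits = [self.kind, f"N={self.N}"]
        for name in ("S", "L", "W"):
            val = getattr(self, name)
            if val is not None:
                bits.append(f"{name}={val:g}")
        return " ".join(bits)


def _rasterize(rects: list[Rect], grid: TissueGrid) -> np.ndarray:
    """Overlap-majority rasterisation of axis-aligned rectangles.

    Each rectangle edge snaps to the nearest lattice line (half-up), which is
    the per-axis majority rule: a row or column of cells is burned when the
    rectangle covers at least half of it, with exact halves resolved towards
    the upper edge so opposite edges never double-count.
    """
    ny, nx = grid.shape
    h = grid.spacing
    mask = np.zeros((ny, nx), dtype=bool)
    for r in rects:
        ix0 = int(np.floor(r.x0 / h + 0.5))
        ix1 = int(np.floor(r.x1 / h + 0.5))
        iy0 = int(np.floor(r.y0 / h + 0.5))
        iy1 = int(np.floor(r.y1 / h + 0.5))
        mask[max(iy0, 0):min(iy1, ny), max(ix0, 0):min(ix1, nx)] = True
    return mask


def _finalize(kind: str, N: int, rects: list[Rect], grid: TissueGrid,
              geometry: GeometryConfig, *, S=None, L=None, W=None,
              gap=None) -> BurnPattern:
    for i, a in enumerate(rects):
        for b in rects[i + 1:]:
            if a.x0 < b.x1 and b.x0 < a.x1 and a.y0 < b.y1 and b.y0 < a.y1:
                raise ConfigurationError(
                    f"burn rectangles overlap (N={N} too dense for these sizes)")
        if not (0 <= a.y0 and a.y1 <= geometry.sector_length):
            raise ConfigurationError("burns overflow the sector length")
    mask = _rasterize(rects, grid)
    realized = float(mask.sum()) * grid.site_area
    intended = float(sum(r.area for r in rects))
    return BurnPattern(kind=kind, N=N, S=S, L=L, W=W, rects=rects, mask=mask,
                       realized_area=realized, intended_area=intended,
                       normalized_burn_area=realized / grid.region_area,
                       gap=gap)


def _sector_bounds(geometry: GeometryConfig, sector: int) -> tuple[float, float]:
    x0 = sector * geometry.av_distance
    return x0, x0 + geometry.av_distance


def _wall_offsets(geometry: GeometryConfig, sector: int) -> tuple[float, float]:
    """Half-diameters of the bounding vessels (left wall, right wall)."""
    left_kind_art = sector % 2 == 0
    d_left = geometry.arteriole_diameter if left_kind_art else geometry.venule_diameter
    d_right = geometry.venule_diameter if left_kind_art else geometry.arteriole_diameter
    return d_left / 2.0, d_right / 2.0


def make_band_pattern(N: int, L: float, W: float, geometry: GeometryConfig,
                      grid: TissueGrid) -> BurnPattern:
    """N rectangular bands of length L (across the sector) and width W.

    Bands are split evenly between the two treated sectors, evenly spaced
    along the sector length with equal end margins, perpendicular to the
    boundary vessels.  Shortened bands (L < av_distance) are centred
    mid-sector, leaving a gap of (av_distance - L) / 2 to each vessel.
    """
    if N < 2 or N % 2 != 0:
        raise ConfigurationError("band pattern N must be a positive even count")
    if L <= 0 or L > geometry.av_distance:
        raise ConfigurationError("band length L must lie in (0, av_distance]")
    if W <= 0:
        raise ConfigurationError("band width W must be positive")
    n_per = N // len(geometry.treated_sectors)
    hgt = geometry.sector_length
    margin = (hgt - n_per * W) / (n_per + 1)
    if margin <= 0:
        raise ConfigurationError("bands overlap: N * W exceeds the sector length")
    rects = []
    for s in geometry.treated_sectors:
        x0, x1 = _sector_bounds(geometry, s)
        cx = 0.5 * (x0 + x1)
        for i in range(n_per):
            y0 = margin * (i + 1) + W * i
            rects.append(Rect(cx - L / 2, y0, cx + L / 2, y0 + W))
    gap = (geometry.av_distance - L) / 2.0
    return _finalize("band", N, rects, grid, geometry, L=L, W=W, gap=gap)


def dot_count(N: int, geometry: GeometryConfig) -> int:
    """Number of dots carrying the same total area as N reference bands.

    The dot grid is defined at the reference 100 µm edge; smaller-S sweeps
    keep these dot centres fixed (the 'N spacing') and shrink each square.
    """
    return int(round(N * geometry.av_distance * REFERENCE_BAND_WIDTH
                     / REFERENCE_DOT_EDGE**2))


def make_dot_pattern(N: int, S: float, geometry: GeometryConfig,
                     grid: TissueGrid) -> BurnPattern:
    """Square dots of edge S alongside the arteriole and venule columns.

    The dot count is area-matched to N bands at the reference 100 µm edge
    and distributed round-robin over the four vessel-adjacent columns of the
    two treated sectors.  Within a column, dots are evenly spaced with equal
    end margins; the realised inter-dot gap is pitch - S.
    """
    if N < 1:
        raise ConfigurationError("dot pattern N must be >= 1")
    if S <= 0:
        raise ConfigurationError("dot edge S must be positive")
    total = dot_count(N, geometry)
    columns = []                          # (x_inner_edge_start, +1/-1 direction)
    h = grid.spacing
    for s in geometry.treated_sectors:
        x0, x1 = _sector_bounds(geometry, s)
        d_left, d_right = _wall_offsets(geometry, s)
        columns.append((x0 + d_left + h, +1))     # one lattice site off the wall
        columns.append((x1 - d_right - h, -1))
    per_col = [total // len(columns)] * len(columns)
    for k in range(total % len(columns)):
        per_col[k] += 1
    hgt = geometry.sector_length
    rects = []
    gaps = []
    for (x_edge, direction), n_dots in zip(columns, per_col):
        if n_dots == 0:
            continue
        g = (hgt - n_dots * S) / (n_dots + 1)
        if g < 0:
            raise ConfigurationError("dots overflow the sector length")
        gaps.append(g)
        for i in range(n_dots):
            y0 = g * (i + 1) + S * i
            xa = x_edge if direction > 0 else x_edge - S
            rects.append(Rect(xa, y0, xa + S, y0 + S))
    gap = float(np.mean(gaps)) if gaps else None
    return _finalize("dot", N, rects, grid, geometry, S=S, gap=gap)


def make_prp_comparator(geometry: GeometryConfig) -> BurnPattern:
    """The standard-PRP arithmetic comparator (not rasterised)."""
    p = BurnPattern(kind="prp", N=0, normalized_burn_area=PRP_BURN_FRACTION)
    p.mask = None
    return p


def prp_estimated_total(control_median_ischemia: float) -> float:
    """PRP outcome estimate: burned fraction plus untreated-style ischemic
    progression scaled to the unburned remainder of the retina."""
    f = PRP_BURN_FRACTION
    return f + (1.0 - f) * control_median_ischemia


def make_pattern(pattern: PatternConfig, geometry: GeometryConfig,
                 grid: TissueGrid) -> BurnPattern:
    if pattern.kind == "none":
        return BurnPattern(kind="none", N=0,
                           mask=np.zeros(grid.shape, dtype=bool))
    if pattern.kind == "band":
        return make_band_pattern(pattern.N, pattern.L, pattern.W, geometry, grid)
    if pattern.kind == "dot":
        return make_dot_pattern(pattern.N, pattern.S, geometry, grid)
    if pattern.kind == "prp":
        return make_prp_comparator(geometry)
    raise ConfigurationError(f"unknown pattern kind {pattern.kind!r}")


def apply_burn(grid: TissueGrid, pattern: BurnPattern) -> TissueGrid:
    """Relabel viable cells under the mask as photocoagulated.

    Vessel segments under a burn are left intact (burns ablate the oxygen
    sinks, not the inner-retinal vasculature, by default).  Returns a new
    grid; the input is unchanged.
    """
    out = grid.copy()
    if pattern.mask is not None and pattern.kind != "none":
        burnable = out.viable_mask() & pattern.mask
        out.labels[burnable] = Label.BURNED
    return out
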