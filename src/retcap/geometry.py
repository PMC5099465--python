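"""Schematic peripheral-retina vascular network and tissue lattice.

The network is a ladder: vertical boundary vessels (alternating arteriole /
venule) every ``av_distance`` µm, a horizontal shunt vessel joining their
tops, and horizontal capillary rungs spanning each A/V sector.  The tissue
between vessels is tiled deterministically with Mueller cells and other
retinal cells.

Coordinates are continuous µm with the origin at the lower-left corner of
the modelled patch; lattice sites are half-open squares of edge
``spacing`` whose centres sit at ``(i + 0.5) * spacing``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

from .config import GeometryConfig
from .errors import ConfigurationError

ARTERIOLE = "arteriole"
VENULE = "venule"
SHUNT = "shunt"
CAPILLARY = "capillary"

LARGE_VESSEL_KINDS = frozenset({ARTERIOLE, VENULE, SHUNT})


class Label(IntEnum):
    """Per-site tissue labels."""

    MUELLER = 0
    OTHER = 1
    VESSEL = 2
    BURNED = 3
    OUTSIDE = 4


VIABLE_LABELS = (Label.MUELLER, Label.OTHER)


@dataclass
class Node:
    id: str
    x: float
    y: float
    pressure: float | None = None       # boundary pressure, mmHg, if fixed


@dataclass
class VesselSegment:
    id: str
    kind: str                            # arteriole | venule | shunt | capillary
    node_a: str
    node_b: str
    diameter: float                      # µm
    length: float                        # µm, straight (raster) length
    occluded: bool = False
    sector: int | None = None            # for capillary rungs
    hydraulic_length: float | None = None  # µm; tortuous path length for flow

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise ConfigurationError(f"segment {self.id}: non-positive diameter/length")
        if self.node_a == self.node_b:
            raise ConfigurationError(f"segment {self.id}: degenerate (node_a == node_b)")
        if self.hydraulic_length is None:
            self.hydraulic_length = self.length


@dataclass
class VascularNetwork:
    nodes: dict[str, Node]
    segments: list[VesselSegment]
    inlet_nodes: set[str]
    outlet_nodes: set[str]

    def __post_init__(self):
        self._by_id = {s.id: s for s in self.segments}

    def segment(self, seg_id: str) -> VesselSegment:
        try:
            return self._by_id[seg_id]
        except KeyError:
            raise KeyError(f"unknown segment id {seg_id!r}") from None

    @property
    def capillaries(self) -> list[VesselSegment]:
        return [s for s in self.segments if s.kind == CAPILLARY]

    def open_capillaries(self, sectors: tuple[int, ...] | None = None) -> list[VesselSegment]:
        caps = [s for s in self.capillaries if not s.occluded]
        if sectors is not None:
            caps = [s for s in caps if s.sector in sectors]
        return caps

    def boundary_pressures(self) -> dict[str, float]:
        return {n.id: n.pressure for n in self.nodes.values() if n.pressure is not None}

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, x=n.x, y=n.y,
                       pressure=float("nan") if n.pressure is None else n.pressure)
        for s in self.segments:
            g.add_edge(s.node_a, s.node_b, key=s.id, kind=s.kind,
                       diameter=s.diameter, length=s.length, occluded=s.occluded)
        return g

    def to_json(self, path: str | Path | None = None) -> str:
        data = {
            "nodes": [{"id": n.id, "x": n.x, "y": n.y, "pressure": n.pressure}
                      for n in self.nodes.values()],
            "segments": [{"id": s.id, "kind": s.kind, "node_a": s.node_a,
                          "node_b": s.node_b, "diameter": s.diameter,
                          "length": s.length, "occluded": s.occluded,
                          "sector": s.sector}
                         for s in self.segments],
            "inlet_nodes": sorted(self.inlet_nodes),
            "outlet_nodes": sorted(self.outlet_nodes),
        }
        text = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class TissueGrid:
    """2-D lattice of cell labels with per-site sector indices.

    ``labels`` is indexed ``[iy, ix]`` with y increasing upward.  Vessel
    rasterisation bookkeeping (which sites belong to which segment, and the
    one-site perivascular ring around each segment) is precomputed here and
    consumed by the oxygen/VEGF solvers.
    """

    spacing: float
    labels: np.ndarray                   # int8 [ny, nx]
    sector_index: np.ndarray             # int16 [ny, nx]
    region_area: float                   # µm², treated sectors
    treated_sectors: tuple[int, ...]
    segment_sites: dict[str, np.ndarray] = field(default_factory=dict)   # flat indices
    segment_arc: dict[str, np.ndarray] = field(default_factory=dict)     # µm from node_a
    ring_sites: dict[str, np.ndarray] = field(default_factory=dict)      # flat indices
    large_vessel_sites: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))             # flat indices

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def site_area(self) -> float:
        return self.spacing ** 2

    def viable_mask(self) -> np.ndarray:
        return (self.labels == Label.MUELLER) | (self.labels == Label.OTHER)

    def treated_mask(self) -> np.ndarray:
        m = np.zeros(self.labels.shape, dtype=bool)
        for s in self.treated_sectors:
            m |= self.sector_index == s
        return m

    def centres(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.labels.shape
        xc = (np.arange(nx) + 0.5) * self.spacing
        yc = (np.arange(ny) + 0.5) * self.spacing
        return xc, yc

    def labels_to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.labels, fmt="%d", delimiter=",")

    def copy(self) -> "TissueGrid":
        return TissueGrid(
            spacing=self.spacing,
            labels=self.labels.copy(),
            sector_index=self.sector_index,
            region_area=self.region_area,
            treated_sectors=self.treated_sectors,
            segment_sites=self.segment_sites,
            segment_arc=self.segment_arc,
            ring_sites=self.ring_sites,
            large_vessel_sites=self.large_vessel_sites,
        )


def _column_kind(c: int) -> str:
    return ARTERIOLE if c % 2 == 0 else VENULE


def _vessel_diameter(cfg: GeometryConfig, kind: str) -> float:
    return {
        ARTERIOLE: cfg.arteriole_diameter,
        VENULE: cfg.venule_diameter,
        SHUNT: cfg.shunt_diameter,
        CAPILLARY: cfg.capillary_diameter,
    }[kind]


def rung_y_positions(cfg: GeometryConfig) -> np.ndarray:
    """Capillary rung centrelines, evenly spaced along the sector."""
    pitch = cfg.sector_length / cfg.n_rungs
    return (np.arange(cfg.n_rungs) + 0.5) * pitch


def shunt_y(cfg: GeometryConfig) -> float:
    return cfg.sector_length - cfg.shunt_diameter / 2.0


def build_peripheral_network(cfg: GeometryConfig) -> VascularNetwork:
    """Construct the ladder network: boundary vessels, shunt, capillary rungs.

    Deterministic pure construction: two calls with equal configs produce
    identical node and segment lists.
    """
    violations = cfg.validate()
    if violations:
        raise ConfigurationError("; ".join(violations))

    nodes: dict[str, Node] = {}
    segments: list[VesselSegment] = []
    inlets: set[str] = set()
    outlets: set[str] = set()
    ys = rung_y_positions(cfg)
    y_top = shunt_y(cfg)

    for c in range(cfg.n_sectors + 1):
        x = c * cfg.av_distance
        kind = _column_kind(c)
        d = _vessel_diameter(cfg, kind)
        bottom = f"c{c}_b"
        if kind == ARTERIOLE:
            nodes[bottom] = Node(bottom, x, 0.0, pressure=cfg.inlet_pressure)
            inlets.add(bottom)
        else:
            nodes[bottom] = Node(bottom, x, 0.0, pressure=cfg.outlet_pressure)
            outlets.add(bottom)
        prev, prev_y = bottom, 0.0
        for i, y in enumerate(ys):
            nid = f"c{c}_r{i}"
            nodes[nid] = Node(nid, x, float(y))
            segments.append(VesselSegment(f"{kind[0]}{c}_{i}", kind, prev, nid, d,
                                          float(y - prev_y)))
            prev, prev_y = nid, float(y)
        top = f"c{c}_t"
        nodes[top] = Node(top, x, y_top)
        segments.append(VesselSegment(f"{kind[0]}{c}_top", kind, prev, top, d,
                                      float(y_top - prev_y)))

    for s in range(cfg.n_sectors):
        for i in range(cfg.n_rungs):
            segments.append(VesselSegment(
                f"cap_s{s}_r{i}", CAPILLARY, f"c{s}_r{i}", f"c{s + 1}_r{i}",
                cfg.capillary_diameter, cfg.av_distance, sector=s,
                hydraulic_length=cfg.av_distance * cfg.capillary_tortuosity))

    for c in range(cfg.n_sectors):
        segments.append(VesselSegment(f"shunt_{c}", SHUNT, f"c{c}_t", f"c{c + 1}_t",
                                      cfg.shunt_diameter, cfg.av_distance))

    return VascularNetwork(nodes, segments, inlets, outlets)


def _nearest_indices(centrelines: np.ndarray, target: float, count: int,
                     n_max: int) -> np.ndarray:
    """Indices of the ``count`` lattice rows/columns nearest ``target``."""
    order = np.argsort(np.abs(centrelines - target), kind="stable")
    idx = np.sort(order[:count])
    return idx[(idx >= 0) & (idx < n_max)]


def _cell_block_parity(n: int, a_sites: int, b_sites: int) -> np.ndarray:
    """0/1 block parity along one axis for alternating cell-size stripes."""
    period = a_sites + b_sites
    pos = np.arange(n) % period
    return (pos >= a_sites).astype(np.int8)


def tile_tissue(network: VascularNetwork, cfg: GeometryConfig) -> TissueGrid:
    """Rasterise vessels onto the lattice and tile the interstitium.

    Mueller and other retinal cells interleave in a deterministic
    checkerboard of blocks snapped to the lattice (nominal sizes 24 µm and
    21 µm).  Every vessel segment records its site set, the arc position of
    each site along the segment, and a one-site perivascular ring used for
    wall exchange and perivascular VEGF sampling.
    """
    violations = cfg.validate()
    if violations:
        raise ConfigurationError("; ".join(violations))
    h = cfg.spacing
    nx = int(round(cfg.width / h))
    ny = int(round(cfg.sector_length / h))
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h

    # deterministic interleaved tiling of Mueller / other cell blocks
    m_sites = max(1, round(cfg.mueller_size / h))
    o_sites = max(1, round(cfg.other_size / h))
    px = _cell_block_parity(nx, m_sites, o_sites)
    py = _cell_block_parity(ny, m_sites, o_sites)
    labels = np.where((px[None, :] + py[:, None]) % 2 == 0,
                      np.int8(Label.MUELLER), np.int8(Label.OTHER))

    sector = np.clip(np.floor(xc / cfg.av_distance).astype(np.int16), 0,
                     cfg.n_sectors - 1)
    sector_index = np.broadcast_to(sector[None, :], (ny, nx)).copy()

    node = network.nodes
    seg_sites: dict[str, np.ndarray] = {}
    seg_arc: dict[str, np.ndarray] = {}

    def add_segment_sites(seg: VesselSegment, iys: np.ndarray, ixs: np.ndarray) -> None:
        iy_g, ix_g = np.meshgrid(iys, ixs, indexing="ij")
        flat = (iy_g * nx + ix_g).ravel()
        a = node[seg.node_a]
        if abs(node[seg.node_b].x - a.x) > abs(node[seg.node_b].y - a.y):
            arc = np.abs(xc[ix_g.ravel()] - a.x)
        else:
            arc = np.abs(yc[iy_g.ravel()] - a.y)
        seg_sites[seg.id] = flat
        seg_arc[seg.id] = arc

    # vertical boundary vessels first (they own their columns), then rungs/shunt
    for seg in network.segments:
        if seg.kind in (ARTERIOLE, VENULE):
            a, b = node[seg.node_a], node[seg.node_b]
            w = max(1, round(seg.diameter / h))
            ixs = _nearest_indices(xc, a.x, w, nx)
            y_lo, y_hi = sorted((a.y, b.y))
            iys = np.nonzero((yc >= y_lo) & (yc < y_hi))[0]
            if len(iys) == 0:
                iys = _nearest_indices(yc, 0.5 * (y_lo + y_hi), 1, ny)
            add_segment_sites(seg, iys, ixs)
            labels[np.ix_(iys, ixs)] = Label.VESSEL

    vertical_vessel = labels == Label.VESSEL
    for seg in network.segments:
        if seg.kind in (CAPILLARY, SHUNT):
            a, b = node[seg.node_a], node[seg.node_b]
            w = max(1, round(seg.diameter / h))
            iys = _nearest_indices(yc, a.y, w, ny)
            x_lo, x_hi = sorted((a.x, b.x))
            ixs = np.nonzero((xc >= x_lo) & (xc < x_hi) &
                             ~vertical_vessel[iys[0], :])[0]
            add_segment_sites(seg, iys, ixs)
            labels[np.ix_(iys, ixs)] = Label.VESSEL

    grid = TissueGrid(
        spacing=h,
        labels=labels,
        sector_index=sector_index,
        region_area=cfg.region_area,
        treated_sectors=tuple(cfg.treated_sectors),
        segment_sites=seg_sites,
        segment_arc=seg_arc,
    )
    vessel_all = labels == Label.VESSEL
    for seg in network.segments:
        grid.ring_sites[seg.id] = _ring(seg_sites[seg.id], vessel_all, ny, nx)
    large = [seg_sites[s.id] for s in network.segments if s.kind != CAPILLARY]
    if large:
        grid.large_vessel_sites = np.unique(np.concatenate(large))
    return grid


def _ring(flat: np.ndarray, vessel_mask: np.ndarray, ny: int, nx: int) -> np.ndarray:
    """One-site dilation of a site set, excluding all vessel sites."""
    iy, ix = np.divmod(flat, nx)
    cand = []
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        yy, xx = iy + dy, ix + dx
        ok = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
        cand.append(yy[ok] * nx + xx[ok])
    cand = np.unique(np.concatenate(cand))
    keep = ~vessel_mask.ravel()[cand]
    return cand[keep]


def build_geometry(cfg: GeometryConfig) -> tuple[VascularNetwork, TissueGrid]:
    network = build_peripheral_network(cfg)
    return network, tile_tissue(network, cfg)
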