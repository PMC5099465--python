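"""Shared fixtures: a tiny fast geometry and the session-wide default model."""

from __future__ import annotations

import numpy as np
import pytest

import retcap as rc
from retcap.config import GeometryConfig, RunConfig


def tiny_run_config() -> RunConfig:
    """A reduced two-sector ladder that solves in milliseconds."""
    cfg = RunConfig()
    cfg.geometry = GeometryConfig(
        n_sectors=2, treated_sectors=(0, 1), sector_length=385.0, n_rungs=5)
    return cfg


@pytest.fixture()
def tiny_cfg() -> RunConfig:
    return tiny_run_config()


@pytest.fixture()
def tiny_geometry(tiny_cfg):
    return rc.build_geometry(tiny_cfg.geometry)


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def default_geometry(default_cfg):
    return rc.build_geometry(default_cfg.geometry)


@pytest.fixture(scope="session")
def default_flow(default_cfg, default_geometry):
    network, _ = default_geometry
    return rc.solve_flow(network, viscosity=default_cfg.viscosity)


@pytest.fixture(scope="session")
def default_oxygen(default_cfg, default_geometry, default_flow):
    network, grid = default_geometry
    return rc.solve_oxygen(network, default_flow, grid, default_cfg.oxygen)


@pytest.fixture(scope="session")
def default_vegf(default_cfg, default_geometry, default_oxygen):
    _, grid = default_geometry
    return rc.solve_vegf(grid, default_oxygen, default_cfg.vegf)


@pytest.fixture(scope="session")
def occluded_sector_state(default_cfg):
    """Default geometry with every sector-1 rung occluded, re-equilibrated."""
    cfg = default_cfg
    network, grid = rc.build_geometry(cfg.geometry)
    for seg in network.capillaries:
        if seg.sector == 1:
            rc.occlude_segment(network, seg.id)
    flow = rc.solve_flow(network, viscosity=cfg.viscosity)
    oxy = rc.solve_oxygen(network, flow, grid, cfg.oxygen)
    vegf = rc.solve_vegf(grid, oxy, cfg.vegf)
    return network, grid, flow, oxy, vegf


def make_line_grid(n: int, spacing: float = 5.0,
                   label: int = int(rc.Label.OTHER)) -> rc.TissueGrid:
    """A 1 x n pseudo-1-D tissue grid for closed-form solver checks."""
    labels = np.full((1, n), label, dtype=np.int8)
    return rc.TissueGrid(
        spacing=spacing, labels=labels,
        sector_index=np.zeros((1, n), dtype=np.int16),
        region_area=n * spacing * spacing, treated_sectors=(0,))
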