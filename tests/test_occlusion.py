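"""Occlusion probability model and the stochastic event loop."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import retcap as rc
from retcap.config import OcclusionModel
from retcap.occlusion import (initial_state, occlusion_probability, run,
                              seed_initial_occlusion, step)
from tests.conftest import tiny_run_config


def tiny_state(cfg=None):
    cfg = cfg or tiny_run_config()
    network, grid = rc.build_geometry(cfg.geometry)
    return initial_state(network, grid, cfg)


def test_hill_midpoint_and_velocity_limits():
    m = OcclusionModel()
    assert occlusion_probability(m, 0.0, m.vegf_half) == pytest.approx(m.p_max / 2)
    assert occlusion_probability(m, 1e9, 100.0) == pytest.approx(0.0, abs=1e-30)
    assert occlusion_probability(m, 0.0, 0.0) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(v=st.floats(0, 1e5), dv=st.floats(1e-3, 1e4),
       vegf=st.floats(0.01, 100), dV=st.floats(1e-3, 100))
def test_probability_monotone_and_bounded(v, dv, vegf, dV):
    m = OcclusionModel()
    p = occlusion_probability(m, v, vegf)
    assert 0.0 <= p <= 1.0
    assert occlusion_probability(m, v + dv, vegf) <= p
    assert occlusion_probability(m, v, vegf + dV) >= p


def test_negative_inputs_rejected():
    m = OcclusionModel()
    with pytest.raises(ValueError):
        occlusion_probability(m, -1.0, 1.0)
    with pytest.raises(ValueError):
        occlusion_probability(m, 1.0, -1.0)


def test_large_vessels_protected_at_basal_vegf(default_cfg, default_geometry,
                                               default_flow, default_vegf):
    network, grid = default_geometry
    m = default_cfg.occlusion
    for seg in network.segments:
        if seg.kind == "capillary":
            continue
        v = default_flow.segment_velocity[seg.id]
        vegf = default_vegf.perivascular_level(grid, seg.id)
        assert occlusion_probability(m, v, vegf) < 1e-4


def test_capillaries_quiescent_at_basal_vegf(default_cfg, default_geometry,
                                             default_flow, default_vegf):
    """Without a seed occlusion the intact network produces no cascades."""
    network, grid = default_geometry
    m = default_cfg.occlusion
    for seg in network.capillaries:
        p = occlusion_probability(m, default_flow.segment_velocity[seg.id],
                                  default_vegf.perivascular_level(grid, seg.id))
        assert p < 1e-4


def test_seed_is_deterministic_and_treated_only(monkeypatch):
    import retcap.occlusion as occ

    cfg = rc.RunConfig()
    network, grid = rc.build_geometry(cfg.geometry)
    base = occ.SimulationState(t=0.0, network=network, grid=grid, flow=None,
                               oxy=None, vegf=None, config=cfg)
    monkeypatch.setattr(occ, "equilibrate", lambda s: s)
    first = None
    counts = {}
    for trial in range(400):
        st_ = base.clone()
        rng = np.random.default_rng(123 if trial == 0 else trial)
        seed_initial_occlusion(st_, rng)
        (week, sid), = st_.events
        assert week == 0.0
        seg = st_.network.segment(sid)
        assert seg.kind == "capillary"
        assert seg.sector in cfg.geometry.treated_sectors
        counts[sid] = counts.get(sid, 0) + 1
        if trial == 0:
            first = sid
    st2 = base.clone()
    seed_initial_occlusion(st2, np.random.default_rng(123))
    assert st2.events[0][1] == first
    # all 20 treated rungs are reachable, roughly uniformly
    assert len(counts) == 20
    expected = 400 / 20
    assert max(counts.values()) < 3 * expected


def test_seed_choice_is_uniform(monkeypatch):
    """Selection frequencies match a uniform draw over candidates."""
    import retcap.occlusion as occ

    cfg = tiny_run_config()
    network, grid = rc.build_geometry(cfg.geometry)
    base = occ.SimulationState(t=0.0, network=network, grid=grid, flow=None,
                               oxy=None, vegf=None, config=cfg)
    monkeypatch.setattr(occ, "equilibrate", lambda s: s)
    n_caps = len(network.capillaries)
    draws = 10_000
    counts = np.zeros(n_caps)
    ids = sorted(s.id for s in network.capillaries)
    rng = np.random.default_rng(0)
    for _ in range(draws):
        st_ = base.clone()
        seed_initial_occlusion(st_, rng)
        counts[ids.index(st_.events[0][1])] += 1
    expected = draws / n_caps
    sigma = np.sqrt(expected * (1 - 1 / n_caps))
    assert np.all(np.abs(counts - expected) <= 4 * sigma)


def test_seed_requires_open_candidates():
    cfg = tiny_run_config()
    state = tiny_state(cfg)
    for seg in state.network.capillaries:
        rc.occlude_segment(state.network, seg.id)
    with pytest.raises(rc.StateError):
        seed_initial_occlusion(state, np.random.default_rng(0))


def test_null_process_only_advances_time():
    cfg = tiny_run_config()
    cfg.occlusion = dataclasses.replace(cfg.occlusion, p_max=0.0)
    state = tiny_state(cfg)
    t0, events0 = state.t, list(state.events)
    step(state, cfg.occlusion, np.random.default_rng(0))
    assert state.t == t0 + cfg.occlusion.examination_interval
    assert state.events == events0


def test_run_zero_duration_is_identity():
    cfg = tiny_run_config()
    state = tiny_state(cfg)
    state, traj = run(state, cfg.occlusion, 0.0, np.random.default_rng(0))
    assert state.t == 0.0 and state.events == []


def test_same_seed_reproduces_event_list_exactly():
    cfg = tiny_run_config()
    logs = []
    for _ in range(2):
        state = tiny_state(cfg)
        rng = np.random.default_rng(42)
        seed_initial_occlusion(state, rng)
        state, _ = run(state, cfg.occlusion, 40.0, rng)
        logs.append(list(state.events))
    assert logs[0] == logs[1]
    assert len(logs[0]) >= 1


def test_occlusions_are_monotone_and_match_event_log():
    cfg = tiny_run_config()
    state = tiny_state(cfg)
    rng = np.random.default_rng(3)
    seed_initial_occlusion(state, rng)
    seen = 1
    for _ in range(30):
        step(state, cfg.occlusion, rng)
        n = len(state.events)
        assert n >= seen
        seen = n
        occluded = {s.id for s in state.network.segments if s.occluded}
        assert occluded == state.occluded_ids
    weeks = [w for w, _ in state.events]
    assert weeks == sorted(weeks)
    from retcap.occlusion import events_to_dataframe

    log = events_to_dataframe(state)
    assert list(log.columns) == ["week", "segment", "velocity", "vegf"]
    assert np.isfinite(log["velocity"]).all() and np.isfinite(log["vegf"]).all()
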