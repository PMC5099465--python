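"""Run configuration: geometry, physics, occlusion, pattern and experiment blocks.

All lengths are in micrometres (µm), pressures in mmHg, oxygen tensions in
mmHg, times in seconds for transport rates and in weeks for the occlusion
event clock.  Velocities are µm/s.  VEGF concentrations are arbitrary units;
the occlusion probability only ever sees VEGF normalised to the basal
steady-state level, so the absolute scale of the synthesis rates is
irrelevant (see :mod:`retcap.vegf`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError


@dataclass
class GeometryConfig:
    """Geometry of the schematic peripheral-retina vascular ladder.

    The modelled patch is ``n_sectors`` arteriole/venule (A/V) sectors side
    by side.  Vertical boundary vessels alternate arteriole, venule,
    arteriole, ... at ``av_distance`` spacing; a shunt vessel joins their
    tops; horizontal capillary rungs span each sector.  The two middle
    sectors are the treated region where burns are placed and where the
    initial occlusion is seeded.
    """

    av_distance: float = 300.0          # µm, arteriole-venule centreline distance
    sector_length: float = 770.0        # µm, vertical extent of a sector
    n_sectors: int = 4
    treated_sectors: tuple[int, ...] = (1, 2)
    spacing: float = 5.0                # µm, lattice site edge
    n_rungs: int = 10                   # capillary rungs per sector
    arteriole_diameter: float = 20.0    # µm
    venule_diameter: float = 25.0
    shunt_diameter: float = 18.0
    capillary_diameter: float = 10.0
    mueller_size: float = 24.0          # µm, nominal Mueller cell edge
    other_size: float = 21.0            # µm, nominal other-retinal-cell edge
    capillary_tortuosity: float = 3.0   # hydraulic length / straight length
    inlet_pressure: float = 40.0        # mmHg at arteriole heads
    outlet_pressure: float = 20.0       # mmHg at venule tails

    @property
    def width(self) -> float:
        return self.n_sectors * self.av_distance

    @property
    def region_area(self) -> float:
        """Area of the treated sectors, centreline to centreline (µm²)."""
        return len(self.treated_sectors) * self.av_distance * self.sector_length

    def validate(self) -> list[str]:
        v = []
        for name in ("av_distance", "sector_length", "spacing", "arteriole_diameter",
                     "venule_diameter", "shunt_diameter", "capillary_diameter",
                     "mueller_size", "other_size"):
            if getattr(self, name) <= 0:
                v.append(f"geometry.{name} must be positive")
        if self.n_sectors < 1:
            v.append("geometry.n_sectors must be >= 1")
        if self.n_rungs < 1:
            v.append("geometry.n_rungs must be >= 1")
        if self.capillary_tortuosity < 1.0:
            v.append("geometry.capillary_tortuosity must be >= 1")
        if any(s < 0 or s >= self.n_sectors for s in self.treated_sectors):
            v.append("geometry.treated_sectors outside sector range")
        if self.spacing > min(self.mueller_size, self.other_size):
            v.append("geometry.spacing larger than the smallest cell size")
        if self.spacing > 0:
            for name in ("av_distance", "sector_length"):
                val = getattr(self, name)
                if abs(val / self.spacing - round(val / self.spacing)) > 1e-9:
                    v.append(f"geometry.{name} must be a multiple of the lattice spacing")
        if self.inlet_pressure <= self.outlet_pressure:
            v.append("geometry.inlet_pressure must exceed outlet_pressure")
        return v


@dataclass
class OxygenConfig:
    """Oxygen transport constants.

    ``consumption`` is the zeroth-order tissue consumption expressed as a
    tension drain (mmHg/s); below ``cutoff_po2`` it ramps linearly to zero so
    tensions never go negative.  ``wall_exchange`` lumps wall permeability
    and solubility per unit wall area: the intravascular tension relaxes
    towards the perivascular tissue tension with decay exponent
    ``wall_exchange * (pi * diameter) * length / flow`` along a segment.
    """

    diffusivity: float = 1500.0         # µm²/s
    consumption: float = 31.0           # mmHg/s at full rate
    cutoff_po2: float = 2.0             # mmHg, linear-ramp consumption cutoff
    inlet_po2: float = 50.0             # mmHg at arteriole heads
    choroid_po2: float = 50.0           # mmHg clamp under photocoagulated sites
    wall_exchange: float = 64.0         # µm/s per unit wall area
    hypoxia_threshold: float = 15.0     # mmHg
    tol: float = 1e-6                   # mmHg, fixed-point convergence
    max_iter: int = 200

    def validate(self) -> list[str]:
        v = []
        for name in ("diffusivity", "cutoff_po2", "inlet_po2", "choroid_po2",
                     "hypoxia_threshold", "tol"):
            if getattr(self, name) <= 0:
                v.append(f"oxygen.{name} must be positive")
        if self.consumption < 0 or self.wall_exchange < 0:
            v.append("oxygen.consumption and oxygen.wall_exchange must be non-negative")
        if self.max_iter < 1:
            v.append("oxygen.max_iter must be >= 1")
        return v


@dataclass
class VegfConfig:
    """VEGF synthesis/diffusion/decay constants.

    Synthesis is gated on the hypoxia threshold: Mueller cells below it
    synthesise at ``hypoxic_rate``, normoxic ones at ``basal_rate`` (the
    diabetic, permissively elevated baseline).  Decay folds consumption by
    all cell types including endothelium into one first-order constant; the
    screening length sqrt(diffusivity/decay) sets how far an occlusion's
    VEGF plume reaches.
    """

    diffusivity: float = 100.0          # µm²/s
    decay: float = 0.05                 # 1/s  (screening length ~45 µm)
    basal_rate: float = 1.0             # a.u./s per Mueller site
    hypoxic_rate: float = 45.0          # a.u./s per hypoxic Mueller site
    vessel_sink: float = 0.6            # extra sink on large-vessel wall sites

    @property
    def screening_length(self) -> float:
        return (self.diffusivity / self.decay) ** 0.5

    def validate(self) -> list[str]:
        v = []
        for name in ("diffusivity", "decay", "basal_rate"):
            if getattr(self, name) <= 0:
                v.append(f"vegf.{name} must be positive")
        if self.hypoxic_rate <= self.basal_rate:
            v.append("vegf.hypoxic_rate must exceed basal_rate")
        if self.vessel_sink < 0:
            v.append("vegf.vessel_sink must be non-negative")
        return v


@dataclass
class OcclusionModel:
    """Stochastic occlusion probability model.

    Per examination interval, an open capillary occludes with probability

        p = p_max * V^n / (V^n + vegf_half^n) * exp(-v / v_scale)

    where ``V`` is the basal-normalised perivascular VEGF level and ``v``
    the segment's mean blood speed.  Monotone increasing in VEGF, monotone
    decreasing in velocity; clamped to [0, 1].
    """

    examination_interval: float = 1.0   # weeks
    p_max: float = 1.0
    vegf_half: float = 2.2              # basal-normalised VEGF at half-maximum
    vegf_hill: float = 8.0
    v_scale: float = 4000.0             # µm/s
    include_large_vessels: bool = False
    recompute_per_event: bool = False

    def validate(self) -> list[str]:
        v = []
        if not (0.0 <= self.p_max <= 1.0):
            v.append("occlusion.p_max must lie in [0, 1]")
        for name in ("examination_interval", "vegf_half", "vegf_hill", "v_scale"):
            if getattr(self, name) <= 0:
                v.append(f"occlusion.{name} must be positive")
        return v


@dataclass
class PatternConfig:
    """Burn pattern request: kind none|dot|band|prp with N/S/L/W in µm."""

    kind: str = "none"
    N: int = 4
    S: float = 100.0                    # dot edge
    L: float = 300.0                    # band length
    W: float = 100.0                    # band width
    burn_occludes_vessels: bool = False

    def validate(self) -> list[str]:
        v = []
        if self.kind not in ("none", "dot", "band", "prp"):
            v.append(f"pattern.kind {self.kind!r} not one of none|dot|band|prp")
        if self.kind in ("dot", "band") and self.N < 1:
            v.append("pattern.N must be >= 1")
        if self.kind == "dot" and self.S <= 0:
            v.append("pattern.S must be positive")
        if self.kind == "band":
            if self.W <= 0:
                v.append("pattern.W must be positive")
            if self.L <= 0:
                v.append("pattern.L must be positive")
            if self.N % 2 != 0:
                v.append("pattern.N must be even for band patterns "
                         "(bands are split between the two treated sectors)")
        return v


@dataclass
class ExperimentConfig:
    n_replicates: int = 24
    base_seed: int = 0
    duration_weeks: float = 156.0       # three model years
    snapshot_weeks: tuple[float, ...] = (0.0, 56.0, 144.0)
    output_dir: str = "results"

    def validate(self) -> list[str]:
        v = []
        if self.n_replicates < 1:
            v.append("experiment.n_replicates must be >= 1")
        if self.duration_weeks < 0:
            v.append("experiment.duration_weeks must be >= 0")
        return v


@dataclass
class RunConfig:
    """Top-level configuration; serialisable to/from YAML or JSON."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    oxygen: OxygenConfig = field(default_factory=OxygenConfig)
    vegf: VegfConfig = field(default_factory=VegfConfig)
    occlusion: OcclusionModel = field(default_factory=OcclusionModel)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    viscosity: float = 2.0e-3           # Pa·s, constant effective blood viscosity

    def validate(self) -> list[str]:
        v = []
        for block in ("geometry", "oxygen", "vegf", "occlusion", "pattern", "experiment"):
            v.extend(getattr(self, block).validate())
        if self.viscosity <= 0:
            v.append("viscosity must be positive")
        return v

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["geometry"]["treated_sectors"] = list(self.geometry.treated_sectors)
        d["experiment"]["snapshot_weeks"] = list(self.experiment.snapshot_weeks)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


_BLOCKS = {
    "geometry": GeometryConfig,
    "oxygen": OxygenConfig,
    "vegf": VegfConfig,
    "occlusion": OcclusionModel,
    "pattern": PatternConfig,
    "experiment": ExperimentConfig,
}


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    kwargs: dict[str, Any] = {}
    data = dict(data or {})
    for name, cls in _BLOCKS.items():
        block = dict(data.pop(name, {}) or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - known
        if unknown:
            raise ConfigurationError(f"unknown key(s) in {name!r} block: {sorted(unknown)}")
        for tup in ("treated_sectors", "snapshot_weeks"):
            if tup in block and isinstance(block[tup], list):
                block[tup] = tuple(block[tup])
        kwargs[name] = cls(**block)
    if "viscosity" in data:
        kwargs["viscosity"] = float(data.pop("viscosity"))
    if data:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(data)}")
    return RunConfig(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) file; defaults if path is None."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return the list of invariant violations (empty list = valid)."""
    return cfg.validate()


def require_valid(cfg: RunConfig) -> None:
    violations = validate_config(cfg)
    if violations:
        raise ConfigurationError("; ".join(violations))
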