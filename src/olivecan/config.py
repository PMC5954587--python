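"""Simulation configuration: named parameter blocks, YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .carbon import GrowthParams, SoilCarbonParams
from .management import IrrigationEvent, ManagementPlan, TillageEvent
from .phenology import PhenologyParams
from .spac import LeafParams, SoilRetention

__all__ = ["SoilConfig", "CanopyConfig", "PlantHydraulicConfig", "SimulationConfig",
           "load_config", "dump_config", "default_config"]


@dataclass(frozen=True)
class SoilConfig:
    """Soil profile shared by both zones (contents evolve separately)."""

    layer_dz: tuple[float, ...] = (0.3, 0.5, 0.6, 0.6)  # m
    theta_ul: float = 0.23  # field capacity, m3 m-3
    theta_ll: float = 0.07  # wilting point
    theta_sat: float = 0.40
    theta_init: float = 0.18
    cn: float = 75.0
    shc: str = "good"
    swcon: float = 0.4  # d-1
    u_stage1: float = 9.0  # mm
    alpha_stage2: float = 3.5  # mm d^-1/2
    microadvection: float = 1.3  # wetted-zone enhancement
    airdry_fraction: float = 0.5  # air-dry limit as fraction of theta_ll
    retention: SoilRetention = field(default_factory=SoilRetention)

    @property
    def n_layers(self) -> int:
        return len(self.layer_dz)


@dataclass(frozen=True)
class CanopyConfig:
    r_zx: float = 1.15  # vertical/horizontal crown radius ratio
    lad_init: float = 1.5  # m2 m-3, also used when inverting initial GC
    base_height: float = 0.8  # m
    max_height: float = 5.0  # m
    g_function: float = 0.5  # extinction G (spherical leaf angles)
    scatter: float = 0.10
    c_int: float = 0.4  # canopy rain storage per unit LAI, mm


@dataclass(frozen=True)
class PlantHydraulicConfig:
    sapwood_area: float = 6.0e-4  # m2 sapwood per m2 ground
    vessel_conductivity: float = 5.5e4  # mmol m-1 s-1 MPa-1
    root_permeability: float = 0.55  # mmol m-2 root s-1 MPa-1
    root_radius: float = 0.3e-3  # m
    allow_efflux: bool = True
    gs_unstressed: float = 0.25  # mol m-2 s-1, for the maximum-ET rule


@dataclass(frozen=True)
class SimulationConfig:
    n_substeps: int = 24
    latitude: float = 37.8
    start_year: int = 2001
    years: int = 3
    spacing_row: float = 7.0  # m
    spacing_in: float = 3.5  # m
    tree_age: int = 10
    ca: float = 400.0  # umol mol-1
    initial_gc: float = 0.30
    initial_lv: tuple[float, ...] = (0.6, 0.4, 0.2, 0.1)  # cm cm-3 per layer
    prior_y_dry: float = 300.0  # g DM m-2, year before the simulation
    seed: int = 0
    soil: SoilConfig = field(default_factory=SoilConfig)
    canopy: CanopyConfig = field(default_factory=CanopyConfig)
    hydraulics: PlantHydraulicConfig = field(default_factory=PlantHydraulicConfig)
    leaf: LeafParams = field(default_factory=LeafParams)
    phenology: PhenologyParams = field(default_factory=PhenologyParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    soil_carbon: SoilCarbonParams = field(default_factory=SoilCarbonParams)
    management: ManagementPlan = field(default_factory=ManagementPlan)

    def __post_init__(self):
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")
        if self.soil.n_layers < 2:
            raise ValueError("need at least 2 soil layers")
        if len(self.initial_lv) != self.soil.n_layers:
            raise ValueError("initial_lv length must match the soil layers")


def default_config(**overrides) -> SimulationConfig:
    return dataclasses.replace(SimulationConfig(), **overrides)


_BLOCKS = {
    "soil": SoilConfig,
    "canopy": CanopyConfig,
    "hydraulics": PlantHydraulicConfig,
    "leaf": LeafParams,
    "phenology": PhenologyParams,
    "growth": GrowthParams,
    "soil_carbon": SoilCarbonParams,
    "management": ManagementPlan,
}


def _build(cls, data):
    if not isinstance(data, dict):
        return data
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "retention" and isinstance(v, dict):
            v = SoilRetention(**v)
        elif f.name == "irrigation_events" and v:
            v = tuple(IrrigationEvent(**e) for e in v)
        elif f.name == "tillage_events" and v:
            v = tuple(TillageEvent(**e) for e in v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file; omitted keys keep
    their documented defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCKS:
            kwargs[key] = _build(_BLOCKS[key], value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return SimulationConfig(**kwargs)


def dump_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
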