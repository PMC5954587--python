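"""Management operations: irrigation scheduling, harvest, pruning, tillage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date

import numpy as np

from .carbon import TreeCarbonState, GrowthParams

__all__ = [
    "IrrigationEvent",
    "TillageEvent",
    "ManagementPlan",
    "schedule_irrigation",
    "apply_harvest",
    "apply_pruning",
    "apply_tillage",
]


@dataclass(frozen=True)
class IrrigationEvent:
    doy: int
    depth: float  # mm, orchard-area basis
    year: int | None = None  # None = every year

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("negative irrigation depth")


@dataclass(frozen=True)
class TillageEvent:
    doy: int
    cn_delta: float = 0.0  # offset applied to the zone CN
    cn_set: float | None = None  # absolute CN (wins over delta)
    year: int | None = None


@dataclass(frozen=True)
class ManagementPlan:
    """Schedules and parameters of the four management operations.

    Irrigation runs either from an explicit event list or from the auto
    rule: every ``irrigation_interval`` days apply ``irrigation_fraction``
    of the maximum (unstressed) ET lost since the last irrigation, net of
    effective rain.
    """

    irrigation_mode: str = "auto"  # "auto" | "events" | "none"
    irrigation_interval: int = 7  # d
    irrigation_fraction: float = 1.0
    irrigation_season: tuple[int, int] = (91, 304)  # DOY window (Apr-Oct)
    irrigation_events: tuple[IrrigationEvent, ...] = ()
    wetted_fraction: float = 0.15
    harvest_doy: int = 349
    pruning_interval: int = 2  # years
    pruning_doy: int = 60
    f_prune: float = 0.20
    residue_fate: str = "incorporate"  # "incorporate" | "export"
    tillage_events: tuple[TillageEvent, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.f_prune <= 1.0):
            raise ValueError("F_prune must be in [0, 1]")
        if not (0.0 <= self.wetted_fraction < 1.0):
            raise ValueError("wetted fraction must be in [0, 1)")
        if self.irrigation_mode not in ("auto", "events", "none"):
            raise ValueError(f"unknown irrigation mode {self.irrigation_mode}")
        if self.residue_fate not in ("incorporate", "export"):
            raise ValueError(f"unknown residue fate {self.residue_fate}")


def schedule_irrigation(
    plan: ManagementPlan,
    date: _date,
    et_deficit: float,
    days_since_last: int,
) -> float:
    """Today's irrigation depth (mm, orchard basis).

    ``et_deficit`` accumulates maximum ET minus effective rain since the
    last application (clamped at zero by the caller when rain exceeds ET).
    """
    doy = date.timetuple().tm_yday
    if plan.irrigation_mode == "none":
        return 0.0
    if plan.irrigation_mode == "events":
        depth = 0.0
        for ev in plan.irrigation_events:
            if ev.doy == doy and (ev.year is None or ev.year == date.year):
                depth += ev.depth
        return depth
    lo, hi = plan.irrigation_season
    if not (lo <= doy <= hi):
        return 0.0
    if days_since_last < plan.irrigation_interval:
        return 0.0
    return plan.irrigation_fraction * max(et_deficit, 0.0)


def apply_harvest(
    state: TreeCarbonState, p: GrowthParams
) -> tuple[float, float, TreeCarbonState]:
    """Remove fruits; Y_oil = oil ratio x fruit dry biomass.

    Returns (Y_dry, Y_oil, updated state); the FN record for next season's
    recurrence is kept by the caller before clearing.
    """
    y_dry = state.fruits
    y_oil = p.oil_ratio * y_dry
    return y_dry, y_oil, replace(state, fruits=0.0)


def apply_pruning(
    state: TreeCarbonState, f_prune: float, residue_fate: str, c_dm: float = 0.45
) -> tuple[TreeCarbonState, float]:
    """Remove a fraction of leaves, shoots (all cohorts) and branches.

    Returns the updated state and the residue carbon flux (g C m-2) routed
    to the soil fresh pool under ``incorporate`` (0 under ``export``; the
    exported mass leaves the system and is logged by the caller).
    """
    if not (0.0 <= f_prune <= 1.0):
        raise ValueError("F_prune must be in [0, 1]")
    removed_dm = f_prune * (state.leaves + state.shoots + state.branches)
    new = replace(
        state,
        leaves=(1.0 - f_prune) * state.leaves,
        shoot_cohorts=(1.0 - f_prune) * state.shoot_cohorts,
        branches=(1.0 - f_prune) * state.branches,
    )
    residue_c = c_dm * removed_dm if residue_fate == "incorporate" else 0.0
    return new, residue_c


def apply_tillage(cn: float, event: TillageEvent) -> float:
    """New curve number after a tillage event, clamped to (0, 100]."""
    new = event.cn_set if event.cn_set is not None else cn + event.cn_delta
    return min(max(new, 1.0), 100.0)
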