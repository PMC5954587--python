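"""Daily carbon economy: assimilate pool, respiration, allocation and yield.

The day's gross assimilation (plus fruit photosynthesis and, when growth
demand exceeds supply, a capped draw from reserves) feeds maintenance
respiration first; the remainder is allocated with fruits as the priority
sink, fixed partitioning coefficients for the vegetative organs, and a
production value (PV) per organ accounting for growth respiration.  Fruit
number follows a recurrence on the previous season's fruit and node counts,
which is what makes alternate bearing emerge.  Leaf/fine-root turnover,
frost defoliation, shoot-cohort aging and a two-pool soil carbon model close
the ecosystem budget (RESP_eco, NEE).

Substrate and reserves are in g CH2O m-2; biomass in g DM m-2 ground.
Carbon audits use 12/30 g C per g CH2O and ``c_dm`` (default 0.45) per g DM;
growth respiration in carbon units is the residual between substrate carbon
and the carbon fixed in new biomass, which makes the whole-system carbon
balance close by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TreeCarbonState",
    "GrowthParams",
    "SoilCarbonParams",
    "SoilCarbonState",
    "CarbonFluxes",
    "C_CH2O",
    "maintenance_respiration",
    "daily_assimilate_pool",
    "determine_fruit_number",
    "allocate_growth",
    "senescence_turnover",
    "shoots_to_branches",
    "frost_defoliation",
    "distribute_fine_root_growth",
    "soil_carbon_step",
    "ecosystem_fluxes",
]

C_CH2O = 12.0 / 30.0  # g C per g CH2O

VEG_ORGANS = ("leaves", "shoots", "branches", "coarse_roots", "fine_roots")


@dataclass
class TreeCarbonState:
    """Biomass of the six organ types plus reserves and fruit bookkeeping."""

    leaves: float = 0.0  # g DM m-2 ground
    shoot_cohorts: np.ndarray = field(default_factory=lambda: np.zeros(3))
    branches: float = 0.0  # incl. trunk
    coarse_roots: float = 0.0
    fine_roots: np.ndarray = field(default_factory=lambda: np.zeros((2, 4)))
    fruits: float = 0.0
    reserves: float = 0.0  # g CH2O m-2
    fruit_number: float = 0.0  # fruits m-2
    nodes_this_season: float = 0.0  # nodes m-2

    @property
    def shoots(self) -> float:
        return float(self.shoot_cohorts.sum())

    @property
    def fine_roots_total(self) -> float:
        return float(self.fine_roots.sum())

    def organ_biomass(self) -> dict[str, float]:
        return {
            "leaves": self.leaves,
            "shoots": self.shoots,
            "branches": self.branches,
            "coarse_roots": self.coarse_roots,
            "fine_roots": self.fine_roots_total,
            "fruits": self.fruits,
        }

    def biomass_total(self) -> float:
        return sum(self.organ_biomass().values())

    def check(self) -> None:
        vals = list(self.organ_biomass().values()) + [self.reserves]
        if any(v < -1e-9 for v in vals):
            raise ValueError(f"negative biomass/reserves: {self.organ_biomass()}")


@dataclass(frozen=True)
class GrowthParams:
    """Allocation, respiration and morphology parameters."""

    # vegetative partitioning coefficients (applied to the post-fruit pool)
    part_leaves: float = 0.20
    part_shoots: float = 0.15
    part_branches: float = 0.25
    part_coarse_roots: float = 0.15
    part_fine_roots: float = 0.25
    # production values, g DM per g CH2O substrate
    pv_leaves: float = 0.68
    pv_shoots: float = 0.69
    pv_branches: float = 0.70
    pv_coarse_roots: float = 0.70
    pv_fine_roots: float = 0.69
    pv_fruits: float = 0.55  # oil-rich organ, more expensive
    # maintenance coefficients at 20 degC, g CH2O g-1 DM d-1
    km_leaves: float = 0.0060
    km_shoots: float = 0.0020
    km_branches: float = 0.0004
    km_coarse_roots: float = 0.0004
    km_fine_roots: float = 0.0080
    km_fruits: float = 0.0030
    q10: float = 2.0
    t_ref: float = 20.0
    # turnover (d-1)
    leaf_turnover: float = 1.0 / 900.0  # ~2.5-year leaf lifespan
    fine_root_turnover: float = 0.003
    # morphology
    sla: float = 0.005  # m2 g-1 DM
    srl: float = 15.0  # m g-1 DM
    c_dm: float = 0.45  # g C per g DM
    # fruiting
    oil_ratio: float = 0.42  # g oil per g fruit DM
    fruit_pot_rate: float = 4.0e-4  # g DM fruit-1 degCd-1
    mean_fruit_mass: float = 0.6  # g DM, for seeding FN from prior yield
    fn_per_node: float = 1.5  # recurrence gain on previous-year nodes
    fn_feedback: float = 0.7  # recurrence loss on previous-year FN
    nodes_per_g_shoot: float = 3.0
    fruit_photo_coef: float = 0.001  # g CH2O g-1 fruit DM d-1 while growing
    f_remob: float = 0.05  # daily cap on reserve remobilization
    # stress thresholds
    frost_t_onset: float = -7.0  # degC, defoliation starts
    frost_t_full: float = -14.0  # complete defoliation
    heat_t_threshold: float = 37.0  # degC during flowering
    heat_fn_reduction: float = 0.10  # FN loss per hot flowering day
    heat_window: int = 10  # days after flowering

    def partitioning(self) -> dict[str, float]:
        coefs = {
            "leaves": self.part_leaves,
            "shoots": self.part_shoots,
            "branches": self.part_branches,
            "coarse_roots": self.part_coarse_roots,
            "fine_roots": self.part_fine_roots,
        }
        if any(v < 0 for v in coefs.values()) or sum(coefs.values()) > 1.0 + 1e-9:
            raise ValueError("partitioning coefficients must be >= 0 and sum <= 1")
        return coefs

    def pv(self, organ: str) -> float:
        return getattr(self, f"pv_{organ}")

    def km(self, organ: str) -> float:
        return getattr(self, f"km_{organ}")


# ---------------------------------------------------------------------------
# Respiration and the assimilate pool


def maintenance_respiration(state: TreeCarbonState, steps, p: GrowthParams) -> float:
    """Daily maintenance respiration (g CH2O m-2 d-1), Q10 on sub-daily T."""
    organs = state.organ_biomass()
    base = sum(p.km(o) * b for o, b in organs.items())
    if base == 0.0:
        return 0.0
    tfac = sum(p.q10 ** ((s.temp - p.t_ref) / 10.0) * s.dt for s in steps)
    return base * tfac


def daily_assimilate_pool(
    a_daily: float,
    fruit_biomass: float,
    reserves: float,
    resp_m: float,
    p: GrowthParams,
    fruit_active: bool = False,
    demand: float | None = None,
) -> tuple[float, float, float, bool]:
    """Build the day's substrate pool (g CH2O m-2).

    pool = assimilation + fruit photosynthesis + remobilization - RESP_M.
    A maintenance deficit is drawn from reserves (floored at zero, flagged
    as starvation); remobilization is capped at ``f_remob`` of reserves and
    only occurs when growth ``demand`` exceeds the supply.

    Returns (pool, updated reserves, fruit_photosynthesis, starvation).
    """
    if reserves < 0:
        raise ValueError("negative reserves")
    fruit_photo = p.fruit_photo_coef * fruit_biomass if fruit_active else 0.0
    pool = a_daily + fruit_photo - resp_m
    starvation = False
    if pool < 0.0:
        deficit = -pool
        draw = min(deficit, reserves)
        reserves -= draw
        pool = draw - deficit  # <= 0
        if pool < 0.0:
            starvation = True
            pool = 0.0
    if demand is not None and demand > pool:
        remob = min(p.f_remob * reserves, demand - pool)
        reserves -= remob
        pool += remob
    return pool, reserves, fruit_photo, starvation


# ---------------------------------------------------------------------------
# Fruit number and allocation


def determine_fruit_number(
    fn_prev: float, nodes_prev: float, hot_flowering_days: int, p: GrowthParams
) -> float:
    """Alternate-bearing recurrence with heat-stress reduction.

    FN = max(0, a * nodes_prev - b * FN_prev), then reduced by a fraction
    per flowering-window day whose Tmax exceeded the heat threshold.
    """
    fn = max(0.0, p.fn_per_node * nodes_prev - p.fn_feedback * fn_prev)
    fn *= max(1.0 - p.heat_fn_reduction, 0.0) ** int(hot_flowering_days)
    return fn


def allocate_growth(
    pool: float,
    fn: float,
    dtt: float,
    growth_active: bool,
    fruit_active: bool,
    p: GrowthParams,
) -> tuple[dict[str, float], float, float, float]:
    """Allocate the day's substrate pool.

    Fruits are the priority sink: their demand (FN x potential rate x
    today's degCd, converted to substrate through PV) is served first,
    min(sink demand, pool) — sink- vs source-limited.  The remainder is
    split by the fixed vegetative coefficients while growth is active;
    out-of-season substrate accrues to reserves.

    Returns (organ DM increments, RESP_g in g C, surplus to reserves in g
    CH2O, substrate spent).  Conservation: spent + surplus = pool exactly.
    """
    if pool < 0:
        raise ValueError("negative pool")
    coefs = p.partitioning()
    growth = {o: 0.0 for o in VEG_ORGANS}
    growth["fruits"] = 0.0
    spent = 0.0
    resp_g_c = 0.0

    remaining = pool
    if fruit_active and fn > 0 and dtt > 0:
        demand_dm = fn * p.fruit_pot_rate * dtt
        demand_substrate = demand_dm / p.pv_fruits
        s = min(demand_substrate, remaining)
        growth["fruits"] = s * p.pv_fruits
        resp_g_c += s * (C_CH2O - p.c_dm * p.pv_fruits)
        spent += s
        remaining -= s

    if growth_active and remaining > 0.0:
        for organ, c in coefs.items():
            s = c * remaining
            growth[organ] = s * p.pv(organ)
            resp_g_c += s * (C_CH2O - p.c_dm * p.pv(organ))
            spent += s
        remaining *= 1.0 - sum(coefs.values())
    surplus = remaining
    return growth, resp_g_c, surplus, spent


def distribute_fine_root_growth(
    increment: float,
    zone_fractions,
    layer_dz,
    theta,
    theta_ul,
    theta_ll,
) -> np.ndarray:
    """Split fine-root growth over (zone, layer) compartments.

    Weight = compartment volume x plant-available water factor (clamped to
    [0, 1]); all-dry profiles fall back to volume weighting.  The returned
    increments sum to ``increment`` exactly.
    """
    if increment < 0:
        raise ValueError("negative increment")
    fr = np.asarray(zone_fractions, dtype=float)[:, None]
    dz = np.asarray(layer_dz, dtype=float)[None, :]
    vol = fr * dz
    avail = np.clip(
        (np.asarray(theta) - np.asarray(theta_ll))
        / (np.asarray(theta_ul) - np.asarray(theta_ll)),
        0.0,
        1.0,
    )
    w = vol * avail
    if w.sum() <= 0.0:
        w = vol
    return increment * w / w.sum()


# ---------------------------------------------------------------------------
# Turnover, cohorts, stress


def senescence_turnover(
    state: TreeCarbonState, p: GrowthParams
) -> tuple[TreeCarbonState, float, float]:
    """First-order leaf and fine-root turnover; litter equals the loss."""
    leaf_litter = p.leaf_turnover * state.leaves
    root_litter_arr = p.fine_root_turnover * state.fine_roots
    new = replace(
        state,
        leaves=state.leaves - leaf_litter,
        fine_roots=state.fine_roots - root_litter_arr,
    )
    return new, leaf_litter, float(root_litter_arr.sum())


def shoots_to_branches(state: TreeCarbonState) -> TreeCarbonState:
    """Year-boundary cohort aging; the 3-year cohort converts to branches."""
    cohorts = state.shoot_cohorts
    promoted = float(cohorts[-1])
    new_cohorts = np.concatenate([[0.0], cohorts[:-1]])
    return replace(
        state, shoot_cohorts=new_cohorts, branches=state.branches + promoted
    )


def frost_defoliation(
    tmin: float, state: TreeCarbonState, p: GrowthParams
) -> tuple[TreeCarbonState, float]:
    """Defoliate a fraction of leaves, linear between the two thresholds."""
    if tmin >= p.frost_t_onset:
        return state, 0.0
    frac = min((p.frost_t_onset - tmin) / (p.frost_t_onset - p.frost_t_full), 1.0)
    litter = frac * state.leaves
    return replace(state, leaves=state.leaves - litter), litter


# ---------------------------------------------------------------------------
# Soil carbon


@dataclass(frozen=True)
class SoilCarbonParams:
    k_fresh: float = 0.02  # d-1 at reference conditions
    k_humus: float = 8.0e-5
    humification: float = 0.2  # fraction of fresh decay entering humus
    q10: float = 2.0
    t_ref: float = 20.0


@dataclass
class SoilCarbonState:
    fresh: float = 100.0  # g C m-2
    humus: float = 4000.0


def soil_moisture_modifier(theta_rel: float) -> float:
    """Decomposition moisture factor: optimal near field capacity,
    reduced toward dryness and saturation.

    ``theta_rel`` is plant-available water content relative to the
    field-capacity/wilting-point span; values above 1 indicate wetter than
    field capacity (approaching saturation around 1.5).
    """
    if theta_rel <= 0.0:
        return 0.1
    if theta_rel <= 1.0:
        return 0.1 + 0.9 * theta_rel
    return max(1.0 - 0.6 * (theta_rel - 1.0), 0.4)


def soil_carbon_step(
    pools: SoilCarbonState,
    litter_c: float,
    residue_c: float,
    soil_temp: float,
    theta_rel: float,
    p: SoilCarbonParams,
) -> tuple[float, SoilCarbonState]:
    """One day of two-pool decomposition.  Carbon conserved to 1e-9.

    Fresh-pool decay partly humifies; the rest, plus humus decay, is
    heterotrophic respiration.
    """
    if pools.fresh < 0 or pools.humus < 0:
        raise ValueError("negative soil carbon pool")
    mod = p.q10 ** ((soil_temp - p.t_ref) / 10.0) * soil_moisture_modifier(theta_rel)
    fresh = pools.fresh + litter_c + residue_c
    decay_f = min(p.k_fresh * mod, 1.0) * fresh
    decay_h = min(p.k_humus * mod, 1.0) * pools.humus
    humified = p.humification * decay_f
    resp_h = (decay_f - humified) + decay_h
    new = SoilCarbonState(
        fresh=fresh - decay_f, humus=pools.humus + humified - decay_h
    )
    balance = (litter_c + residue_c) - (
        (new.fresh - pools.fresh) + (new.humus - pools.humus) + resp_h
    )
    if abs(balance) > 1e-9:
        raise RuntimeError(f"soil carbon balance violated by {balance:.2e} g C")
    return resp_h, new


# ---------------------------------------------------------------------------
# Ecosystem fluxes


@dataclass(frozen=True)
class CarbonFluxes:
    """Daily orchard carbon fluxes, g C m-2 d-1 (NEE positive = source)."""

    assimilation: float
    fruit_photo: float
    resp_m: float
    resp_g: float
    resp_h: float

    @property
    def resp_eco(self) -> float:
        return self.resp_m + self.resp_g + self.resp_h

    @property
    def nee(self) -> float:
        return self.resp_eco - (self.assimilation + self.fruit_photo)


def ecosystem_fluxes(
    assimilation_c: float,
    fruit_photo_c: float,
    resp_m_c: float,
    resp_g_c: float,
    resp_h_c: float,
) -> CarbonFluxes:
    return CarbonFluxes(assimilation_c, fruit_photo_c, resp_m_c, resp_g_c, resp_h_c)
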