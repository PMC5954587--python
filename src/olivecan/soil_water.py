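"""Daily water balance of the two soil zones (dry and drip-wetted).

Each zone is a stack of layers holding volumetric water content between an
air-dry floor and saturation.  The daily sequence is: canopy interception
(orchard level), partition of effective rain over the zones, curve-number
runoff, tipping-bucket drainage with a diffusive redistribution pass,
two-stage soil evaporation, and root water uptake (computed by the SPAC
module and applied here).  Irrigation enters the wetted zone only, as
surface infiltration below the canopy.  All depths are mm on the zone's own
area basis unless stated otherwise; there is no lateral flow between zones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .weather import DailyWeather, saturation_vapor_pressure, solar_geometry

__all__ = [
    "SoilLayerState",
    "SoilZoneState",
    "CanopyWaterStore",
    "ZoneWaterFluxes",
    "intercept_rainfall",
    "evaporate_intercepted",
    "partition_effective_precip",
    "curve_number_runoff",
    "adjust_cn_for_moisture",
    "drain_and_redistribute",
    "soil_evaporation",
    "zone_water_step",
    "penman_monteith",
    "aerodynamic_resistance",
    "penman_fao_potential",
]

LATENT_HEAT = 2.45  # MJ kg-1
PSYCHROMETRIC = 0.0665  # kPa K-1
AIR_DENSITY_CP = 1.013e-3 * 1.225  # rho*cp, MJ m-3 K-1 (approx, sea level)
VON_KARMAN = 0.41


class WaterBalanceError(RuntimeError):
    """Internal mass-balance violation (reported with the flux breakdown)."""


@dataclass
class SoilLayerState:
    """One soil layer: thickness, water content limits and root length density."""

    dz: float  # m
    theta: float  # m3 m-3
    theta_ul: float  # field capacity ("drained upper limit")
    theta_ll: float  # wilting point ("lower limit")
    theta_sat: float
    lv: float = 0.0  # root length density, cm cm-3

    def __post_init__(self):
        if not (self.theta_ll < self.theta_ul < self.theta_sat):
            raise ValueError(
                f"need theta_ll < theta_ul < theta_sat, got "
                f"{self.theta_ll}, {self.theta_ul}, {self.theta_sat}"
            )
        if self.dz <= 0 or self.lv < 0 or not (0 <= self.theta <= self.theta_sat):
            raise ValueError("invalid layer state")

    @property
    def water_mm(self) -> float:
        return self.theta * self.dz * 1000.0


@dataclass
class SoilZoneState:
    """One of the two surface compartments (dry or wetted)."""

    fraction: float  # of orchard surface, 0-1
    layers: list[SoilLayerState]
    cn: float  # SCS curve number (average moisture condition)
    shc: str = "good"  # soil hydrological condition
    cum_stage1: float = 0.0  # evaporation since last full wetting, mm
    t_stage2: int = 0  # days since stage-2 onset

    def __post_init__(self):
        if not (0.0 < self.cn <= 100.0):
            raise ValueError(f"CN must be in (0, 100], got {self.cn}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("zone fraction must be in [0, 1]")

    @property
    def water_mm(self) -> float:
        return sum(l.water_mm for l in self.layers)


@dataclass
class CanopyWaterStore:
    """Rain water held on the foliage, evaporating before any transpiration."""

    stored: float = 0.0  # mm
    capacity: float = 0.0  # mm

    def __post_init__(self):
        if not (0.0 <= self.stored <= self.capacity + 1e-12):
            raise ValueError("stored water outside [0, capacity]")


@dataclass(frozen=True)
class ZoneWaterFluxes:
    """Daily fluxes on the zone's own area basis (mm d-1)."""

    p_eff: float
    runoff: float
    infiltration: float
    drainage: float
    es: float
    rwu: float
    irrigation: float
    delta_storage: float

    def check_closure(self, tol: float = 1e-6) -> None:
        resid = (
            self.infiltration
            + self.irrigation
            - self.drainage
            - self.es
            - self.rwu
            - self.delta_storage
        )
        if abs(resid) > tol:
            raise WaterBalanceError(
                f"zone water closure violated by {resid:.3e} mm: {self}"
            )


# ---------------------------------------------------------------------------
# Canopy interception


def intercept_rainfall(
    p: float, store: CanopyWaterStore, lai: float, c_int: float = 0.4
) -> tuple[float, CanopyWaterStore]:
    """Withhold rain on the canopy up to ``c_int * LAI`` mm of storage."""
    if p < 0:
        raise ValueError("negative precipitation")
    capacity = c_int * lai
    stored = min(store.stored, capacity)
    p_int = min(p, max(capacity - stored, 0.0))
    return p - p_int, CanopyWaterStore(stored=stored + p_int, capacity=capacity)


def aerodynamic_resistance(wind: float, canopy_height: float, z_ref: float = 10.0) -> float:
    """Log-profile aerodynamic resistance (s m-1) above a tall sparse canopy."""
    u = max(wind, 0.5)
    h = max(canopy_height, 0.5)
    d = 0.65 * h
    z0m = 0.1 * h
    z0h = 0.1 * z0m
    z = max(z_ref, h + 2.0)
    return (
        math.log((z - d) / z0m)
        * math.log((z - d) / z0h)
        / (VON_KARMAN**2 * u)
    )


def penman_monteith(
    rn_mj: float,
    temp: float,
    vpd: float,
    ra: float,
    rc: float = 0.0,
    dt_days: float = 1.0,
) -> float:
    """Penman-Monteith evaporation (mm over ``dt_days``) for net radiation
    ``rn_mj`` (MJ m-2 over the same interval) and resistances in s m-1."""
    delta = (
        4098.0
        * saturation_vapor_pressure(temp)
        / (temp + 237.3) ** 2
    )  # kPa K-1
    seconds = dt_days * 86400.0
    num = delta * rn_mj + seconds * AIR_DENSITY_CP * vpd / ra
    den = delta + PSYCHROMETRIC * (1.0 + rc / ra)
    return max(num / den / LATENT_HEAT, 0.0)


def evaporate_intercepted(
    store: CanopyWaterStore,
    rn_mj: float,
    temp: float,
    vpd: float,
    wind: float,
    canopy_height: float,
    dt_days: float = 1.0,
) -> tuple[float, CanopyWaterStore, bool]:
    """Evaporate stored canopy water at the null-resistance Penman-Monteith rate.

    Returns (Ecan, updated store, transpiration-blocked flag).  The flag is
    raised while any water remains on the foliage.
    """
    if store.stored <= 0.0:
        return 0.0, store, False
    ra = aerodynamic_resistance(wind, canopy_height)
    potential = penman_monteith(rn_mj, temp, vpd, ra, rc=0.0, dt_days=dt_days)
    ecan = min(potential, store.stored)
    new = CanopyWaterStore(stored=store.stored - ecan, capacity=store.capacity)
    return ecan, new, new.stored > 1e-12


def penman_fao_potential(day: DailyWeather, latitude_deg: float) -> float:
    """Daily FAO-style potential evaporation (mm) from daily weather.

    Net radiation is approximated as (1 - albedo) * srad minus a clear-sky
    scaled longwave loss; used as the stage-one soil evaporation potential
    and the wet-canopy demand ceiling.
    """
    doy = day.date.timetuple().tm_yday
    ra_ext = solar_geometry(latitude_deg, doy).ra
    rso = 0.75 * ra_ext
    tmaxk, tmink = day.tmax + 273.16, day.tmin + 273.16
    rel = min(day.srad / rso, 1.0) if rso > 0 else 1.0
    rnl = (
        4.903e-9
        * 0.5
        * (tmaxk**4 + tmink**4)
        * (0.34 - 0.14 * math.sqrt(max(day.ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    rn = max((1.0 - 0.23) * day.srad - max(rnl, 0.0), 0.0)
    t = day.tmean
    vpd = max(saturation_vapor_pressure(t) - day.ea, 0.0)
    ra = 208.0 / max(day.wind, 0.5)  # FAO grass aerodynamic resistance
    return penman_monteith(rn, t, vpd, ra, rc=70.0, dt_days=1.0)


# ---------------------------------------------------------------------------
# Partition, runoff, drainage


def partition_effective_precip(p_eff: float, fractions: list[float]) -> list[float]:
    """Every zone receives the same depth on its own area (volume conserved)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"zone fractions must sum to 1, got {fractions}")
    return [p_eff for _ in fractions]


def curve_number_runoff(depth: float, cn: float) -> float:
    """SCS curve-number storm runoff (mm) for a water input ``depth`` (mm)."""
    if not (0.0 < cn <= 100.0):
        raise ValueError(f"CN must be in (0, 100], got {cn}")
    if depth < 0:
        raise ValueError("negative depth")
    s = 25400.0 / cn - 254.0
    ia = 0.2 * s
    if depth <= ia:
        return 0.0
    return (depth - ia) ** 2 / (depth + 0.8 * s)


def adjust_cn_for_moisture(cn2: float, paw_topsoil: float) -> float:
    """Antecedent-moisture CN adjustment from topsoil plant-available water.

    Three linear classes: dry (AMC I) below 0.3, average between, wet
    (AMC III) above 0.7, using the standard CN1/CN3 conversions.
    """
    cn1 = cn2 / (2.281 - 0.01281 * cn2)
    cn3 = cn2 / (0.427 + 0.00573 * cn2)
    if paw_topsoil <= 0.3:
        return cn1
    if paw_topsoil >= 0.7:
        return cn3
    if paw_topsoil < 0.5:
        f = (paw_topsoil - 0.3) / 0.2
        return cn1 + f * (cn2 - cn1)
    f = (paw_topsoil - 0.5) / 0.2
    return cn2 + f * (cn3 - cn2)


def drain_and_redistribute(
    layers: list[SoilLayerState],
    infiltration: float,
    irrigation: float = 0.0,
    swcon: float = 0.4,
    redist_rate: float = 0.10,
) -> tuple[list[SoilLayerState], float]:
    """Tipping-bucket drainage cascade plus a diffusive redistribution pass.

    Water above field capacity drains downward at ``swcon`` per day, capped
    so no layer exceeds saturation; bottom drainage leaves the profile.  A
    second pass relaxes water-content differences between adjacent layers
    below field capacity.  Mass is conserved to 1e-9 mm.
    """
    if infiltration < 0 or irrigation < 0:
        raise ValueError("negative water input")
    out = [replace(l) for l in layers]
    before = sum(l.water_mm for l in out) + infiltration + irrigation

    flux = infiltration + irrigation  # mm arriving at the top of the profile
    for i, layer in enumerate(out):
        cap_mm = layer.theta_sat * layer.dz * 1000.0
        w = layer.water_mm + flux
        held = min(w, cap_mm)
        flux = w - held
        theta = held / (layer.dz * 1000.0)
        ul_mm = layer.theta_ul * layer.dz * 1000.0
        if held > ul_mm:
            drain = swcon * (held - ul_mm)
            held -= drain
            flux += drain
        layer.theta = held / (layer.dz * 1000.0)
    drainage = flux

    # Diffusive redistribution between adjacent layers below field capacity.
    for i in range(len(out) - 1):
        a, b = out[i], out[i + 1]
        rel_a = (a.theta - a.theta_ll) / (a.theta_ul - a.theta_ll)
        rel_b = (b.theta - b.theta_ll) / (b.theta_ul - b.theta_ll)
        if a.theta > a.theta_ul or b.theta > b.theta_ul:
            continue
        grad = rel_a - rel_b
        if abs(grad) < 1e-12:
            continue
        dz_min = min(a.dz, b.dz)
        move = redist_rate * grad * dz_min * 1000.0 * 0.5 * (
            (a.theta_ul - a.theta_ll) + (b.theta_ul - b.theta_ll)
        )
        # cap so the gradient cannot invert
        cap_a = max((a.theta - a.theta_ll) * a.dz * 1000.0, 0.0)
        cap_b = max((b.theta - b.theta_ll) * b.dz * 1000.0, 0.0)
        if move > 0:
            move = min(move, cap_a, max(0.0, (b.theta_ul - b.theta) * b.dz * 1000.0))
        else:
            move = -min(-move, cap_b, max(0.0, (a.theta_ul - a.theta) * a.dz * 1000.0))
        a.theta -= move / (a.dz * 1000.0)
        b.theta += move / (b.dz * 1000.0)

    after = sum(l.water_mm for l in out) + drainage
    if abs(after - before) > 1e-9:
        raise WaterBalanceError(
            f"drainage mass balance violated by {after - before:.3e} mm"
        )
    for l in out:
        if not (-1e-12 <= l.theta <= l.theta_sat + 1e-12):
            raise WaterBalanceError(f"layer theta out of range: {l.theta}")
        l.theta = min(max(l.theta, 0.0), l.theta_sat)
    return out, drainage


# ---------------------------------------------------------------------------
# Soil evaporation


def soil_evaporation(
    zone: SoilZoneState,
    es_potential: float,
    soil_rad_fraction: float,
    microadvection: float = 1.0,
    u_stage1: float = 9.0,
    alpha_stage2: float = 3.5,
    airdry_fraction: float = 0.5,
    wetting: float = 0.0,
) -> tuple[float, SoilZoneState]:
    """Two-stage soil evaporation for one zone (mm d-1, zone area basis).

    Stage 1 (energy limited): potential x transmitted-radiation fraction x
    microadvection (>=1 for the small wetted patch).  After ``u_stage1`` mm
    have evaporated since the last full rewetting, stage 2 follows the
    square-root-of-time law ``alpha * (sqrt(t) - sqrt(t-1))``.  Wetting
    events offset the stage-1 total and, when large enough, reset to stage 1.
    Extraction empties the top layer down to the air-dry limit, spilling
    into the second layer.
    """
    cum = max(zone.cum_stage1 - wetting, 0.0)
    t2 = zone.t_stage2 if cum >= u_stage1 else 0

    demand = max(es_potential, 0.0) * max(soil_rad_fraction, 0.0) * max(microadvection, 1.0)
    if cum < u_stage1:
        es = demand
    else:
        t2 += 1
        es = min(demand, alpha_stage2 * (math.sqrt(t2) - math.sqrt(t2 - 1)))

    # supply limit: top two layers down to air-dry
    out = [replace(l) for l in zone.layers]
    remaining = es
    extracted = 0.0
    for layer in out[:2]:
        airdry = airdry_fraction * layer.theta_ll
        avail = max((layer.theta - airdry) * layer.dz * 1000.0, 0.0)
        take = min(avail, remaining)
        layer.theta -= take / (layer.dz * 1000.0)
        extracted += take
        remaining -= take
        if remaining <= 0:
            break
    es = extracted
    new_zone = replace(
        zone, layers=out, cum_stage1=cum + es, t_stage2=t2
    )
    return es, new_zone


# ---------------------------------------------------------------------------
# Orchestration


def zone_water_step(
    zone: SoilZoneState,
    p_eff_depth: float,
    irrigation: float,
    es_potential: float,
    soil_rad_fraction: float,
    rwu_mm_per_layer: np.ndarray | list[float] | None = None,
    microadvection: float = 1.0,
    swcon: float = 0.4,
    u_stage1: float = 9.0,
    alpha_stage2: float = 3.5,
    cn_override: float | None = None,
) -> tuple[ZoneWaterFluxes, SoilZoneState]:
    """One daily water-balance step for a single zone.

    ``p_eff_depth`` is the effective rain depth assigned to this zone,
    ``irrigation`` the depth applied (wetted zone only; bypasses runoff),
    ``rwu_mm_per_layer`` the root water uptake per layer on the zone's area
    basis.  Returns the flux summary (closure checked to 1e-6 mm) and the
    updated zone.
    """
    before = zone.water_mm

    paw = _topsoil_paw(zone)
    cn = cn_override if cn_override is not None else adjust_cn_for_moisture(zone.cn, paw)
    runoff = curve_number_runoff(p_eff_depth, cn)
    infiltration = p_eff_depth - runoff

    layers, drainage = drain_and_redistribute(
        zone.layers, infiltration, irrigation, swcon=swcon
    )
    zone2 = replace(zone, layers=layers)

    es, zone3 = soil_evaporation(
        zone2,
        es_potential,
        soil_rad_fraction,
        microadvection=microadvection,
        u_stage1=u_stage1,
        alpha_stage2=alpha_stage2,
        wetting=infiltration + irrigation,
    )

    rwu_total = 0.0
    if rwu_mm_per_layer is not None:
        layers = [replace(l) for l in zone3.layers]
        for layer, r in zip(layers, rwu_mm_per_layer):
            layer.theta -= r / (layer.dz * 1000.0)
            rwu_total += r
            if layer.theta < -1e-9:
                raise WaterBalanceError(
                    f"root uptake {r} mm exceeds layer storage"
                )
            layer.theta = max(layer.theta, 0.0)
        zone3 = replace(zone3, layers=layers)

    fluxes = ZoneWaterFluxes(
        p_eff=p_eff_depth,
        runoff=runoff,
        infiltration=infiltration,
        drainage=drainage,
        es=es,
        rwu=rwu_total,
        irrigation=irrigation,
        delta_storage=zone3.water_mm - before,
    )
    fluxes.check_closure()
    return fluxes, zone3


def _topsoil_paw(zone: SoilZoneState) -> float:
    top = zone.layers[: min(2, len(zone.layers))]
    num = sum((l.theta - l.theta_ll) * l.dz for l in top)
    den = sum((l.theta_ul - l.theta_ll) * l.dz for l in top)
    return min(max(num / den, 0.0), 1.0) if den > 0 else 0.5
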