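"""Orchard state initialization, the daily loop, and output tables.

The daily order of operations is fixed: weather disaggregation -> phenology
(chilling sub-daily) -> management events -> canopy interception and wet-
canopy evaporation -> per-zone runoff / infiltration / drainage -> diurnal
SPAC loop (root uptake, transpiration, assimilation; transpiration is
suppressed while the canopy holds intercepted water) -> soil evaporation ->
carbon economy -> geometry and root-length updates -> soil carbon -> closure
audits.  Water and carbon are audited daily and annually; violations raise
with the flux breakdown rather than being absorbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as _date

import numpy as np
import pandas as pd

from . import canopy_radiation as cr
from . import carbon as cb
from . import management as mg
from . import phenology as ph
from . import soil_water as sw
from . import spac
from .config import SimulationConfig
from .weather import DailyWeather, disaggregate_day

__all__ = ["OrchardState", "initialize_state", "step_day", "run"]


class SimulationError(RuntimeError):
    pass


@dataclass
class OrchardState:
    """Everything that persists from one day to the next."""

    config: SimulationConfig
    carbon: cb.TreeCarbonState
    zones: list[sw.SoilZoneState]  # [dry] or [dry, wetted]
    canopy_store: sw.CanopyWaterStore
    geometry: cr.CrownGeometry
    pheno: ph.PhenoState
    soil_carbon: cb.SoilCarbonState
    # season bookkeeping
    fn_prev: float = 0.0
    nodes_prev: float = 0.0
    heat_days: int = 0
    fn_set: bool = False
    # irrigation rule
    et_deficit: float = 0.0
    days_since_irrigation: int = 999
    # running audit (orchard-basis mm / g C m-2 since simulation start)
    water_in: float = 0.0
    water_out: float = 0.0
    water_store0: float = 0.0
    carbon_in: float = 0.0
    carbon_out: float = 0.0
    carbon_store0: float = 0.0

    @property
    def zone_fractions(self) -> list[float]:
        return [z.fraction for z in self.zones]

    def water_storage(self) -> float:
        """Total stored water, orchard-basis mm (profile + canopy)."""
        return (
            sum(z.fraction * z.water_mm for z in self.zones)
            + self.canopy_store.stored
        )

    def carbon_storage(self) -> float:
        """System carbon, g C m-2 (biomass + reserves + soil pools)."""
        g = self.config.growth
        return (
            g.c_dm * self.carbon.biomass_total()
            + cb.C_CH2O * self.carbon.reserves
            + self.soil_carbon.fresh
            + self.soil_carbon.humus
        )


def _build_zone(cfg: SimulationConfig, fraction: float, lv: np.ndarray) -> sw.SoilZoneState:
    s = cfg.soil
    layers = [
        sw.SoilLayerState(
            dz=dz,
            theta=s.theta_init,
            theta_ul=s.theta_ul,
            theta_ll=s.theta_ll,
            theta_sat=s.theta_sat,
            lv=float(lv[i]),
        )
        for i, dz in enumerate(s.layer_dz)
    ]
    return sw.SoilZoneState(fraction=fraction, layers=layers, cn=s.cn, shc=s.shc)


def initialize_state(
    config: SimulationConfig, prerun_tmean: list[float]
) -> OrchardState:
    """Build the initial orchard state.

    Crown radii are inverted from the initial ground cover, leaf biomass
    from crown volume x LAD / SLA, the woody organs from allometric ratios
    to leaf biomass, fine roots from the initial root length densities, and
    the first-season fruit number from the prior year's dry yield.  The
    phenology state is pre-run on the preceding ~3 months of daily mean
    temperatures (chilling accumulation).
    """
    if len(prerun_tmean) < 90:
        raise SimulationError(
            f"need >= 90 days of pre-run temperatures, got {len(prerun_tmean)}"
        )
    cell = config.spacing_row * config.spacing_in
    a_h_max = 0.5 * min(config.spacing_row, config.spacing_in)
    a_h = math.sqrt(config.initial_gc * cell / math.pi)
    if a_h > a_h_max + 1e-9:
        raise SimulationError(
            f"initial GC {config.initial_gc} incompatible with spacing "
            f"{config.spacing_row} x {config.spacing_in}"
        )
    can = config.canopy
    g = config.growth
    a_v = can.r_zx * a_h
    volume = 4.0 / 3.0 * math.pi * a_h**2 * a_v
    leaf_area = volume * can.lad_init  # m2 per tree
    lai = leaf_area / cell
    leaves = lai / g.sla  # g DM m-2

    shoots = 0.25 * leaves
    carbon_state = cb.TreeCarbonState(
        leaves=leaves,
        shoot_cohorts=np.array([shoots / 3.0] * 3),
        branches=3.0 * leaves,
        coarse_roots=1.5 * leaves,
        fruits=0.0,
        reserves=0.3 * leaves,  # modest starting reserve pool
    )

    f_wet = config.management.wetted_fraction
    lv = np.asarray(config.initial_lv, dtype=float)
    fractions = [1.0 - f_wet, f_wet] if f_wet > 0 else [1.0]
    zones = [_build_zone(config, f, lv) for f in fractions]

    # fine roots from Lv: mass = length / SRL, per zone-layer on orchard basis
    n_l = config.soil.n_layers
    fine = np.zeros((len(zones), n_l))
    for zi, zone in enumerate(zones):
        for li, layer in enumerate(zone.layers):
            length = lv[li] * 1.0e4 * layer.dz * zone.fraction  # m per m2 orchard
            fine[zi, li] = length / g.srl
    carbon_state.fine_roots = fine

    fn_prev = config.prior_y_dry / g.mean_fruit_mass
    nodes_prev = fn_prev * (1.0 + g.fn_feedback) / g.fn_per_node  # steady state

    pheno = ph.PhenoState()
    for t in prerun_tmean:
        pheno.chill_units += ph.chilling_effectiveness(t, config.phenology)
    if pheno.chill_units >= config.phenology.chill_requirement:
        pheno.dormant = False

    geometry = cr.update_crown_geometry(
        leaves, g.sla, can.lad_init, can.r_zx,
        config.spacing_row, config.spacing_in,
        base_height=can.base_height, max_height=can.max_height,
    )

    state = OrchardState(
        config=config,
        carbon=carbon_state,
        zones=zones,
        canopy_store=sw.CanopyWaterStore(0.0, can.c_int * lai),
        geometry=geometry,
        pheno=pheno,
        soil_carbon=cb.SoilCarbonState(),
        fn_prev=fn_prev,
        nodes_prev=nodes_prev,
    )
    state.water_store0 = state.water_storage()
    state.carbon_store0 = state.carbon_storage()
    return state


# ---------------------------------------------------------------------------
# Daily step


def _hydraulic_paths(cfg: SimulationConfig, zones, temp: float):
    """Branch list of the uptake network from the current soil state."""
    ret = cfg.soil.retention
    hyd = cfg.hydraulics
    paths = []
    for zi, zone in enumerate(zones):
        for li, layer in enumerate(zone.layers):
            if layer.lv <= 0 or layer.theta <= 0:
                continue
            psi = spac.soil_water_potential(layer.theta, layer.theta_sat, ret)
            r_s = spac.layer_soil_resistance(
                layer.theta, layer.theta_sat, layer.lv, layer.dz, ret,
                root_radius=hyd.root_radius,
            )
            r_r = spac.layer_root_resistance(
                layer.lv,
                layer.dz,
                root_permeability=hyd.root_permeability,
                theta_factor=spac.root_theta_factor(
                    layer.theta, layer.theta_ul, layer.theta_ll
                ),
                temperature_factor=spac.root_temperature_factor(temp),
                root_radius=hyd.root_radius,
            )
            # branch resistances act on the zone's area; scale to orchard basis
            r_total = (r_s + r_r) / max(zone.fraction, 1e-9)
            depth = sum(l.dz for l in zone.layers[: li + 1]) - 0.5 * layer.dz
            paths.append(
                spac.HydraulicPathElement(
                    zone=zi,
                    layer=li,
                    psi_s=psi - spac.GRAVITY_HEAD * depth,
                    r_total=r_total,
                    area_fraction=zone.fraction,
                )
            )
    return paths


def _unstressed_et(state: OrchardState, day: DailyWeather) -> float:
    """Maximum-ET proxy for the auto-irrigation rule (mm d-1).

    The model's own Penman potential scaled by a ground-cover-dependent
    orchard coefficient (sparse canopies transpire well below the reference
    rate); kept deliberately cheap so the rule does not require a second
    unstressed simulation."""
    cfg = state.config
    kc = min(1.0, 0.30 + 1.2 * state.geometry.gc)
    return kc * sw.penman_fao_potential(day, cfg.latitude)


def step_day(state: OrchardState, day: DailyWeather) -> tuple[OrchardState, dict]:
    """Advance the orchard one day; returns the updated state and the
    daily output record.  Mutates nothing in ``state`` (a new state is
    returned) except through its dataclass replacement semantics."""
    cfg = state.config
    doy = day.date.timetuple().tm_yday
    steps = disaggregate_day(day, cfg.n_substeps, cfg.latitude)
    ca = day.ca if day.ca is not None else cfg.ca
    g = cfg.growth
    store_before = state.water_storage()
    carbon_before = state.carbon_storage()

    # --- phenology -------------------------------------------------------
    pheno = state.pheno
    if doy == 305:  # autumn: new dormancy cycle
        pheno.reset_for_autumn()
    pheno = ph.accumulate_chilling(pheno, steps, cfg.phenology)
    was_flowering = pheno.flowering_doy
    pheno = ph.advance_phenology(pheno, doy, day.tmean, cfg.phenology)

    heat_days = state.heat_days
    fn_set = state.fn_set
    fn = state.carbon.fruit_number
    if pheno.flowering_doy is not None and not fn_set:
        if doy < pheno.flowering_doy + g.heat_window and day.tmax > g.heat_t_threshold:
            heat_days += 1
    if pheno.fruit_growth_active and not fn_set:
        fn = cb.determine_fruit_number(state.fn_prev, state.nodes_prev, heat_days, g)
        fn_set = True

    # --- management ------------------------------------------------------
    zones = [replace(z, layers=[replace(l) for l in z.layers]) for z in state.zones]
    for ev in cfg.management.tillage_events:
        if ev.doy == doy and (ev.year is None or ev.year == day.date.year):
            for z in zones:
                z.cn = mg.apply_tillage(z.cn, ev)

    irr = mg.schedule_irrigation(
        cfg.management, day.date, state.et_deficit, state.days_since_irrigation
    )

    # --- interception and wet-canopy evaporation -------------------------
    p_eff, store = sw.intercept_rainfall(
        day.rain, state.canopy_store, state.geometry.lai, cfg.canopy.c_int
    )
    stored_initial = store.stored
    rn_mj = 0.77 * day.srad
    ra = sw.aerodynamic_resistance(day.wind, state.geometry.height)
    vpd_day = max(sw.saturation_vapor_pressure(day.tmean) - day.ea, 0.0)
    potential_ecan = sw.penman_monteith(rn_mj, day.tmean, vpd_day, ra, rc=0.0)
    ecan = min(potential_ecan, stored_initial)
    store = sw.CanopyWaterStore(
        stored=stored_initial - ecan, capacity=store.capacity
    )
    # steps blocked by a wet canopy: leading fraction of the day
    wet_flags = [False] * len(steps)
    if stored_initial > 1e-9:
        frac_wet = (
            1.0 if potential_ecan <= 0 else min(stored_initial / potential_ecan, 1.0)
        )
        k = min(len(steps), int(math.ceil(frac_wet * len(steps))))
        for i in range(k):
            wet_flags[i] = True

    # --- per-zone runoff / infiltration / drainage -----------------------
    depths = sw.partition_effective_precip(p_eff, [z.fraction for z in zones])
    zone_pre = []
    for zi, zone in enumerate(zones):
        depth = depths[zi]
        irr_depth = 0.0
        if irr > 0.0 and len(zones) > 1 and zi == 1:
            irr_depth = irr / zone.fraction  # orchard mm -> zone-area mm
        paw = sw._topsoil_paw(zone)
        cn = sw.adjust_cn_for_moisture(zone.cn, paw)
        runoff = sw.curve_number_runoff(depth, cn)
        infiltration = depth - runoff
        layers, drainage = sw.drain_and_redistribute(
            zone.layers, infiltration, irr_depth, swcon=cfg.soil.swcon
        )
        zones[zi] = replace(zone, layers=layers)
        zone_pre.append((depth, runoff, infiltration, irr_depth, drainage))

    # --- diurnal SPAC loop ----------------------------------------------
    lai = state.geometry.lai
    ep = 0.0
    a_mol = 0.0
    ipar_mj = 0.0
    psi_leaf_min = 0.0
    psi_collar_min = 0.0
    rwu_paths = None
    paths = _hydraulic_paths(cfg, zones, day.tmean) if lai > 0 else []
    if paths and lai > 0:
        parts = [
            cr.intercept_radiation(
                state.geometry, s.elevation, s.par_beam, s.par_diffuse,
                g=cfg.canopy.g_function, scatter=cfg.canopy.scatter,
            )
            for s in steps
        ]
        r_x = spac.plant_xylem_resistance(
            state.geometry.height,
            state.geometry.a_h,
            cfg.hydraulics.sapwood_area,
            cfg.hydraulics.vessel_conductivity,
        )
        ep, a_mol, rwu_mm, psi_leaf_min, psi_collar_min = spac.diurnal_water_carbon(
            paths,
            r_x,
            steps,
            parts,
            ca,
            cfg.leaf,
            tree_height=state.geometry.height,
            canopy_wet=wet_flags,
            allow_efflux=cfg.hydraulics.allow_efflux,
        )
        rwu_paths = rwu_mm
        # intercepted PAR, MJ m-2 d-1 (umol m-2 s-1 -> MJ via 4.57 umol J-1)
        for s, p in zip(steps, parts):
            ipar_mj += p.ipar * s.dt * 86400.0 / 4.57 * 1e-6

    # apply uptake to the zones (zone-area basis), capped at a dry floor
    rwu_total = 0.0
    if rwu_paths is not None:
        for p, mm in zip(paths, rwu_paths):
            zone = zones[p.zone]
            layer = zone.layers[p.layer]
            depth_zone = mm / max(zone.fraction, 1e-9)
            floor = 0.25 * layer.theta_ll
            avail = max((layer.theta - floor) * layer.dz * 1000.0, 0.0)
            if depth_zone > 0:
                take = min(depth_zone, avail)
            else:  # efflux into the layer, capped at saturation
                room = max((layer.theta_sat - layer.theta) * layer.dz * 1000.0, 0.0)
                take = -min(-depth_zone, room)
            layer.theta -= take / (layer.dz * 1000.0)
            actual_mm = take * zone.fraction
            rwu_total += actual_mm
        ep = rwu_total  # Kirchhoff: transpiration equals total uptake

    # --- soil evaporation ------------------------------------------------
    es_pot = sw.penman_fao_potential(day, cfg.latitude)
    f_soil_rad = 1.0 - cr.diffuse_interception_fraction(
        state.geometry, cfg.canopy.g_function
    )
    es_orchard = 0.0
    zone_fluxes = []
    for zi, zone in enumerate(zones):
        micro = cfg.soil.microadvection if (len(zones) > 1 and zi == 1) else 1.0
        depth, runoff, infiltration, irr_depth, drainage = zone_pre[zi]
        es, zone2 = sw.soil_evaporation(
            zone,
            es_pot,
            f_soil_rad,
            microadvection=micro,
            u_stage1=cfg.soil.u_stage1,
            alpha_stage2=cfg.soil.alpha_stage2,
            airdry_fraction=cfg.soil.airdry_fraction,
            wetting=infiltration + irr_depth,
        )
        zones[zi] = zone2
        es_orchard += zone2.fraction * es
        zone_fluxes.append(
            dict(p_eff=depth, runoff=runoff, infiltration=infiltration,
                 irrigation=irr_depth, drainage=drainage, es=es)
        )

    # --- carbon economy --------------------------------------------------
    carbon_state = state.carbon
    a_ch2o = a_mol * 30.0  # mol CO2 -> g CH2O
    resp_m = cb.maintenance_respiration(carbon_state, steps, g)

    dtt = max(day.tmean - cfg.phenology.fruit_tt_base, 0.0)
    demand = 0.0
    if pheno.fruit_growth_active and fn > 0:
        demand = fn * g.fruit_pot_rate * dtt / g.pv_fruits
    reserves0 = carbon_state.reserves
    pool, reserves, fruit_photo, starving = cb.daily_assimilate_pool(
        a_ch2o, carbon_state.fruits, carbon_state.reserves, resp_m, g,
        fruit_active=pheno.fruit_growth_active, demand=demand if demand > 0 else None,
    )
    resp_m_paid = resp_m if not starving else a_ch2o + fruit_photo + reserves0

    growth, resp_g_c, surplus, spent = cb.allocate_growth(
        pool, fn, dtt, pheno.growth_active, pheno.fruit_growth_active, g
    )
    reserves += surplus

    carbon_state = replace(
        carbon_state,
        leaves=carbon_state.leaves + growth["leaves"],
        branches=carbon_state.branches + growth["branches"],
        coarse_roots=carbon_state.coarse_roots + growth["coarse_roots"],
        fruits=carbon_state.fruits + growth["fruits"],
        reserves=reserves,
        fruit_number=fn,
        nodes_this_season=carbon_state.nodes_this_season
        + g.nodes_per_g_shoot * growth["shoots"],
    )
    cohorts = carbon_state.shoot_cohorts.copy()
    cohorts[0] += growth["shoots"]
    carbon_state.shoot_cohorts = cohorts
    if growth["fine_roots"] > 0.0:
        theta = np.array([[l.theta for l in z.layers] for z in zones])
        theta_ul = np.array([[l.theta_ul for l in z.layers] for z in zones])
        theta_ll = np.array([[l.theta_ll for l in z.layers] for z in zones])
        inc = cb.distribute_fine_root_growth(
            growth["fine_roots"],
            [z.fraction for z in zones],
            cfg.soil.layer_dz,
            theta,
            theta_ul,
            theta_ll,
        )
        carbon_state.fine_roots = carbon_state.fine_roots + inc

    carbon_state, leaf_litter, root_litter = cb.senescence_turnover(carbon_state, g)
    carbon_state, frost_litter = cb.frost_defoliation(day.tmin, carbon_state, g)

    # --- management: harvest and pruning ---------------------------------
    y_dry = y_oil = 0.0
    residue_c = 0.0
    export_c = 0.0
    if doy == cfg.management.harvest_doy:
        fn_prev_next = carbon_state.fruit_number
        y_dry, y_oil, carbon_state = mg.apply_harvest(carbon_state, g)
        export_c += g.c_dm * y_dry
    else:
        fn_prev_next = None

    prune_year = (
        cfg.management.pruning_interval > 0
        and (day.date.year - cfg.start_year) % cfg.management.pruning_interval == 0
    )
    if prune_year and doy == cfg.management.pruning_doy:
        removed_before = carbon_state.leaves + carbon_state.shoots + carbon_state.branches
        carbon_state, residue_c = mg.apply_pruning(
            carbon_state, cfg.management.f_prune, cfg.management.residue_fate, g.c_dm
        )
        if cfg.management.residue_fate == "export":
            export_c += g.c_dm * cfg.management.f_prune * removed_before

    # --- geometry / root length updates ----------------------------------
    geometry = cr.update_crown_geometry(
        carbon_state.leaves, g.sla, cfg.canopy.lad_init, cfg.canopy.r_zx,
        cfg.spacing_row, cfg.spacing_in,
        base_height=cfg.canopy.base_height, max_height=cfg.canopy.max_height,
    )
    for zi, zone in enumerate(zones):
        for li, layer in enumerate(zone.layers):
            mass = carbon_state.fine_roots[zi, li]
            length = mass * g.srl  # m per m2 orchard
            vol = zone.fraction * layer.dz
            layer.lv = (length / vol) * 1.0e-4 if vol > 0 else 0.0

    # --- soil carbon ------------------------------------------------------
    litter_c = g.c_dm * (leaf_litter + root_litter + frost_litter)
    theta_rel_top = sw._topsoil_paw(zones[0])
    resp_h, soil_c = cb.soil_carbon_step(
        state.soil_carbon, litter_c, residue_c, day.tmean, theta_rel_top,
        cfg.soil_carbon,
    )

    # --- audits -----------------------------------------------------------
    new_store = sw.CanopyWaterStore(
        stored=min(store.stored, cfg.canopy.c_int * geometry.lai)
        if cfg.canopy.c_int * geometry.lai > 0 else 0.0,
        capacity=cfg.canopy.c_int * geometry.lai,
    )
    spilled = store.stored - new_store.stored  # capacity shrank (pruning etc.)

    runoff_orch = sum(z.fraction * f["runoff"] for z, f in zip(zones, zone_fluxes))
    drain_orch = sum(z.fraction * f["drainage"] for z, f in zip(zones, zone_fluxes))
    et = ep + es_orchard + ecan

    new_state = replace(
        state,
        carbon=carbon_state,
        zones=zones,
        canopy_store=new_store,
        geometry=geometry,
        pheno=pheno,
        soil_carbon=soil_c,
        heat_days=heat_days if not fn_set else 0,
        fn_set=fn_set,
        et_deficit=0.0 if irr > 0 else max(
            state.et_deficit + _unstressed_et(state, day) - p_eff, 0.0
        ),
        days_since_irrigation=1 if irr > 0 else state.days_since_irrigation + 1,
    )
    if fn_prev_next is not None:
        new_state.fn_prev = fn_prev_next
    new_state.water_in = state.water_in + day.rain + irr
    new_state.water_out = (
        state.water_out + runoff_orch + drain_orch + et + spilled
    )
    assim_c = cb.C_CH2O * a_ch2o
    fruit_photo_c = cb.C_CH2O * fruit_photo
    resp_m_c = cb.C_CH2O * resp_m_paid
    new_state.carbon_in = state.carbon_in + assim_c + fruit_photo_c
    new_state.carbon_out = (
        state.carbon_out + resp_m_c + resp_g_c + resp_h + export_c
    )

    # daily closure checks
    water_resid = (
        (new_state.water_in - new_state.water_out)
        - (new_state.water_storage() - new_state.water_store0)
    )
    prev_resid = (state.water_in - state.water_out) - (
        store_before - state.water_store0
    )
    if abs(water_resid - prev_resid) > 1e-6:
        raise SimulationError(
            f"{day.date}: daily water closure violated by "
            f"{water_resid - prev_resid:.3e} mm"
        )
    carbon_resid = (
        (new_state.carbon_in - new_state.carbon_out)
        - (new_state.carbon_storage() - new_state.carbon_store0)
    )
    prev_cresid = (state.carbon_in - state.carbon_out) - (
        carbon_before - state.carbon_store0
    )
    if abs(carbon_resid - prev_cresid) > 1e-6:
        raise SimulationError(
            f"{day.date}: daily carbon closure violated by "
            f"{carbon_resid - prev_cresid:.3e} g C"
        )

    fluxes = cb.ecosystem_fluxes(
        assim_c, fruit_photo_c, resp_m_c, resp_g_c, resp_h
    )
    record = {
        "date": day.date,
        "rain": day.rain,
        "irrigation": irr,
        "p_eff": p_eff,
        "runoff": runoff_orch,
        "drainage": drain_orch,
        "es": es_orchard,
        "ep": ep,
        "ecan": ecan,
        "et": et,
        "theta_dry": float(np.mean([l.theta for l in zones[0].layers])),
        "theta_wet": float(np.mean([l.theta for l in zones[-1].layers]))
        if len(zones) > 1 else float("nan"),
        "theta_min": min(l.theta for z in zones for l in z.layers),
        "theta_max": max(l.theta for z in zones for l in z.layers),
        "psi_leaf_min": psi_leaf_min,
        "psi_collar_min": psi_collar_min,
        "ipar_mj": ipar_mj,
        "assimilation": fluxes.assimilation,
        "resp_m": fluxes.resp_m,
        "resp_g": fluxes.resp_g,
        "resp_h": fluxes.resp_h,
        "resp_eco": fluxes.resp_eco,
        "nee": fluxes.nee,
        "lai": geometry.lai,
        "gc": geometry.gc,
        "leaves": carbon_state.leaves,
        "shoots": carbon_state.shoots,
        "branches": carbon_state.branches,
        "coarse_roots": carbon_state.coarse_roots,
        "fine_roots": carbon_state.fine_roots_total,
        "fruits": carbon_state.fruits,
        "reserves": carbon_state.reserves,
        "fruit_number": carbon_state.fruit_number,
        "dormant": pheno.dormant,
        "growth_active": pheno.growth_active,
        "fruit_growth_active": pheno.fruit_growth_active,
        "flowering_doy": pheno.flowering_doy,
        "y_dry": y_dry,
        "y_oil": y_oil,
        "water_closure": water_resid,
        "carbon_closure": carbon_resid,
    }
    return new_state, record


def _year_boundary(state: OrchardState) -> OrchardState:
    """January 1: shoot cohorts age, node counter archives and resets."""
    carbon_state = cb.shoots_to_branches(state.carbon)
    nodes = carbon_state.nodes_this_season
    carbon_state = replace(carbon_state, nodes_this_season=0.0)
    new = replace(state, carbon=carbon_state)
    new.nodes_prev = nodes
    new.fn_set = False
    new.heat_days = 0
    return new


def run(
    config: SimulationConfig, weather: list[DailyWeather]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full simulation; returns (daily table, annual summary).

    ``weather`` must cover the simulated years; records before January 1 of
    ``start_year`` (at least 90 days) serve as the phenology pre-run.
    """
    start = _date(config.start_year, 1, 1)
    prerun = [d for d in weather if d.date < start]
    series = [d for d in weather if d.date >= start]
    need = (_date(config.start_year + config.years, 1, 1) - start).days
    if len(series) < need:
        raise SimulationError(
            f"weather covers {len(series)} days from {start}, need {need}"
        )
    if len(prerun) < 90:
        raise SimulationError(
            "weather must include >= 90 days before the simulation start "
            "for the phenology pre-run"
        )
    state = initialize_state(config, [d.tmean for d in prerun])

    records = []
    for day in series[:need]:
        if day.date.month == 1 and day.date.day == 1 and day.date > start:
            state = _year_boundary(state)
        state, rec = step_day(state, day)
        records.append(rec)
    daily = pd.DataFrame(records)

    daily["year"] = pd.to_datetime(daily["date"]).dt.year
    annual_rows = []
    for year, grp in daily.groupby("year"):
        annual_rows.append(
            {
                "year": int(year),
                "rain": grp["rain"].sum(),
                "irrigation": grp["irrigation"].sum(),
                "et": grp["et"].sum(),
                "ep": grp["ep"].sum(),
                "es": grp["es"].sum(),
                "ecan": grp["ecan"].sum(),
                "runoff": grp["runoff"].sum(),
                "drainage": grp["drainage"].sum(),
                "ipar_mj": grp["ipar_mj"].sum(),
                "assimilation": grp["assimilation"].sum(),
                "nee": grp["nee"].sum(),
                "y_dry": grp["y_dry"].sum(),
                "y_oil": grp["y_oil"].sum(),
                "fruit_number": grp["fruit_number"].max(),
                "water_closure": grp["water_closure"].iloc[-1],
                "carbon_closure": grp["carbon_closure"].iloc[-1],
            }
        )
    annual = pd.DataFrame(annual_rows)
    # biennial means of oil yield (overlapping two-year windows)
    if len(annual) >= 2:
        annual["y_oil_biennial"] = (
            annual["y_oil"].rolling(2).mean().shift(-1).values
        )
    return daily, annual
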