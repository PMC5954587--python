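"""Soil-plant-atmosphere continuum: hydraulic network and leaf gas exchange.

Water moves from soil layers to the foliage down water-potential gradients
through three resistances in series per root branch (soil-to-root-interface
R_s, interface-to-xylem R_r) joined in parallel at the collar, then through
the xylem (R_x) to the leaves — the electrical-circuit analogy.  Transpiration
demand comes from sunlit/shaded leaf gas exchange: a C3 biochemical model
coupled to a stomatal model whose conductance declines with leaf water
potential, solved by damped fixed-point iteration per sub-daily step.

Units: water potentials MPa; resistances MPa s m2 mmol-1 (ground-area basis);
fluxes mmol H2O m-2 ground s-1; conductances mol m-2 leaf s-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoilRetention",
    "HydraulicPathElement",
    "LeafParams",
    "GasExchangeState",
    "GasExchangeConvergenceError",
    "NetworkSolution",
    "soil_water_potential",
    "unsaturated_conductivity",
    "layer_soil_resistance",
    "layer_root_resistance",
    "plant_xylem_resistance",
    "solve_soil_plant_network",
    "leaf_gas_exchange",
    "solve_canopy_step",
    "diurnal_water_carbon",
    "mm_per_day_to_mmol",
    "mmol_to_mm",
]

R_GAS = 8.314  # J mol-1 K-1
GRAVITY_HEAD = 0.01  # MPa per m of height
WATER_MOLAR_MASS = 18.015e-3  # kg mol-1
O2_MMOL = 210.0  # intercellular O2, mmol mol-1


class GasExchangeConvergenceError(RuntimeError):
    """The coupled (Ci, psi_l) iteration failed to converge."""


def mm_per_day_to_mmol(mm_d: float) -> float:
    """mm H2O d-1 -> mmol m-2 s-1."""
    return mm_d / 86400.0 / WATER_MOLAR_MASS * 1.0e3


def mmol_to_mm(mmol_m2_s: float, seconds: float) -> float:
    """Integrate a mmol m-2 s-1 flux over ``seconds`` into mm (kg m-2)."""
    return mmol_m2_s * seconds * WATER_MOLAR_MASS * 1.0e-3


# ---------------------------------------------------------------------------
# Soil hydraulics


@dataclass(frozen=True)
class SoilRetention:
    """Campbell retention/conductivity parameters for one texture."""

    psi_e: float = -0.003  # air-entry potential, MPa (sandy loam)
    b: float = 3.6  # Campbell exponent (psi ~ -1.5 MPa at theta_ll = 0.07)
    k_sat: float = 5.0e3  # saturated conductivity, mmol m-1 s-1 MPa-1

    def __post_init__(self):
        if self.psi_e >= 0 or self.b <= 0 or self.k_sat <= 0:
            raise ValueError("invalid retention parameters")


def soil_water_potential(theta: float, theta_sat: float, ret: SoilRetention) -> float:
    """Campbell water retention: psi = psi_e (theta/theta_sat)^-b (MPa)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return ret.psi_e * (theta / theta_sat) ** (-ret.b)


def unsaturated_conductivity(theta: float, theta_sat: float, ret: SoilRetention) -> float:
    """Campbell conductivity k = k_sat (theta/theta_sat)^(2b+3)."""
    return ret.k_sat * (theta / theta_sat) ** (2.0 * ret.b + 3.0)


def layer_soil_resistance(
    theta: float,
    theta_sat: float,
    lv: float,
    dz: float,
    ret: SoilRetention,
    root_radius: float = 0.3e-3,
) -> float:
    """Single-root (Gardner/Cowan) soil-to-root-interface resistance.

    ``lv`` in cm cm-3, ``dz`` in m.  Returns infinity when the layer holds
    no roots (the branch is excluded from the network).
    """
    if lv <= 0.0:
        return math.inf
    lv_m = lv * 1.0e4  # cm cm-3 -> m root m-3 soil
    d_half = 1.0 / math.sqrt(math.pi * lv_m)  # half distance between roots, m
    k = unsaturated_conductivity(theta, theta_sat, ret)
    return math.log(d_half / root_radius) / (4.0 * math.pi * k * lv_m * dz)


def root_theta_factor(theta: float, theta_ul: float, theta_ll: float) -> float:
    """Root permeability reduction in drying soil (1 above a threshold)."""
    rel = (theta - theta_ll) / (theta_ul - theta_ll)
    return min(max(rel / 0.5, 0.05), 1.0)


def root_temperature_factor(temp: float, t_ref: float = 20.0) -> float:
    """Viscosity-like Q10 reduction of root permeability below ``t_ref``."""
    if temp >= t_ref:
        return 1.0
    return max(1.25 ** ((temp - t_ref) / 10.0), 0.05)


def layer_root_resistance(
    lv: float,
    dz: float,
    root_permeability: float = 0.55,
    theta_factor: float = 1.0,
    temperature_factor: float = 1.0,
    root_radius: float = 0.3e-3,
) -> float:
    """Radial root resistance of one layer (MPa s m2 mmol-1, ground basis).

    ``root_permeability`` in mmol m-2 root surface s-1 MPa-1 (radial
    conductivity ~1e-8 m s-1 MPa-1); root surface area per ground area
    follows from Lv (cm cm-3) and layer thickness.
    """
    if lv <= 0.0:
        return math.inf
    lv_m = lv * 1.0e4
    area = 2.0 * math.pi * root_radius * lv_m * dz  # m2 root m-2 ground
    perm = root_permeability * min(theta_factor, 1.0) * min(temperature_factor, 1.0)
    return 1.0 / (perm * area)


def plant_xylem_resistance(
    tree_height: float,
    crown_radius: float,
    sapwood_area: float,
    vessel_conductivity: float = 5.5e4,
) -> float:
    """Xylem resistance from tree size and sapwood (MPa s m2 mmol-1).

    ``sapwood_area`` in m2 sapwood per m2 ground; ``vessel_conductivity`` is
    the Hagen-Poiseuille-type sapwood-specific conductivity in
    mmol m-1 s-1 MPa-1 per m2 sapwood; path length = height + mean crown
    radius.
    """
    if min(tree_height, sapwood_area, vessel_conductivity) <= 0:
        raise ValueError("tree height, sapwood area and conductivity must be > 0")
    path = tree_height + max(crown_radius, 0.0)
    conductance = vessel_conductivity * sapwood_area / path
    return 1.0 / conductance


@dataclass(frozen=True)
class HydraulicPathElement:
    """One soil-layer branch of the uptake network."""

    zone: int
    layer: int
    psi_s: float  # MPa, gravity-corrected driving potential
    r_total: float  # R_s + R_r, MPa s m2 mmol-1
    area_fraction: float = 1.0  # zone surface fraction (flux bookkeeping)


@dataclass(frozen=True)
class NetworkSolution:
    psi_collar: float
    psi_leaf: float
    rwu: np.ndarray  # per branch, mmol m-2 ground s-1
    supply_limited: bool


def solve_soil_plant_network(
    paths: list[HydraulicPathElement],
    r_x: float,
    e_p: float,
    allow_efflux: bool = True,
    psi_min: float | None = None,
) -> NetworkSolution:
    """Solve the parallel-branch uptake network for a transpiration demand.

    Kirchhoff balance at the collar: sum_i (psi_i - psi_collar)/R_i = E_p.
    With ``allow_efflux`` False, branches that would lose water are pruned
    iteratively.  ``psi_min`` flags (not enforces) a supply-limited state
    when the implied leaf potential would fall below it.
    """
    finite = [p for p in paths if math.isfinite(p.r_total)]
    if not finite or e_p < 0:
        raise ValueError("need at least one finite path and E_p >= 0")
    psi = np.array([p.psi_s for p in finite])
    r = np.array([p.r_total for p in finite])

    active = np.ones(len(finite), dtype=bool)
    for _ in range(len(finite) + 1):
        g = 1.0 / r[active]
        psi_collar = (np.sum(psi[active] * g) - e_p) / np.sum(g)
        if allow_efflux:
            break
        losing = active & (psi < psi_collar - 1e-12)
        if not losing.any():
            break
        active &= ~losing

    rwu = np.zeros(len(finite))
    rwu[active] = (psi[active] - psi_collar) / r[active]
    psi_leaf = psi_collar - e_p * r_x
    limited = psi_min is not None and psi_leaf < psi_min

    # map back onto the original path list (excluded branches -> 0)
    full = np.zeros(len(paths))
    j = 0
    for i, p in enumerate(paths):
        if math.isfinite(p.r_total):
            full[i] = rwu[j]
            j += 1
    return NetworkSolution(psi_collar, psi_leaf, full, limited)


# ---------------------------------------------------------------------------
# Leaf biochemistry and stomata


@dataclass(frozen=True)
class LeafParams:
    """C3 photosynthesis and stomatal parameters (25 degC reference)."""

    vcmax25: float = 70.0  # umol m-2 s-1
    jmax25: float = 126.0
    theta_j: float = 0.9  # curvature of the light response
    alpha_j: float = 0.3  # mol e- per mol photons absorbed
    ha_vcmax: float = 65330.0  # J mol-1, Arrhenius activation
    ha_jmax: float = 43540.0
    g0: float = 0.01  # minimum stomatal conductance, mol m-2 s-1 (H2O)
    g1: float = 6.0  # stomatal slope (Leuning form)
    d0: float = 1.5  # VPD sensitivity, kPa
    psi_onset: float = -1.0  # MPa, start of stomatal downregulation
    psi_closure: float = -5.0  # MPa, near-complete closure
    psi_min: float = -8.0  # MPa, hard supply limit on leaf water potential


def _arrhenius(k25: float, ha: float, t: float) -> float:
    tk = t + 273.15
    return k25 * math.exp(ha * (tk - 298.15) / (298.15 * R_GAS * tk))


def _photo_constants(t: float) -> tuple[float, float, float]:
    """Gamma*, Kc, Ko at leaf temperature t (Bernacchi temperature responses)."""
    gamma = _arrhenius(42.75, 37830.0, t)
    kc = _arrhenius(404.9, 79430.0, t)
    ko = _arrhenius(278.4, 36380.0, t)  # mmol mol-1
    return gamma, kc, ko


def psi_stomatal_factor(psi_l: float, psi_onset: float, psi_closure: float) -> float:
    """Logistic downregulation of stomatal conductance with leaf potential."""
    mid = 0.5 * (psi_onset + psi_closure)
    k = 8.0 / (psi_onset - psi_closure)
    x = min(max(-k * (psi_l - mid), -50.0), 50.0)
    return 1.0 / (1.0 + math.exp(x))


def gross_assimilation(ci: float, par_abs: float, t: float, p: LeafParams) -> float:
    """Gross CO2 fixation rate (umol m-2 s-1) at intercellular CO2 ``ci``.

    Minimum of the Rubisco-limited and electron-transport-limited rates; dark
    respiration is carried by the whole-plant maintenance budget instead of
    being subtracted here.
    """
    if par_abs <= 0.0:
        return 0.0
    gamma, kc, ko = _photo_constants(t)
    if ci <= gamma:
        return 0.0
    vcmax = _arrhenius(p.vcmax25, p.ha_vcmax, t)
    jmax = _arrhenius(p.jmax25, p.ha_jmax, t)
    wc = vcmax * (ci - gamma) / (ci + kc * (1.0 + O2_MMOL / ko))
    i2 = p.alpha_j * par_abs
    j = (
        i2 + jmax - math.sqrt((i2 + jmax) ** 2 - 4.0 * p.theta_j * i2 * jmax)
    ) / (2.0 * p.theta_j)
    wj = j * (ci - gamma) / (4.0 * ci + 8.0 * gamma)
    return max(min(wc, wj), 0.0)


@dataclass(frozen=True)
class GasExchangeState:
    """Converged per-leaf-class state."""

    a_gross: float  # umol CO2 m-2 leaf s-1
    gs: float  # stomatal conductance to H2O, mol m-2 s-1
    ci: float  # umol mol-1
    psi_leaf: float  # MPa
    iterations: int = 0


def leaf_gas_exchange(
    par_abs: float,
    t_leaf: float,
    vpd: float,
    ca: float,
    params: LeafParams | None = None,
    psi_leaf: float = 0.0,
    ci_tol: float = 0.1,
    max_iter: int = 50,
) -> GasExchangeState:
    """Solve one leaf class at a fixed leaf water potential.

    Damped fixed-point iteration over Ci: assimilation -> stomatal
    conductance (Leuning with VPD and psi_l downregulation) -> Ci from the
    diffusion equation.  Raises on non-convergence.
    """
    p = params or LeafParams()
    if ca <= 0:
        raise ValueError("ca must be positive")
    fpsi = psi_stomatal_factor(psi_leaf, p.psi_onset, p.psi_closure)
    gamma = _photo_constants(t_leaf)[0]

    def _step(ci):
        a = gross_assimilation(ci, par_abs, t_leaf, p)
        gs = p.g0 + p.g1 * a / max(ca - gamma, 1.0) / (1.0 + vpd / p.d0) * fpsi
        return a, gs, min(max(ca - 1.6 * a / gs, 0.0), ca)

    ci = 0.7 * ca
    for it in range(1, max_iter + 1):
        a, gs, ci_new = _step(ci)
        if abs(ci_new - ci) < ci_tol:
            a, gs, ci_new = _step(ci_new)
            return GasExchangeState(a, gs, ci_new, psi_leaf, it)
        ci = ci + 0.5 * (ci_new - ci)

    # The damped map can two-cycle under a strong stomatal feedback; the
    # residual g(Ci) = Ci - map(Ci) brackets a root on [0, Ca], so fall back
    # to bisection, which is unconditionally convergent.
    lo, hi = 0.0, ca
    g_lo = lo - _step(lo)[2]
    for it in range(max_iter, max_iter + 60):
        mid = 0.5 * (lo + hi)
        g_mid = mid - _step(mid)[2]
        if abs(hi - lo) < ci_tol:
            a, gs, _ = _step(mid)
            return GasExchangeState(a, gs, mid, psi_leaf, it)
        if (g_mid < 0) == (g_lo < 0):
            lo, g_lo = mid, g_mid
        else:
            hi = mid
    raise GasExchangeConvergenceError(
        f"Ci iteration did not converge; last residual {abs(hi - lo):.3f}"
    )


# ---------------------------------------------------------------------------
# Coupled canopy step and diurnal integration


@dataclass(frozen=True)
class CanopyStepResult:
    e_p: float  # mmol m-2 ground s-1
    a_gross: float  # umol CO2 m-2 ground s-1
    rwu: np.ndarray  # per branch, mmol m-2 ground s-1
    psi_collar: float
    psi_leaf: float
    sunlit: GasExchangeState
    shaded: GasExchangeState
    supply_limited: bool


def solve_canopy_step(
    paths: list[HydraulicPathElement],
    r_x: float,
    par_sunlit: float,
    par_shaded: float,
    lai_sunlit: float,
    lai_shaded: float,
    t_air: float,
    vpd: float,
    ca: float,
    params: LeafParams | None = None,
    tree_height: float = 4.0,
    allow_efflux: bool = True,
    p_atm: float = 101.3,
    tol_psi: float = 0.005,
    max_iter: int = 50,
) -> CanopyStepResult:
    """Jointly solve gas exchange of both leaf classes with the SPAC network.

    Leaf temperature equals air temperature (canopy coupled to the
    atmosphere); transpiration uses the imposed-evaporation form
    E = gs * VPD / P per leaf class.  Damped fixed point over psi_l, with
    the per-class Ci loops nested inside.
    """
    p = params or LeafParams()
    grav = GRAVITY_HEAD * tree_height

    # supply cap: E_p at which psi_leaf would reach psi_min (linear network)
    finite = [q for q in paths if math.isfinite(q.r_total)]
    g_sum = sum(1.0 / q.r_total for q in finite)
    psi_bar = sum(q.psi_s / q.r_total for q in finite) / g_sum
    r_tot = 1.0 / g_sum + r_x
    e_p_crit = max((psi_bar - grav - p.psi_min) / r_tot, 0.0)

    def _evaluate(psi_l):
        """One sweep of the coupled system at a trial leaf potential."""
        sun = leaf_gas_exchange(par_sunlit, t_air, vpd, ca, p, psi_leaf=psi_l)
        sha = leaf_gas_exchange(par_shaded, t_air, vpd, ca, p, psi_leaf=psi_l)
        e_p = (
            (sun.gs * lai_sunlit + sha.gs * lai_shaded) * vpd / p_atm * 1.0e3
        )  # mmol m-2 ground s-1
        limited = e_p > e_p_crit
        if limited:
            e_p = e_p_crit
        sol = solve_soil_plant_network(paths, r_x, e_p, allow_efflux=allow_efflux)
        return sun, sha, e_p, sol, sol.psi_leaf - grav, limited

    sol = solve_soil_plant_network(paths, r_x, 0.0, allow_efflux=allow_efflux)
    psi_top = sol.psi_collar - grav  # zero-flow (most optimistic) potential
    psi_l = psi_top
    last = None
    for it in range(1, max_iter + 1):
        sun, sha, e_p, sol, psi_new, limited = _evaluate(psi_l)
        if abs(psi_new - psi_l) < tol_psi:
            psi_l = psi_new
            last = (sun, sha, e_p, sol, limited)
            break
        psi_l = psi_l + 0.5 * (psi_new - psi_l)
    else:
        # The map psi_l -> psi_new is monotone decreasing (wetter leaf ->
        # more open stomata -> more demand -> drier leaf), so the residual
        # psi - map(psi) is increasing with a bracketed unique root.
        lo = min(p.psi_min, psi_top) - 5.0
        hi = psi_top
        for it in range(max_iter, max_iter + 80):
            mid = 0.5 * (lo + hi)
            sun, sha, e_p, sol, psi_new, limited = _evaluate(mid)
            if abs(hi - lo) < tol_psi:
                psi_l = mid
                last = (sun, sha, e_p, sol, limited)
                break
            if mid - psi_new < 0:
                lo = mid
            else:
                hi = mid
        if last is None:
            raise GasExchangeConvergenceError(
                f"psi_l iteration did not converge; last residual "
                f"{abs(psi_new - psi_l):.4f}"
            )
    sun, sha, e_p, sol, limited = last
    a_ground = sun.a_gross * lai_sunlit + sha.a_gross * lai_shaded
    return CanopyStepResult(
        e_p=e_p,
        a_gross=a_ground,
        rwu=sol.rwu,
        psi_collar=sol.psi_collar,
        psi_leaf=psi_l,
        sunlit=sun,
        shaded=sha,
        supply_limited=limited,
    )


def diurnal_water_carbon(
    build_paths,
    r_x: float,
    steps,
    partitions,
    ca: float,
    params: LeafParams | None = None,
    tree_height: float = 4.0,
    canopy_wet=None,
    allow_efflux: bool = True,
):
    """Integrate the coupled SPAC/gas-exchange solution over one day.

    ``build_paths()`` returns the current branch list (soil state is taken
    as frozen within the day); ``partitions`` are per-step
    :class:`~olivecan.canopy_radiation.RadiationPartition`; steps with a
    true ``canopy_wet`` flag contribute no transpiration (intercepted water
    evaporates instead) but keep assimilating.

    Returns (E_p mm d-1, A_gross mol CO2 m-2 ground d-1, RWU mm per branch,
    midday psi_leaf MPa, psi_collar MPa at minimum).
    """
    paths = build_paths() if callable(build_paths) else build_paths
    n = len(steps)
    wet = canopy_wet if canopy_wet is not None else [False] * n
    e_day = 0.0
    a_day = 0.0
    rwu = np.zeros(len(paths))
    psi_l_min = 0.0
    psi_c_min = 0.0
    for step, part, w in zip(steps, partitions, wet):
        seconds = step.dt * 86400.0
        vpd = 0.0 if w else step.vpd
        res = solve_canopy_step(
            paths,
            r_x,
            part.par_sunlit,
            part.par_shaded,
            part.lai_sunlit,
            part.lai_shaded,
            step.temp,
            vpd,
            ca,
            params,
            tree_height=tree_height,
            allow_efflux=allow_efflux,
        )
        e_day += mmol_to_mm(res.e_p, seconds)
        a_day += res.a_gross * seconds * 1e-6  # mol m-2
        rwu += res.rwu * seconds * WATER_MOLAR_MASS * 1.0e-3  # mm per branch
        psi_l_min = min(psi_l_min, res.psi_leaf)
        psi_c_min = min(psi_c_min, res.psi_collar)
    return e_day, a_day, rwu, psi_l_min, psi_c_min
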