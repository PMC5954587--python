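"""Phenology: chilling-driven dormancy, budbreak, flowering and fruit timing.

Olive enters a dormant stage in autumn that is released by chilling
accumulation; vegetative growth resumes once the running mean temperature
exceeds a threshold, flowering follows a two-phase (chilling then forcing)
scheme, and fruit growth runs from a thermal-time offset after flowering to
maturity or harvest.  Chilling is accumulated sub-daily with a triangular
effectiveness curve (full weight at the optimum, zero at the limits).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "PhenologyParams",
    "PhenoState",
    "chilling_effectiveness",
    "accumulate_chilling",
    "flowering_date",
    "advance_phenology",
]


@dataclass(frozen=True)
class PhenologyParams:
    chill_t_min: float = 0.0  # degC, zero effectiveness below
    chill_t_opt: float = 7.0  # full effectiveness
    chill_t_max: float = 14.0  # zero above
    chill_requirement: float = 40.0  # chill-day equivalents
    forcing_base: float = 10.0  # degC, forcing thermal time base
    forcing_requirement: float = 400.0  # degCd from release to flowering
    budbreak_t_threshold: float = 12.0  # degC, 7-day running mean
    budbreak_window: int = 7  # d
    fruit_onset_tt: float = 250.0  # degCd after flowering
    maturity_tt: float = 2200.0  # degCd after flowering
    fruit_tt_base: float = 10.0  # degC, fruit thermal-time base


@dataclass
class PhenoState:
    chill_units: float = 0.0
    dormant: bool = True
    growth_active: bool = False
    flowering_doy: int | None = None
    forcing_units: float = 0.0
    tt_since_flowering: float = 0.0
    fruit_growth_active: bool = False
    mature: bool = False
    mean_temp_window: list = field(default_factory=list)

    def reset_for_autumn(self) -> None:
        """Start of a new dormancy cycle (called at the year boundary)."""
        self.chill_units = 0.0
        self.dormant = True
        self.growth_active = False
        self.flowering_doy = None
        self.forcing_units = 0.0
        self.tt_since_flowering = 0.0
        self.fruit_growth_active = False
        self.mature = False


def chilling_effectiveness(temp: float, p: PhenologyParams) -> float:
    """Triangular weight: 0 at the limits, 1 at the optimum."""
    if temp <= p.chill_t_min or temp >= p.chill_t_max:
        return 0.0
    if temp <= p.chill_t_opt:
        return (temp - p.chill_t_min) / (p.chill_t_opt - p.chill_t_min)
    return (p.chill_t_max - temp) / (p.chill_t_max - p.chill_t_opt)


def accumulate_chilling(state: PhenoState, steps, p: PhenologyParams) -> PhenoState:
    """Add sub-daily chilling (each step weighted by its day fraction)."""
    if not state.dormant:
        return state
    units = sum(chilling_effectiveness(s.temp, p) * s.dt for s in steps)
    state.chill_units += units
    if state.chill_units >= p.chill_requirement:
        state.dormant = False
    return state


def flowering_date(daily_tmean, p: PhenologyParams, state: PhenoState | None = None):
    """First day-of-year on which post-release forcing reaches the requirement.

    ``daily_tmean`` is an iterable of (day_of_year, tmean) covering one
    season in order.  Returns None if chilling or forcing is never satisfied
    (a valid outcome).  Chilling here uses the daily mean as a single step.
    """
    s = state or PhenoState()
    for doy, t in daily_tmean:
        if s.dormant:
            s.chill_units += chilling_effectiveness(t, p)
            if s.chill_units >= p.chill_requirement:
                s.dormant = False
            continue
        s.forcing_units += max(t - p.forcing_base, 0.0)
        if s.forcing_units >= p.forcing_requirement:
            return doy
    return None


def advance_phenology(
    state: PhenoState, doy: int, tmean: float, p: PhenologyParams, harvest: bool = False
) -> PhenoState:
    """Daily update of flags and thermal time after the chilling step.

    Order per day: forcing towards flowering, budbreak from the running
    temperature mean, fruit-growth onset and maturity from thermal time
    since flowering; harvest forces fruit growth to cease.
    """
    if not state.dormant:
        if state.flowering_doy is None:
            state.forcing_units += max(tmean - p.forcing_base, 0.0)
            if state.forcing_units >= p.forcing_requirement:
                state.flowering_doy = doy
        if not state.growth_active:
            state.mean_temp_window.append(tmean)
            if len(state.mean_temp_window) > p.budbreak_window:
                state.mean_temp_window.pop(0)
            if (
                len(state.mean_temp_window) == p.budbreak_window
                and sum(state.mean_temp_window) / p.budbreak_window
                > p.budbreak_t_threshold
            ):
                state.growth_active = True
                state.mean_temp_window = []

    if state.flowering_doy is not None and not state.mature:
        state.tt_since_flowering += max(tmean - p.fruit_tt_base, 0.0)
        if (
            not state.fruit_growth_active
            and state.tt_since_flowering >= p.fruit_onset_tt
        ):
            state.fruit_growth_active = True
        if state.tt_since_flowering >= p.maturity_tt:
            state.mature = True
            state.fruit_growth_active = False

    if harvest:
        state.fruit_growth_active = False
    return state
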