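"""Goodness-of-fit statistics and biennial aggregation for model testing.

Simulated series are compared with field observations through the mean
absolute error (MAE), signed mean error (ME = mean of M - S), root mean
square error (RMSE), coefficient of residual mass (CRM = 1 - sum(S)/sum(M)),
Nash-Sutcliffe modelling efficiency (EF) and an OLS regression of simulated
on measured values.  Because alternate bearing shifts yield between adjacent
years, statistics are also reported on overlapping two-year means per
treatment ("biennia").

A packaged fixture ships the published olive-orchard evaluation dataset
(two 3-year irrigation experiments near Cordoba: seasonal ET and annual oil
yield per treatment, with some ET observations missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "GoodnessOfFit",
    "fit_metrics",
    "linear_regression",
    "biennial_aggregate",
    "evaluate_run",
    "load_reference_dataset",
]

#: Treatment label aliases: the published table labels Experiment I's control
#: "FI" and Experiment II's continuous-deficit "SDI" where the running text
#: calls them "CON" and "CDI".
TREATMENT_ALIASES = {("I", "CON"): "FI", ("II", "CDI"): "SDI"}


@dataclass(frozen=True)
class PairedSeries:
    """Aligned observed/simulated pairs with their grouping labels."""

    experiment: np.ndarray
    treatment: np.ndarray
    year: np.ndarray
    observed: np.ndarray
    simulated: np.ndarray

    @classmethod
    def from_arrays(cls, experiment, treatment, year, observed, simulated):
        obs = np.asarray(observed, dtype=float)
        sim = np.asarray(simulated, dtype=float)
        keep = ~(np.isnan(obs) | np.isnan(sim))
        return cls(
            np.asarray(experiment, dtype=object)[keep],
            np.asarray(treatment, dtype=object)[keep],
            np.asarray(year)[keep],
            obs[keep],
            sim[keep],
        )

    @property
    def n(self) -> int:
        return len(self.observed)


@dataclass(frozen=True)
class GoodnessOfFit:
    n: int
    mae: float  # mean |S - M|
    me: float  # mean (M - S), the signed bias
    rmse: float
    crm: float
    ef: float
    slope: float
    intercept: float
    r2: float


def fit_metrics(pairs: PairedSeries) -> GoodnessOfFit:
    """All goodness-of-fit statistics for one paired series.

    MAE uses absolute residuals; ME is the signed mean of M - S (reported
    separately because published summaries sometimes print the signed form
    under the MAE heading).  CRM requires a non-zero observed total.
    """
    m, s = pairs.observed, pairs.simulated
    n = pairs.n
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    if m.sum() == 0:
        raise ValueError("CRM undefined: observed values sum to zero")
    mae = float(np.mean(np.abs(s - m)))
    me = float(np.mean(m - s))
    rmse = float(np.sqrt(np.mean((s - m) ** 2)))
    crm = float(1.0 - s.sum() / m.sum())
    ss_obs = float(np.sum((m - m.mean()) ** 2))
    ef = float(1.0 - np.sum((s - m) ** 2) / ss_obs) if ss_obs > 0 else float("nan")
    slope, intercept, r2 = linear_regression(pairs)
    return GoodnessOfFit(n, mae, me, rmse, crm, ef, slope, intercept, r2)


def linear_regression(pairs: PairedSeries) -> tuple[float, float, float]:
    """OLS of simulated on measured; r^2 is the squared Pearson correlation."""
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs for a regression")
    if np.var(pairs.observed) == 0:
        raise ValueError("observed values have zero variance")
    res = stats.linregress(pairs.observed, pairs.simulated)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def biennial_aggregate(pairs: PairedSeries) -> PairedSeries:
    """Overlapping consecutive-year means per (experiment, treatment).

    Three years yield two biennia — (y1,y2) and (y2,y3) — so 24 annual
    pairs over 8 treatments reduce to 16.  Single-year treatments are
    skipped.
    """
    df = pd.DataFrame(
        {
            "experiment": pairs.experiment,
            "treatment": pairs.treatment,
            "year": pairs.year,
            "observed": pairs.observed,
            "simulated": pairs.simulated,
        }
    )
    rows = []
    for (exp, trt), grp in df.groupby(["experiment", "treatment"], sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        for i in range(len(grp) - 1):
            if years[i + 1] - years[i] != 1:
                continue
            rows.append(
                (
                    exp,
                    trt,
                    years[i + 1],
                    0.5 * (grp["observed"].iloc[i] + grp["observed"].iloc[i + 1]),
                    0.5 * (grp["simulated"].iloc[i] + grp["simulated"].iloc[i + 1]),
                )
            )
    if not rows:
        raise ValueError("no treatment has two consecutive years")
    exp, trt, yr, obs, sim = zip(*rows)
    return PairedSeries.from_arrays(exp, trt, yr, obs, sim)


def load_reference_dataset() -> pd.DataFrame:
    """The packaged evaluation fixture (observed and simulated columns).

    Missing observations are marked '*' in the file and become NaN.
    """
    with resources.files("olivecan.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh, na_values=["*"])
    return df


def evaluate_run(
    simulated: pd.DataFrame,
    observed: pd.DataFrame,
    variables: dict[str, tuple[str, str]] | None = None,
) -> dict[str, dict[str, GoodnessOfFit]]:
    """Join simulated and observed tables and compute annual and biennial
    statistics per variable.

    Both tables need ``experiment``, ``treatment`` and ``year`` label
    columns; ``variables`` maps a report name to the (observed column,
    simulated column) pair.  Missing observations are excluded from n
    variable by variable.  Raises when the join is empty.
    """
    if variables is None:
        variables = {"et": ("et_obs", "et_sim"), "yoil": ("yoil_obs", "yoil_sim")}
    keys = ["experiment", "treatment", "year"]
    sim = simulated.copy()
    sim["treatment"] = [
        TREATMENT_ALIASES.get((e, t), t)
        for e, t in zip(sim["experiment"], sim["treatment"])
    ]
    merged = observed.merge(sim, on=keys, how="inner", suffixes=("_o", "_s"))
    if merged.empty:
        unmatched = set(map(tuple, observed[keys].values)) - set(
            map(tuple, sim[keys].values)
        )
        raise ValueError(f"empty join; unmatched labels include {sorted(unmatched)[:5]}")

    report: dict[str, dict[str, GoodnessOfFit]] = {}
    for name, (obs_col, sim_col) in variables.items():
        oc = obs_col if obs_col in merged.columns else f"{obs_col}_o"
        sc = sim_col if sim_col in merged.columns else f"{sim_col}_s"
        pairs = PairedSeries.from_arrays(
            merged["experiment"], merged["treatment"], merged["year"],
            merged[oc], merged[sc],
        )
        entry = {"annual": fit_metrics(pairs)}
        try:
            entry["biennial"] = fit_metrics(biennial_aggregate(pairs))
        except ValueError:
            pass
        report[name] = entry
    return report
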