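"""Broken-stick (two-segment) regression for eAge time courses.

During OSKM reprogramming the predicted epigenetic age of fibroblast-derived
cells falls roughly linearly from early time points until a breakpoint and
then plateaus near zero. The model fitted here is two straight lines
constrained to join continuously at a breakpoint tau:

    y(t) = a + b1 * min(t - t0, tau - t0) + b2 * max(t - tau, 0)

where t0 is the start of the fit window, b1 the pre-break slope (the
rejuvenation rate in years/day) and b2 the post-break slope. tau is found by
exhaustive search over a candidate grid; for fixed tau the model is linear
and fitted by ordinary least squares on replicate-level observations.
Inference on b1 (SE, two-sided t-test, df = n - 3) conditions on the
estimated breakpoint, which is standard broken-stick practice; the p-value
must be read as conditional on tau-hat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TimeCourse",
    "BrokenStickFit",
    "aggregate_timecourse",
    "default_breakpoint_grid",
    "fit_broken_stick",
    "simulate_fit_recovery",
    "piecewise_linear",
]

# RSS improvements below this (relative) are treated as ties, broken toward
# the smallest candidate breakpoint.
_TIE_RTOL = 1e-10


@dataclass
class TimeCourse:
    """Day-indexed aggregate of per-sample ages, replicate values retained.

    ``table`` has one row per distinct day (columns ``day``, ``mean``,
    ``sd``, ``n``); ``observations`` keeps the replicate-level points
    (columns ``day``, ``value``) that the broken-stick fit uses.
    """

    table: pd.DataFrame
    observations: pd.DataFrame

    def __post_init__(self):
        days = self.table["day"].to_numpy()
        if not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        if (self.table["n"] < 1).any() or (self.table["sd"] < 0).any():
            raise ValueError("per-day n must be >= 1 and sd >= 0")

    @property
    def days(self) -> np.ndarray:
        return self.table["day"].to_numpy()


def aggregate_timecourse(eages: pd.DataFrame, sheet: pd.DataFrame) -> TimeCourse:
    """Join per-sample ages to the sample sheet and aggregate per day.

    ``eages`` is the table produced by :func:`rejuvotrack.clocks.predict_age`
    (needs columns ``sample`` and ``eage``). Every sample must appear in the
    sheet. SD is the sample standard deviation (ddof=1), 0 for n = 1.
    """
    unmatched = set(eages["sample"]) - set(sheet["sample"])
    if unmatched:
        raise KeyError(f"samples missing from sample sheet: {sorted(unmatched)[:10]}")
    merged = eages.merge(sheet[["sample", "day"]], on="sample", how="left")
    obs = (
        merged[["day", "eage"]]
        .rename(columns={"eage": "value"})
        .sort_values(["day"], kind="stable", ignore_index=True)
    )
    grouped = obs.groupby("day")["value"]
    table = grouped.agg(
        mean="mean", sd=lambda v: v.std(ddof=1), n="size"
    ).reset_index()
    table.loc[table["n"] == 1, "sd"] = 0.0
    table["n"] = table["n"].astype(int)
    return TimeCourse(table=table.sort_values("day", ignore_index=True), observations=obs)


@dataclass
class BrokenStickFit:
    """Result of a continuous two-segment least-squares fit."""

    breakpoint: float            # tau, days
    intercept: float             # value of segment 1 at the window start, years
    slope1: float                # years/day before tau
    slope2: float                # years/day after tau
    se_slope1: float             # conditional on the estimated tau
    p_slope1: float              # two-sided, df = n_obs - 3, conditional on tau
    rss: float
    window: tuple[float, float]
    n_obs: int
    grid: list[float] = field(default_factory=list)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        t0 = self.window[0]
        return (
            self.intercept
            + self.slope1 * np.minimum(t - t0, self.breakpoint - t0)
            + self.slope2 * np.maximum(t - self.breakpoint, 0.0)
        )

    def to_json(self, path, clock: str | None = None, **extra) -> None:
        report = {"clock": clock, **asdict(self), **extra}
        report["window"] = list(report["window"])
        Path(path).write_text(json.dumps(report, indent=2) + "\n")


def default_breakpoint_grid(days, window) -> list[float]:
    """Candidate breakpoints: observed days strictly inside the window plus
    midpoints between adjacent observed days, keeping only candidates with at
    least two distinct observed days on each side (sides include the
    candidate itself when it is an observed day)."""
    lo, hi = window
    days = np.unique(np.asarray(days, dtype=float))
    days = days[(days >= lo) & (days <= hi)]
    interior = days[(days > lo) & (days < hi)]
    mids = (days[:-1] + days[1:]) / 2.0
    candidates = np.unique(np.concatenate([interior, mids]))
    keep = [
        float(tau)
        for tau in candidates
        if lo < tau < hi
        and np.sum(days <= tau) >= 2
        and np.sum(days >= tau) >= 2
    ]
    return keep


def _design(t: np.ndarray, tau: float, t0: float) -> np.ndarray:
    return np.column_stack(
        [
            np.ones_like(t),
            np.minimum(t - t0, tau - t0),
            np.maximum(t - tau, 0.0),
        ]
    )


def fit_broken_stick(
    tc: TimeCourse,
    window: tuple[float, float] = (3.0, 49.0),
    grid: list[float] | None = None,
) -> BrokenStickFit:
    """Fit the continuous two-segment model on replicate-level points.

    For every candidate tau in ``grid`` the model is fitted by least squares;
    the tau minimizing the residual sum of squares wins, ties broken toward
    the smallest tau. Requires at least 5 observations spanning at least 4
    distinct days inside ``window``.
    """
    lo, hi = window
    obs = tc.observations
    mask = (obs["day"] >= lo) & (obs["day"] <= hi)
    t = obs.loc[mask, "day"].to_numpy(dtype=float)
    y = obs.loc[mask, "value"].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError(f"window {window} contains no observations")
    if t.size < 5 or np.unique(t).size < 4:
        raise ValueError(
            "broken-stick fit needs >= 5 observations over >= 4 distinct days"
        )

    if grid is None:
        grid = default_breakpoint_grid(t, window)
    grid = sorted(float(g) for g in grid)
    days_in = np.unique(t)
    usable = [
        tau
        for tau in grid
        if lo < tau < hi
        and np.sum(days_in <= tau) >= 2
        and np.sum(days_in >= tau) >= 2
    ]
    if not usable:
        raise ValueError(
            "no usable breakpoint candidate: need >= 2 distinct days on each side"
        )

    t0 = lo
    best = None  # (rss, tau, coefs)
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    for tau in usable:  # ascending: strict improvement => smallest-tau ties
        X = _design(t, tau, t0)
        coefs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coefs) ** 2))
        if best is None or rss < best[0] - _TIE_RTOL * scale:
            best = (rss, tau, coefs)

    rss, tau, coefs = best
    X = _design(t, tau, t0)
    ols = sm.OLS(y, X).fit()
    se1 = float(ols.bse[1])
    p1 = float(ols.pvalues[1])
    if not np.isfinite(p1):  # perfect fits leave the t-statistic undefined
        p1 = 0.0 if abs(coefs[1]) > 0 else 1.0
    return BrokenStickFit(
        breakpoint=float(tau),
        intercept=float(coefs[0]),
        slope1=float(coefs[1]),
        slope2=float(coefs[2]),
        se_slope1=se1,
        p_slope1=p1,
        rss=rss,
        window=(float(lo), float(hi)),
        n_obs=int(t.size),
        grid=[float(g) for g in usable],
    )


def piecewise_linear(
    t,
    breakpoint: float,
    slope1: float,
    slope2: float = 0.0,
    value_at_breakpoint: float = 0.0,
    decline_start_day: float | None = None,
):
    """Evaluate the continuous two-segment truth curve at days ``t``.

    Before ``decline_start_day`` (if given) the curve is held flat at its
    value there, emulating the lag before rejuvenation begins.
    """
    t = np.asarray(t, dtype=float)
    if decline_start_day is not None:
        t = np.maximum(t, decline_start_day)
    return np.where(
        t <= breakpoint,
        value_at_breakpoint + slope1 * (t - breakpoint),
        value_at_breakpoint + slope2 * (t - breakpoint),
    )


def simulate_fit_recovery(
    days,
    breakpoint: float,
    slope1: float,
    noise_sd: float,
    n_reps: int,
    n_sims: int,
    seed: int,
    slope2: float = 0.0,
    value_at_breakpoint: float = 0.0,
    decline_start_day: float | None = None,
    window: tuple[float, float] = (3.0, 49.0),
    grid: list[float] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo recovery of the broken-stick parameters.

    Simulates ``n_sims`` time courses from the piecewise-linear truth with
    ``n_reps`` replicates per day and i.i.d. Gaussian age noise, refits each
    with :func:`fit_broken_stick`, and returns one row per simulation with
    columns ``tau_hat``, ``slope1_hat``, ``slope2_hat``, ``se_slope1``.
    Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_sims < 1 or n_reps < 1:
        raise ValueError("n_sims and n_reps must be >= 1")
    days = np.asarray(days, dtype=float)
    truth = piecewise_linear(
        days, breakpoint, slope1, slope2, value_at_breakpoint, decline_start_day
    )
    t_rep = np.repeat(days, n_reps)
    mu_rep = np.repeat(truth, n_reps)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_sims):
        y = mu_rep + rng.normal(0.0, noise_sd, size=mu_rep.size) if noise_sd else mu_rep.copy()
        obs = pd.DataFrame({"day": t_rep, "value": y}).sort_values(
            "day", kind="stable", ignore_index=True
        )
        grouped = obs.groupby("day")["value"]
        table = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
        table.loc[table["n"] == 1, "sd"] = 0.0
        tc = TimeCourse(table=table, observations=obs)
        fit = fit_broken_stick(tc, window=window, grid=grid)
        rows.append(
            {
                "tau_hat": fit.breakpoint,
                "slope1_hat": fit.slope1,
                "slope2_hat": fit.slope2,
                "se_slope1": fit.se_slope1,
            }
        )
    return pd.DataFrame(rows)
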