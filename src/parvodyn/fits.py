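"""Curve fits extracting biological rates from the four experiment tables.

Every routine accepts either a list of observation dataclasses, a tidy
DataFrame, or plain x/y arrays, and returns a typed fit-result object. All
nonlinear fits are ordinary least squares via lmfit (Levenberg-Marquardt),
with deterministic jittered restarts on non-convergence.
"""
from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import optimize, stats

from .types import (
    DecayObservation,
    FitFailure,
    FourParamLogisticFit,
    GrowthEstimate,
    HollingFit,
    MortalityFit,
    RatioObservation,
    YieldRegression,
)

__all__ = [
    "logistic4",
    "holling2",
    "fit_four_param_logistic",
    "infectivity_half_time",
    "fit_zoospore_mortality",
    "growth_rate",
    "growth_rate_series",
    "fit_holling_type2",
    "fit_yield_regression",
]

HOURS_PER_DAY = 24.0
DEFAULT_SEARCH_WINDOW_H = 15.0  # max hours after release a zoospore can infect


def logistic4(x, a, b, c, d):
    """Four-parameter logistic: y = d + (a - d) / (1 + exp(b (x - c))).

    Decreasing in x for b > 0; a and d are the upper/lower asymptotes and c
    the x where y = (a + d) / 2.
    """
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + np.exp(b * (x - c)))


def holling2(x, a, b):
    """Holling type-II disc equation, y = a x / (1 + a b x)."""
    x = np.asarray(x, dtype=float)
    return a * x / (1.0 + a * b * x)


def _xy(obs, x_attr: str, y_attr: str, x=None, y=None):
    """Normalise observations to (x, y) float arrays."""
    if x is not None or y is not None:
        if x is None or y is None:
            raise ValueError("provide both x and y")
        return np.asarray(x, float), np.asarray(y, float)
    if isinstance(obs, pd.DataFrame):
        cols = set(obs.columns)
        if {x_attr, y_attr} <= cols:
            return obs[x_attr].to_numpy(float), obs[y_attr].to_numpy(float)
        if {"x", "y"} <= cols:
            return obs["x"].to_numpy(float), obs["y"].to_numpy(float)
        raise ValueError(f"DataFrame needs columns ({x_attr}, {y_attr}) or (x, y)")
    xs = np.array([getattr(o, x_attr) for o in obs], dtype=float)
    ys = np.array([getattr(o, y_attr) for o in obs], dtype=float)
    return xs, ys


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def _stderr(result, names) -> dict[str, float]:
    out = {}
    for n in names:
        se = result.params[n].stderr
        out[n] = float(se) if se is not None else float("nan")
    return out


# ---------------------------------------------------------------------------
# Four-parameter logistic (infectivity decay with zoospore age)
# ---------------------------------------------------------------------------

def fit_four_param_logistic(
    obs: Sequence[DecayObservation] | pd.DataFrame | None = None,
    *,
    x=None,
    y=None,
    max_restarts: int = 5,
) -> FourParamLogisticFit:
    """Fit the 4PL infectivity-decay curve, pooling all observations.

    Seeding: a <- max(y), d <- min(y), c <- age whose y is nearest
    (a + d)/2, b <- 1; up to ``max_restarts`` deterministically jittered
    restarts on non-convergence.

    Raises
    ------
    FitFailure
        If fewer than 5 distinct ages are supplied, the data are flat
        (no decay signal to locate a midpoint in), or the optimizer fails
        after all restarts.
    """
    ages, pct = _xy(obs, "zoospore_age", "infection_pct", x=x, y=y)
    if len(np.unique(ages)) < 5:
        raise FitFailure("need >= 5 distinct zoospore ages for a 4PL fit")
    if np.ptp(pct) < 1e-9:
        raise FitFailure("degenerate flat data: no midpoint is identifiable")

    a0, d0 = float(np.max(pct)), float(np.min(pct))
    c0 = float(ages[np.argmin(np.abs(pct - (a0 + d0) / 2.0))])
    c0 = max(c0, 1e-3)
    model = Model(logistic4)
    rng = np.random.default_rng(0)  # deterministic restart jitter

    last_residual = None
    best = None
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            p0 = dict(a=a0, b=1.0, c=c0, d=d0)
        else:
            jit = rng.normal(scale=0.3, size=4)
            p0 = dict(
                a=a0 * (1 + 0.1 * jit[0]),
                b=float(np.exp(jit[1])),
                c=max(c0 * (1 + 0.3 * jit[2]), 1e-3),
                d=d0 + 0.1 * (a0 - d0) * abs(jit[3]),
            )
        params = model.make_params(**p0)
        params["c"].set(min=1e-6)
        try:
            res = model.fit(pct, params, x=ages)
        except Exception:
            continue
        last_residual = res.residual
        if res.success and np.isfinite(res.chisqr):
            if best is None or res.chisqr < best.chisqr:
                best = res
            if attempt == 0:
                break  # default seeding converged; keep it
    if best is None:
        raise FitFailure("4PL fit did not converge", last_residual=last_residual)

    p = best.params
    a, b, c, d = (float(p[k].value) for k in "abcd")
    if a < d:  # relabel so a is always the upper asymptote
        a, d = d, a
        b = -b
    return FourParamLogisticFit(
        upper_asymptote_a=a,
        lower_asymptote_d=d,
        slope_b=b,
        midpoint_c=c,
        r_squared=_r_squared(pct, best.best_fit),
        param_se=_stderr(best, "abcd"),
        converged=bool(best.success),
    )


def fit_four_param_logistic_per_replicate(
    obs: Sequence[DecayObservation] | pd.DataFrame,
) -> dict[int, FourParamLogisticFit]:
    """Fit each replicate separately (to reproduce mean +/- SE style spreads)."""
    if isinstance(obs, pd.DataFrame):
        groups = {int(k): g for k, g in obs.groupby("replicate")}
    else:
        groups = {}
        for o in obs:
            groups.setdefault(int(o.replicate), []).append(o)
    return {rep: fit_four_param_logistic(g) for rep, g in sorted(groups.items())}


def infectivity_half_time(fit: FourParamLogisticFit) -> float:
    """Age (hours) when infectivity is halfway between the asymptotes: c."""
    return fit.midpoint_c


# ---------------------------------------------------------------------------
# Exponential zoospore mortality
# ---------------------------------------------------------------------------

def _exp_decay(t, y0, m):
    return y0 * np.exp(-m * np.asarray(t, float))


def fit_zoospore_mortality(
    obs: Sequence[DecayObservation] | pd.DataFrame | None = None,
    *,
    x=None,
    y=None,
) -> MortalityFit:
    """Fit y = y0 exp(-m t) to infectivity vs zoospore age.

    Ages arrive in hours and are converted to days before fitting so the
    mortality rate m is natively d^-1. The infectivity decay is the paper
    trail for zoospore death: direct survival of the swimming stage is not
    observable, so its loss of infectivity stands in for it.
    """
    ages_h, pct = _xy(obs, "zoospore_age", "infection_pct", x=x, y=y)
    if len(np.unique(ages_h)) < 3:
        raise FitFailure("need >= 3 distinct ages for the exponential decay fit")
    if np.all(pct == 0):
        raise FitFailure("all-zero series: no decay level to fit")
    t_days = ages_h / HOURS_PER_DAY

    model = Model(_exp_decay, independent_vars=["t"])
    params = model.make_params(y0=float(np.max(pct)), m=1.0)
    try:
        res = model.fit(pct, params, t=t_days)
    except Exception as exc:  # pragma: no cover - lmfit raises rarely here
        raise FitFailure(f"exponential decay fit failed: {exc}") from exc
    if not res.success:
        raise FitFailure("exponential decay fit did not converge",
                         last_residual=res.residual)
    m = float(res.params["m"].value)
    if m < -1e-10:
        raise FitFailure("series increases with age: negative mortality")
    return MortalityFit(
        initial_level=float(res.params["y0"].value),
        mortality_m=max(m, 0.0),
        r_squared=_r_squared(pct, res.best_fit),
        param_se=_stderr(res, ["y0", "m"]),
    )


# ---------------------------------------------------------------------------
# Exponential growth rate
# ---------------------------------------------------------------------------

def growth_rate(N1: float, N2: float, t1: float, t2: float) -> GrowthEstimate:
    """mu = ln(N2/N1) / (t2 - t1), abundances in cells mL^-1, times in days."""
    if N1 <= 0 or N2 <= 0:
        raise ValueError("abundances must be > 0")
    if t2 <= t1:
        raise ValueError("t2 must be > t1")
    mu = math.log(N2 / N1) / (t2 - t1)
    return GrowthEstimate(mu=mu, N1=N1, N2=N2, t1=t1, t2=t2)


def growth_rate_series(times: Iterable[float], counts: Iterable[float]) -> list[GrowthEstimate]:
    """Day-over-day growth estimates along one count series."""
    t = np.asarray(list(times), float)
    n = np.asarray(list(counts), float)
    order = np.argsort(t)
    t, n = t[order], n[order]
    return [growth_rate(n[i], n[i + 1], t[i], t[i + 1]) for i in range(len(t) - 1)]


# ---------------------------------------------------------------------------
# Holling type-II functional response
# ---------------------------------------------------------------------------

def fit_holling_type2(
    obs: Sequence[RatioObservation] | pd.DataFrame | None = None,
    *,
    x=None,
    y=None,
    search_window_T: float = DEFAULT_SEARCH_WINDOW_H,
) -> HollingFit:
    """Fit infection percentage vs zoospore:host ratio to the disc equation.

    The fitted curve is y = a x / (1 + a b x) with a, b >= 0: a is the attack
    rate (initial slope, percent per ratio unit) and b the handling
    coefficient. The attack rate is then expressed per day as
    a' = (a/100) * (24 / T) where T is the searching window in hours
    (zoospores stay infective only ~15 h after release).
    """
    ratios, pct = _xy(obs, "zoospore_host_ratio", "infection_pct", x=x, y=y)
    if len(np.unique(ratios)) < 4:
        raise FitFailure("need >= 4 distinct zoospore:host ratios")
    if search_window_T <= 0:
        raise ValueError("search_window_T must be > 0 hours")

    # slope through the lowest ratio seeds a; the high-ratio plateau seeds b
    lo = np.argmin(ratios)
    a0 = max(pct[lo] / ratios[lo], 1e-3)
    plateau = float(np.max(pct))
    b0 = 1.0 / plateau if plateau > 0 else 0.1

    model = Model(holling2)
    params = model.make_params(a=a0, b=b0)
    params["a"].set(min=0.0)
    params["b"].set(min=0.0)
    try:
        res = model.fit(pct, params, x=ratios)
    except Exception as exc:
        raise FitFailure(f"Holling-II fit failed: {exc}") from exc
    if not res.success:
        raise FitFailure("Holling-II fit did not converge", last_residual=res.residual)

    a = float(res.params["a"].value)
    b = float(res.params["b"].value)
    at_bound = a <= 1e-12 or b <= 1e-12
    return HollingFit(
        slope_a=a,
        handling_b=b,
        attack_daily=(a / 100.0) * (HOURS_PER_DAY / search_window_T),
        search_window_T=search_window_T,
        r_squared=_r_squared(pct, res.best_fit),
        param_se=_stderr(res, ["a", "b"]),
        at_bound=at_bound,
    )


# ---------------------------------------------------------------------------
# Sporocyte diameter -> zoospore yield regression
# ---------------------------------------------------------------------------

def fit_yield_regression(points) -> YieldRegression:
    """OLS of zoospore count on late-sporocyte diameter (microns).

    ``points`` is an iterable of (diameter, count) pairs or a DataFrame with
    ``diameter_um``/``zoospore_count`` (or x/y) columns.
    """
    if isinstance(points, pd.DataFrame):
        cols = set(points.columns)
        if {"diameter_um", "zoospore_count"} <= cols:
            d = points["diameter_um"].to_numpy(float)
            c = points["zoospore_count"].to_numpy(float)
        else:
            d = points["x"].to_numpy(float)
            c = points["y"].to_numpy(float)
    else:
        arr = np.asarray(list(points), dtype=float)
        d, c = arr[:, 0], arr[:, 1]
    if len(d) < 3:
        raise FitFailure("need >= 3 sporocytes for the yield regression")
    if len(np.unique(d)) < 2:
        raise FitFailure("all diameters identical: slope is unidentifiable")

    lr = stats.linregress(d, c)
    return YieldRegression(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r_squared=float(lr.rvalue**2),
        slope_se=float(lr.stderr),
        intercept_se=float(lr.intercept_stderr),
        diameters=d,
        counts=c,
    )
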