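"""Five-state host-parasitoid model and its numerical integration.

State variables (cells mL^-1): H1, H2 uninfected hosts; I1, I2 infected
hosts; P free zoospores. The two hosts compete through a shared logistic
term, the parasitoid removes hosts through a Holling type-II infection term
saturating in host density, infected hosts mature to zoospore release over
the handling (generation) time h, and free zoospores die at rate m:

    dH_i/dt = r_i H_i (K - H1 - H2)/K - f_i(H_i) P
    dI_i/dt = f_i(H_i) P - I_i / h_i
    dP/dt   = eps1 I1/h1 + eps2 I2/h2 - f1(H1) P - f2(H2) P - m P

with f_i(H) = a_i H / (1 + a_i h_i H). Only the uninfected hosts occupy
carrying capacity (infected cells sink out of the competitive pool), and
zoospore release is continuous at rate eps_i I_i / h_i.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .types import (
    STATE_NAMES,
    SimulationSummary,
    SystemState,
    TemperatureParameterSet,
    Trajectory,
)

__all__ = [
    "derivatives",
    "simulate",
    "Scenario",
    "SCENARIOS",
    "run_temperature_grid",
    "summarize",
    "optimum_temperature",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-6  # cells mL^-1
GROWTH_HORIZON_DAYS = 14.0  # matches the 14-day growth experiment
# long enough for the epidemic to peak and decline at every temperature
# (latest host peak ~12 d, epidemic burn-out by ~25 d), but short of the
# spurious regrowth a continuous-state model seeds from sub-cell remnants
# after the hosts crash
PARASITOID_HORIZON_DAYS = 30.0


def _rhs(y: np.ndarray, p: TemperatureParameterSet) -> np.ndarray:
    # clip inside the derivative so tiny negative excursions cannot feed back
    H1, H2, I1, I2, P = np.maximum(y, 0.0)
    crowd = (p.K - H1 - H2) / p.K
    f1 = p.a1 * H1 / (1.0 + p.a1 * p.h1 * H1)  # infections per zoospore per day
    f2 = p.a2 * H2 / (1.0 + p.a2 * p.h2 * H2)
    dH1 = p.r1 * H1 * crowd - f1 * P
    dH2 = p.r2 * H2 * crowd - f2 * P
    dI1 = f1 * P - I1 / p.h1
    dI2 = f2 * P - I2 / p.h2
    dP = p.eps1 * I1 / p.h1 + p.eps2 * I2 / p.h2 - f1 * P - f2 * P - p.m * P
    return np.array([dH1, dH2, dI1, dI2, dP])


def derivatives(state: SystemState, params: TemperatureParameterSet) -> SystemState:
    """Instantaneous rates of change (per day) of the five state variables."""
    d = _rhs(state.as_array(), params)
    # rates can be negative, so bypass SystemState's non-negativity check
    obj = object.__new__(SystemState)
    for name, value in zip(STATE_NAMES, d):
        object.__setattr__(obj, name, float(value))
    return obj


def simulate(
    initial: SystemState,
    params: TemperatureParameterSet,
    horizon: float,
    dt_out: float = 0.05,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    scenario: str = "",
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model to ``horizon`` days on a uniform output grid.

    Uses a stiff-capable adaptive solver; output states are clipped at zero
    (excursions below -atol would indicate an integrator failure and raise).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0 days")
    t_eval = np.arange(0.0, horizon + 0.5 * dt_out, dt_out)
    t_eval[-1] = min(t_eval[-1], horizon)
    sol = solve_ivp(
        lambda t, y: _rhs(y, params),
        (0.0, horizon),
        initial.as_array(),
        t_eval=t_eval,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed for scenario {scenario!r} at "
            f"{params.temperature} degC: {sol.message}"
        )
    states = sol.y.T
    if states.min() < -100.0 * atol:
        raise RuntimeError(
            f"state went negative beyond tolerance ({states.min():.3g}) in "
            f"scenario {scenario!r} at {params.temperature} degC"
        )
    clip_events = int(np.sum(states.min(axis=1) < 0.0))
    return Trajectory(
        times=sol.t,
        states=np.clip(states, 0.0, None),
        parameters=params,
        scenario=scenario,
        clip_events=clip_events,
    )


@dataclass(frozen=True)
class Scenario:
    """Which populations are initialized nonzero."""

    name: str
    host1: bool
    host2: bool
    parasitoid: bool

    @property
    def horizon(self) -> float:
        return PARASITOID_HORIZON_DAYS if self.parasitoid else GROWTH_HORIZON_DAYS


SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in (
        Scenario("host1_alone", True, False, False),
        Scenario("host2_alone", False, True, False),
        Scenario("both", True, True, False),
        Scenario("host1_alone_parasitoid", True, False, True),
        Scenario("host2_alone_parasitoid", False, True, True),
        Scenario("both_parasitoid", True, True, True),
    )
}


def _summary_of(traj: Trajectory) -> SimulationSummary:
    def peak(series):
        i = int(np.argmax(series))
        return float(series[i]), float(traj.times[i])

    max_H1, t1 = peak(traj.H1)
    max_H2, t2 = peak(traj.H2)
    max_P, tp = peak(traj.P)
    dom = max_H2 / max_H1 if max_H1 > 0 else float("inf") if max_H2 > 0 else float("nan")
    return SimulationSummary(
        scenario=traj.scenario,
        temperature=traj.parameters.temperature,
        max_H1=max_H1, t_max_H1=t1,
        max_H2=max_H2, t_max_H2=t2,
        max_P=max_P, t_max_P=tp,
        dominance_ratio=dom,
    )


def summarize(traj_with: Trajectory, traj_without: Trajectory) -> SimulationSummary:
    """Peak metrics of the with-parasitoid run plus with/without impact ratios.

    The impact ratio for each host is (peak abundance with the parasitoid) /
    (peak abundance without); 0/positive is 0, 0/0 is NaN (host absent).
    """
    if traj_with.parameters.temperature != traj_without.parameters.temperature:
        raise ValueError("trajectories must share a temperature")
    s = _summary_of(traj_with)
    ref = _summary_of(traj_without)

    def ratio(with_max, without_max):
        if without_max > 0:
            return with_max / without_max
        return float("nan")

    s.impact_ratio_H1 = ratio(s.max_H1, ref.max_H1)
    s.impact_ratio_H2 = ratio(s.max_H2, ref.max_H2)
    return s


def run_temperature_grid(
    param_table: list[TemperatureParameterSet],
    scenarios: list[Scenario] | list[str] | None = None,
    horizons: dict[str, float] | None = None,
    dt_out: float = 0.05,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> list[tuple[Trajectory, SimulationSummary]]:
    """One (trajectory, summary) per scenario x temperature.

    ``scenarios`` may be Scenario objects or names from ``SCENARIOS``;
    defaults to all six. ``horizons`` optionally overrides the per-scenario
    horizon (growth-only 14 d, with-parasitoid 60 d).
    """
    from .params import initial_state

    if scenarios is None:
        scenarios = list(SCENARIOS.values())
    resolved: list[Scenario] = []
    for s in scenarios:
        if isinstance(s, str):
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}; known: {sorted(SCENARIOS)}")
            s = SCENARIOS[s]
        resolved.append(s)
    if not param_table:
        raise ValueError("parameter table is empty")

    out = []
    for scen in resolved:
        horizon = (horizons or {}).get(scen.name, scen.horizon)
        for p in param_table:
            traj = simulate(
                initial_state(scen.host1, scen.host2, scen.parasitoid),
                p,
                horizon=horizon,
                dt_out=dt_out,
                rtol=rtol,
                atol=atol,
                scenario=scen.name,
            )
            out.append((traj, _summary_of(traj)))
    return out


def optimum_temperature(values_by_temperature: dict[float, float],
                        rel_tol: float = 1e-9) -> tuple[list[float], float]:
    """Argmax temperature(s) of a per-temperature metric on the grid.

    Returns the full argmax set (ties within ``rel_tol`` of the maximum) and,
    as the single representative, the lowest temperature in that set.
    """
    if not values_by_temperature:
        raise ValueError("empty grid")
    vmax = max(values_by_temperature.values())
    cutoff = vmax * (1 - rel_tol) if vmax > 0 else vmax
    ties = sorted(T for T, v in values_by_temperature.items() if v >= cutoff)
    return ties, ties[0]
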