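"""Domain types shared across the fitting, simulation and pipeline layers.

All abundances are cells mL^-1, times are days unless a field name says
hours, rates are d^-1, temperatures are degrees Celsius.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class FitFailure(RuntimeError):
    """Raised when a least-squares fit cannot produce a usable estimate.

    Carries the last residual vector (if any) so callers can diagnose
    non-convergence versus degenerate input.
    """

    def __init__(self, message: str, last_residual: np.ndarray | None = None):
        super().__init__(message)
        self.last_residual = last_residual


# ---------------------------------------------------------------------------
# Experimental observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayObservation:
    """One well of the zoospore-ageing infectivity assay."""

    zoospore_age: float  # hours since zoospore release
    infection_pct: float  # percent infected host cells, in [0, 100]
    replicate: int = 1
    temperature: float = float("nan")  # deg C

    def __post_init__(self):
        if self.zoospore_age < 0:
            raise ValueError(f"zoospore_age must be >= 0, got {self.zoospore_age}")
        if not (0.0 <= self.infection_pct <= 100.0):
            raise ValueError(
                f"infection_pct must be in [0, 100], got {self.infection_pct}"
            )


@dataclass(frozen=True)
class RatioObservation:
    """One well of the functional-response assay at a zoospore:host ratio."""

    zoospore_host_ratio: float
    infection_pct: float
    replicate: int = 1
    temperature: float = float("nan")
    strain: str = ""

    def __post_init__(self):
        if self.zoospore_host_ratio <= 0:
            raise ValueError("zoospore_host_ratio must be > 0")
        if not (0.0 <= self.infection_pct <= 100.0):
            raise ValueError(
                f"infection_pct must be in [0, 100], got {self.infection_pct}"
            )


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass
class FourParamLogisticFit:
    """Four-parameter logistic fit of infectivity vs zoospore age.

    The curve is y = d + (a - d) / (1 + exp(b (x - c))): *a* and *d* are the
    upper and lower infection asymptotes (percent), *b* the slope (h^-1) and
    *c* the age (hours) at which infectivity has dropped halfway between the
    asymptotes.
    """

    upper_asymptote_a: float
    lower_asymptote_d: float
    slope_b: float
    midpoint_c: float
    r_squared: float
    param_se: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self):
        if self.midpoint_c <= 0:
            raise ValueError("midpoint_c must be > 0")
        if self.upper_asymptote_a < self.lower_asymptote_d:
            raise ValueError("upper asymptote must be >= lower asymptote")

    def predict(self, age_h):
        age_h = np.asarray(age_h, dtype=float)
        a, d = self.upper_asymptote_a, self.lower_asymptote_d
        return d + (a - d) / (1.0 + np.exp(self.slope_b * (age_h - self.midpoint_c)))


@dataclass
class MortalityFit:
    """Two-parameter exponential decay y = y0 exp(-m t), t in days."""

    initial_level: float  # percent
    mortality_m: float  # d^-1
    r_squared: float
    param_se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.mortality_m < 0:
            raise ValueError("mortality_m must be >= 0")

    def predict(self, t_days):
        return self.initial_level * np.exp(-self.mortality_m * np.asarray(t_days, float))


@dataclass(frozen=True)
class GrowthEstimate:
    """Exponential growth rate between two abundance observations."""

    mu: float  # d^-1
    N1: float
    N2: float
    t1: float
    t2: float


@dataclass
class HollingFit:
    """Type-II functional response fit, y = a x / (1 + a b x).

    ``slope_a`` (percent per ratio unit) is the initial slope / attack rate of
    the disc equation; ``handling_b`` its handling coefficient.
    ``denominator_coef`` = a*b is the raw coefficient of x in the denominator,
    so the fit is recoverable in either textbook convention.
    ``attack_daily`` is the attack rate converted to d^-1 assuming the
    zoospores have ``search_window_T`` hours of searching time per release.
    """

    slope_a: float
    handling_b: float
    attack_daily: float
    search_window_T: float
    r_squared: float
    param_se: dict[str, float] = field(default_factory=dict)
    at_bound: bool = False

    def __post_init__(self):
        if self.slope_a < 0 or self.handling_b < 0:
            raise ValueError("slope_a and handling_b must be >= 0")

    @property
    def denominator_coef(self) -> float:
        return self.slope_a * self.handling_b

    @property
    def asymptote(self) -> float:
        """Saturating infection percentage (1/b), inf when b = 0."""
        return np.inf if self.handling_b == 0 else 1.0 / self.handling_b

    def predict(self, ratio):
        x = np.asarray(ratio, dtype=float)
        return self.slope_a * x / (1.0 + self.slope_a * self.handling_b * x)


@dataclass
class YieldRegression:
    """OLS of zoospore count against late-sporocyte diameter."""

    slope: float  # zoospores per micron
    intercept: float  # zoospores
    r_squared: float
    slope_se: float
    intercept_se: float
    diameters: np.ndarray = field(default_factory=lambda: np.empty(0))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, diameter_um, clip: bool = True):
        y = self.slope * np.asarray(diameter_um, float) + self.intercept
        return np.clip(y, 0.0, None) if clip else y

    @property
    def mean_yield(self) -> float:
        """Average zoospores per infected host (epsilon of the ODE model)."""
        return float(np.mean(self.counts))


# ---------------------------------------------------------------------------
# Simulation types
# ---------------------------------------------------------------------------

STATE_NAMES = ("H1", "H2", "I1", "I2", "P")


@dataclass(frozen=True)
class TemperatureParameterSet:
    """All model parameters for one temperature.

    Attack rates a1/a2 are stored at true per-parasite scale (the printed
    parameter table lists them multiplied by 10^3).
    """

    temperature: float  # deg C
    r1: float  # A. minutum max growth rate, d^-1
    r2: float  # H. triquetra max growth rate, d^-1
    a1: float  # attack rate on host 1, per zoospore d^-1
    a2: float  # attack rate on host 2
    h1: float  # handling (generation) time, days
    h2: float
    eps1: float  # zoospores per infected host 1
    eps2: float
    m: float  # zoospore mortality, d^-1
    K: float  # shared carrying capacity, cells mL^-1

    def __post_init__(self):
        for name in ("r1", "r2", "a1", "a2", "eps1", "eps2", "m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.K <= 0 or self.h1 <= 0 or self.h2 <= 0:
            raise ValueError("K, h1, h2 must be > 0")


@dataclass(frozen=True)
class SystemState:
    """Instantaneous abundances of the five state variables."""

    H1: float
    H2: float
    I1: float
    I2: float
    P: float

    def __post_init__(self):
        for name in STATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.H1, self.H2, self.I1, self.I2, self.P], dtype=float)


@dataclass
class Trajectory:
    """Integrated model output on an output time grid."""

    times: np.ndarray  # days, strictly increasing
    states: np.ndarray  # shape (n_times, 5), columns per STATE_NAMES
    parameters: TemperatureParameterSet
    scenario: str = ""
    clip_events: int = 0  # number of output samples where clipping acted

    def __post_init__(self):
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __getattr__(self, name):
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name)]
        raise AttributeError(name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_days", self.times)
        df.insert(0, "temperature_C", self.parameters.temperature)
        df.insert(0, "scenario", self.scenario)
        return df


@dataclass
class SimulationSummary:
    """Peak abundances and derived ratios for one scenario x temperature."""

    scenario: str
    temperature: float
    max_H1: float
    t_max_H1: float
    max_H2: float
    t_max_H2: float
    max_P: float
    t_max_P: float
    impact_ratio_H1: float = float("nan")  # max with parasitoid / max without
    impact_ratio_H2: float = float("nan")
    dominance_ratio: float = float("nan")  # max_H2 / max_H1

    def to_dict(self) -> dict:
        return dict(self.__dict__)
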