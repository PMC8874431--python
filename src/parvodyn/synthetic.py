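"""Seeded generators emulating the four experiment tables.

Each generator draws from the mean model its downstream fit assumes, with a
noise process mimicking the named measurement:

* infectivity decay: four-parameter logistic mean + Gaussian replicate noise
  on percentages (well-plate scoring scatter), clipped to [0, 100];
* functional response: Holling type-II mean + binomial counting noise
  (n cells scored per well);
* host growth: exponential (optionally logistic) mean + multiplicative
  lognormal counting noise (Sedgewick-Rafter counts);
* zoospore yield: linear diameter -> count mean + Gaussian noise, rounded to
  whole zoospores and floored at 0.

Identical config + seed gives bit-identical tables. Output uses the same
tidy schema as the experiment-table reader, so generated tables round-trip
through the full fit pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fits import holling2, logistic4

__all__ = [
    "GeneratorConfig",
    "DECAY_AGES_H",
    "RATIOS",
    "gen_decay_table",
    "gen_functional_response_table",
    "gen_growth_table",
    "gen_yield_table",
]

# assay schedule: inoculations every 2 h to 10 h, then hourly until motility
# is lost at 20 h
DECAY_AGES_H = tuple(float(a) for a in (0, 2, 4, 6, 8, 10, 11, 12, 13, 14,
                                        15, 16, 17, 18, 19, 20))
# the eight zoospore:host ratios of the plate design
RATIOS = (1.0, 2.0, 3.5, 5.0, 10.0, 20.0, 50.0, 100.0)

TIDY_COLUMNS = ["experiment", "host", "strain", "temperature_C", "x", "y", "replicate"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Declarative description of one synthetic experiment table.

    ``truth`` holds the mean-model parameters for the given ``kind``:

    - decay: a, b, c, d (four-parameter logistic)
    - functional_response: a, b (disc equation)
    - growth: mu, N0 and optionally K (logistic mode), horizon_days
    - yield: slope, intercept plus the diameter-distribution settings

    ``noise`` is the kind-specific level (Gaussian sd in percent for decay,
    cells scored per well for functional_response via ``n_scored``,
    lognormal CV for growth, Gaussian sd in zoospores for yield). Zero noise
    means points lie exactly on the mean model.
    """

    kind: str
    truth: dict = field(default_factory=dict)
    noise: float = 0.0
    n_replicates: int = 3
    design: tuple | None = None  # ages / ratios / days / n sporocytes override
    seed: int = 0
    n_scored: int = 200
    host: str = ""
    strain: str = ""
    temperature: float = float("nan")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _tidy(experiment, cfg, x, y, replicate) -> pd.DataFrame:
    return pd.DataFrame({
        "experiment": experiment,
        "host": cfg.host,
        "strain": cfg.strain,
        "temperature_C": cfg.temperature,
        "x": np.asarray(x, float),
        "y": np.asarray(y, float),
        "replicate": np.asarray(replicate, int),
    })[TIDY_COLUMNS]


def gen_decay_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """Infectivity (percent) vs zoospore age (hours), replicated."""
    if cfg.kind != "decay":
        raise ValueError(f"expected kind 'decay', got {cfg.kind!r}")
    t = cfg.truth
    for k in ("a", "b", "c", "d"):
        if k not in t:
            raise ValueError(f"decay truth missing {k!r}")
    if t["c"] <= 0:
        raise ValueError("decay truth requires midpoint c > 0")
    ages = np.array(cfg.design if cfg.design is not None else DECAY_AGES_H, float)
    rng = cfg.rng()
    xs, ys, reps = [], [], []
    for rep in range(1, cfg.n_replicates + 1):
        mean = logistic4(ages, t["a"], t["b"], t["c"], t["d"])
        y = mean + (rng.normal(0.0, cfg.noise, size=ages.size) if cfg.noise > 0 else 0.0)
        xs.append(ages)
        ys.append(np.clip(y, 0.0, 100.0))
        reps.append(np.full(ages.size, rep))
    return _tidy("decay", cfg, np.concatenate(xs), np.concatenate(ys),
                 np.concatenate(reps))


def gen_functional_response_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """Infection percentage vs zoospore:host ratio with binomial scoring.

    Each well scores ``n_scored`` cells; the infected fraction is
    binomial(n_scored, mean/100) and reported back as a percentage. Noise-free
    mode (noise == 0) returns the exact disc-equation curve.
    """
    if cfg.kind != "functional_response":
        raise ValueError(f"expected kind 'functional_response', got {cfg.kind!r}")
    a, b = cfg.truth["a"], cfg.truth["b"]
    ratios = np.array(cfg.design if cfg.design is not None else RATIOS, float)
    mean = holling2(ratios, a, b)
    p = mean / 100.0
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("truth gives infection probabilities outside [0, 1]")
    rng = cfg.rng()
    xs, ys, reps = [], [], []
    for rep in range(1, cfg.n_replicates + 1):
        if cfg.noise > 0:
            y = rng.binomial(cfg.n_scored, p) * 100.0 / cfg.n_scored
        else:
            y = mean.copy()
        xs.append(ratios)
        ys.append(y)
        reps.append(np.full(ratios.size, rep))
    return _tidy("functional_response", cfg, np.concatenate(xs),
                 np.concatenate(ys), np.concatenate(reps))


def gen_growth_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """Daily cell counts from exponential (or logistic) growth.

    Truth: mu (d^-1), N0 (cells mL^-1, default 500), horizon_days (default
    14) and optionally K to saturate logistically. Noise is a lognormal CV on
    the counts.
    """
    if cfg.kind != "growth":
        raise ValueError(f"expected kind 'growth', got {cfg.kind!r}")
    mu = cfg.truth["mu"]
    N0 = cfg.truth.get("N0", 500.0)
    horizon = cfg.truth.get("horizon_days", 14)
    K = cfg.truth.get("K")
    days = np.array(cfg.design if cfg.design is not None
                    else np.arange(0, horizon + 1), float)
    if K is None:
        mean = N0 * np.exp(mu * days)
    else:
        mean = K / (1.0 + (K / N0 - 1.0) * np.exp(-mu * days))
    rng = cfg.rng()
    xs, ys, reps = [], [], []
    sigma = np.sqrt(np.log1p(cfg.noise**2)) if cfg.noise > 0 else 0.0
    for rep in range(1, cfg.n_replicates + 1):
        if sigma > 0:
            # mean-preserving lognormal multiplier
            y = mean * rng.lognormal(-0.5 * sigma**2, sigma, size=days.size)
        else:
            y = mean.copy()
        xs.append(days)
        ys.append(y)
        reps.append(np.full(days.size, rep))
    return _tidy("growth", cfg, np.concatenate(xs), np.concatenate(ys),
                 np.concatenate(reps))


def gen_yield_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """(diameter um, zoospore count) pairs for burst late sporocytes.

    Truth: slope, intercept of the diameter -> count line, plus the diameter
    distribution: either ``diameter_shift``/``gamma_shape``/``gamma_scale``
    (right-skewed shifted gamma) or ``diameter_low``/``diameter_high``
    (uniform window). 50 sporocytes by default; ``design`` may give an
    explicit diameter array, and truth key ``n`` overrides the sample size.
    Counts are rounded to whole zoospores and floored at 0.
    """
    if cfg.kind != "yield":
        raise ValueError(f"expected kind 'yield', got {cfg.kind!r}")
    t = cfg.truth
    slope, intercept = t["slope"], t["intercept"]
    rng = cfg.rng()
    if cfg.design is not None:
        d = np.asarray(cfg.design, float)
    else:
        n = int(t.get("n", 50))
        if "diameter_low" in t:
            d = rng.uniform(t["diameter_low"], t["diameter_high"], size=n)
        else:
            d = t["diameter_shift"] + rng.gamma(t["gamma_shape"],
                                                t["gamma_scale"], size=n)
    counts = slope * d + intercept
    if cfg.noise > 0:
        counts = counts + rng.normal(0.0, cfg.noise, size=d.size)
        counts = np.maximum(np.rint(counts), 0.0)
    df = _tidy("yield", cfg, d, counts, np.ones(d.size))
    return df.rename(columns={}).assign(
        diameter_um=df["x"], zoospore_count=df["y"]
    )
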