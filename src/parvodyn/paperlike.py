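"""Bundled "paper-like" reconstruction of the experimental study design.

The raw experiment tables behind the published per-temperature parameter
table are not deposited anywhere, so this module ships a clearly labelled
*synthetic reconstruction*: generator configurations whose truths are the
published point estimates where those are printed, and documented
reconstructions where they are not. Running the generators and fitting the
resulting tables rebuilds a parameter table statistically equivalent to the
published one -- it is a demonstration of the pipeline, not data.

Reconstruction choices (all constants below):

* Host-2 (H. triquetra) infectivity half-lives are printed (7.03, 5.31,
  8.93 h at 13/18/22 degC) and used verbatim. Host-1 (A. minutum) half-lives
  are not printed (described only as unimodal with an 18 degC viability
  optimum); the values here keep that shape and are calibrated so the
  grand-average exponential mortality across all six decay curves equals the
  published grand average of 3 d^-1.
* The disc-equation slope per (host, temperature) is inverted from the
  published daily attack rates (a_pct = a_daily * 100 * T / 24, T = 15 h);
  the saturation coefficient b is not printed and is set so infection at the
  50:1 ratio sits near the published ~75% median at the warm optimum.
* Growth-rate truths are the published per-temperature host growth rates.
* Yield truths target the published per-host mean zoospore yields (105 and
  73) with diameter distributions shaped to the published sample ranges.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .params import _TABLE, TEMPERATURES
from .synthetic import (
    GeneratorConfig,
    gen_decay_table,
    gen_functional_response_table,
    gen_growth_table,
    gen_yield_table,
)

HOST1 = "A_minutum"
HOST2 = "H_triquetra"
HOSTS = (HOST1, HOST2)
STRAINS = ("P1", "P2", "P3")  # three parasitoid strains, as in the assays

DECAY_TEMPERATURES = (13.0, 18.0, 22.0)
SEARCH_WINDOW_H = 15.0

# 4PL truths: upper asymptote, slope and the half-infectivity ages (hours).
DECAY_A = 80.0
DECAY_B = 1.2
DECAY_D = 0.0
DECAY_SIGMA_PCT = 4.0
# host-2 midpoints as printed; host-1 midpoints are reconstructions
# (unimodal with the 18 degC viability optimum, infectivity gone by ~13 h)
DECAY_C = {
    (HOST1, 13.0): 6.0,
    (HOST1, 18.0): 7.4,
    (HOST1, 22.0): 5.5,
    (HOST2, 13.0): 7.03,
    (HOST2, 18.0): 5.31,
    (HOST2, 22.0): 8.93,
}

# Published grand-average zoospore mortality. The exponential-decay proxy
# applied to the reconstructed sigmoid curves overestimates it (the real
# replicate curves are unavailable), so paper-like parameter assembly pins m
# to the published average instead of the reconstruction's grand average.
PAPERLIKE_M = 3.0

# disc-equation saturation coefficient (not printed; see module docstring)
HOLLING_B = 0.0115
FR_N_SCORED = 200

GROWTH_N0 = 500.0
GROWTH_HORIZON_D = 14
GROWTH_CV = 0.10

YIELD_TRUTHS = {
    # host 1: right-skewed diameters (published range 64-241, mean 105 +/- 34)
    HOST1: dict(slope=20.0, intercept=-155.0, diameter_shift=11.3,
                gamma_shape=2.0, gamma_scale=0.85, n=50),
    # host 2: symmetric window (published range 47-98, mean 73 +/- 16)
    HOST2: dict(slope=10.0, intercept=-53.0, diameter_low=10.15,
                diameter_high=15.05, n=50),
}
YIELD_SIGMA = {HOST1: 2.0, HOST2: 1.5}


def holling_truth_a(host: str, temperature: float) -> float:
    """Disc-equation slope (percent per ratio unit) inverted from the
    published daily attack rate at this (host, temperature)."""
    i = TEMPERATURES.index(temperature)
    a_daily = _TABLE["a1_e3" if host == HOST1 else "a2_e3"][i]
    return a_daily * 100.0 * SEARCH_WINDOW_H / 24.0


def growth_truth_mu(host: str, temperature: float) -> float:
    i = TEMPERATURES.index(temperature)
    return _TABLE["r1" if host == HOST1 else "r2"][i]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def paperlike_configs(seed: int = 0, noisy: bool = True) -> list[GeneratorConfig]:
    """Generator configs for the full reconstructed study design."""
    cfgs: list[GeneratorConfig] = []
    n_needed = (len(DECAY_C) + len(HOSTS) * len(TEMPERATURES) * (len(STRAINS) + 1)
                + len(HOSTS))
    seeds = iter(_spawn_seeds(seed, n_needed))
    for (host, T), c in DECAY_C.items():
        cfgs.append(GeneratorConfig(
            kind="decay",
            truth=dict(a=DECAY_A, b=DECAY_B, c=c, d=DECAY_D),
            noise=DECAY_SIGMA_PCT if noisy else 0.0,
            seed=next(seeds), host=host, strain=STRAINS[1], temperature=T,
        ))
    for host in HOSTS:
        for T in TEMPERATURES:
            for strain in STRAINS:
                cfgs.append(GeneratorConfig(
                    kind="functional_response",
                    truth=dict(a=holling_truth_a(host, T), b=HOLLING_B),
                    noise=1.0 if noisy else 0.0,
                    n_scored=FR_N_SCORED,
                    seed=next(seeds), host=host, strain=strain, temperature=T,
                ))
            cfgs.append(GeneratorConfig(
                kind="growth",
                truth=dict(mu=growth_truth_mu(host, T), N0=GROWTH_N0,
                           horizon_days=GROWTH_HORIZON_D),
                noise=GROWTH_CV if noisy else 0.0,
                seed=next(seeds), host=host, temperature=T,
            ))
    for host in HOSTS:
        cfgs.append(GeneratorConfig(
            kind="yield",
            truth=YIELD_TRUTHS[host],
            noise=YIELD_SIGMA[host] if noisy else 0.0,
            seed=next(seeds), host=host, temperature=20.0,
        ))
    return cfgs


_GENERATORS = {
    "decay": gen_decay_table,
    "functional_response": gen_functional_response_table,
    "growth": gen_growth_table,
    "yield": gen_yield_table,
}


def generate_paperlike_tables(seed: int = 0, noisy: bool = True) -> pd.DataFrame:
    """One tidy table holding every reconstructed experiment."""
    frames = [_GENERATORS[c.kind](c) for c in paperlike_configs(seed, noisy)]
    cols = frames[0].columns.intersection(frames[-1].columns)
    return pd.concat([f[cols] for f in frames], ignore_index=True)
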