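# parvodyn

Temperature-resolved host–parasitoid dynamics of the generalist zoosporic
parasitoid *Parvilucifera rostrata* infecting two bloom-forming
dinoflagellates, *Alexandrium minutum* and *Heterocapsa triquetra*.

Harmful-algal-bloom dinoflagellates are attacked by unicellular parasitoids
whose free-swimming zoospores infect host cells, mature inside them and
release hundreds of new zoospores. Whether the parasitoid controls a bloom
depends on temperature twice over: through the hosts' growth rates and
through the parasitoid's infectivity. This package is for plankton
ecologists and modellers who want to go from plate-assay tables to
bloom-scale predictions: it fits the experimental curves that define the
parasitoid's thermal performance and feeds them into a five-state
differential-equation model of two competing hosts under infection.

## What it computes

**Fits** (`parvodyn.fits`), per host × strain × temperature:

- zoospore infectivity vs age: four-parameter logistic
  `y = d + (a−d)/(1+e^{b(x−c)})`; the midpoint `c` is the age (h) at which
  infectivity has halved;
- zoospore mortality `m` (d⁻¹): exponential decay `y = y₀e^{−mt}` using
  infectivity loss as a viability proxy;
- host growth `μ = ln(N₂/N₁)/(t₂−t₁)` (d⁻¹);
- Holling type-II functional response `y = ax/(1+abx)` over zoospore:host
  ratios, with the attack rate made daily via `a′ = (a/100)(24/T)`,
  `T = 15 h` of post-release searching time;
- zoospore yield ε: OLS of zoospores released on sporocyte diameter.

**Dynamics** (`parvodyn.dynamics`), for each temperature in
{13, 15, 18, 20, 22} °C:

    dH_i/dt = r_i H_i (K − H₁ − H₂)/K − a_i H_i P/(1 + a_i h_i H_i)
    dI_i/dt = a_i H_i P/(1 + a_i h_i H_i) − I_i/h_i
    dP/dt   = ε₁I₁/h₁ + ε₂I₂/h₂ − Σ_i a_i H_i P/(1 + a_i h_i H_i) − mP

integrated with a stiff-capable adaptive solver over six scenarios (each
host alone, both together, each ± parasitoid inoculum), with peak
abundances, thermal optima and with/without-parasitoid impact ratios as
summaries.

**Synthetic data** (`parvodyn.synthetic`): seeded generators emulating all
four experiment tables, so every fitter is validated by parameter recovery;
a bundled "paper-like" configuration (`parvodyn.paperlike`) reconstructs
the full study design from published point estimates.

## Worked example

```python
import numpy as np
from parvodyn import (GeneratorConfig, gen_decay_table,
                      fit_four_param_logistic, infectivity_half_time,
                      default_parameter_table, initial_state, simulate,
                      summarize)

# recover a zoospore infectivity half-life from a synthetic ageing assay
cfg = GeneratorConfig(kind="decay", truth=dict(a=80, b=1.2, c=5.31, d=0),
                      noise=4.0, seed=1)
fit = fit_four_param_logistic(gen_decay_table(cfg))
print(f"half-life {infectivity_half_time(fit):.2f} h, R2 {fit.r_squared:.3f}")

# epidemic at 18 degC: both hosts + 2000 zoospores/mL vs parasitoid-free
p18 = default_parameter_table()[2]
base = simulate(initial_state(True, True, False), p18, horizon=30)
wp = simulate(initial_state(True, True, True), p18, horizon=30)
s = summarize(wp, base)
print(f"host2 peak {s.max_H2:.0f} cells/mL on day {s.t_max_H2:.1f}; "
      f"impact ratios {s.impact_ratio_H1:.2f}, {s.impact_ratio_H2:.2f}")
```

prints

```
half-life 5.21 h, R2 0.994
host2 peak 2074 cells/mL on day 2.4; impact ratios 0.20, 0.06
```

The fitted half-life lands within 2% of the configured 5.31 h truth. At
18 °C — where attack rates are near their maximum — the parasitoid caps
*H. triquetra* at ~2100 cells mL⁻¹, 6% of its parasitoid-free peak; run
the same comparison at 13 °C and the ratios rise to ~0.75–0.81, the cold
thermal refuge.

## The analysis

Numbered drivers under `analysis/` rebuild the study end to end, writing
tables under `results/`:

```
python analysis/01_generate_experiments.py   # synthetic experiment tables
python analysis/02_fit_experiments.py        # all curve fits
python analysis/03_build_parameter_table.py  # per-temperature model inputs
python analysis/04_simulate_grid.py          # 6 scenarios x 5 temperatures
python analysis/05_thermal_refuge_summary.py # headline metrics
```

The same workflow is available as a CLI (`parvodyn generate | fit |
simulate | reproduce-paper | report`). `docs/methods.md` documents the
model, assumptions, noise models and numerical choices.

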