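# Methods

`parvodyn` models the biological control of two bloom-forming estuarine
dinoflagellates — *Alexandrium minutum* (host 1) and *Heterocapsa triquetra*
(host 2) — by the generalist zoosporic parasitoid *Parvilucifera rostrata*,
across the 13–22 °C range typical of the bloom season. It has two halves:
curve fits that extract biological rates from four kinds of experiment
table, and a five-state differential-equation model that combines those
rates into bloom-scale predictions on a five-temperature grid.

## Experiment fits

**Infectivity decay (4PL).** Zoospores lose infectivity as they age. The
assay inoculates host plates with zoospores of increasing age (2-hourly to
10 h, then hourly to 20 h, three replicates) and scores percent infected
cells. The mean curve is a four-parameter logistic
`y = d + (a − d) / (1 + exp(b (x − c)))` with upper/lower asymptotes `a`,
`d` (%), slope `b` (h⁻¹) and midpoint `c` (h) — the zoospore age at which
infectivity has fallen halfway. Fitting is pooled nonlinear least squares
(Levenberg–Marquardt via lmfit), seeded with `a ← max(y)`, `d ← min(y)`,
`c ←` the age whose response is nearest `(a+d)/2`, `b ← 1`, with up to five
deterministically jittered restarts; flat series and series with fewer than
five distinct ages raise an explicit fit failure rather than returning a
spurious midpoint. A per-replicate variant reproduces mean ± SE spreads.

**Zoospore mortality.** Direct survival of the swimming stage is not
observable, so the same decay series stands in as a viability proxy, fitted
to `y = y₀ exp(−m t)` with ages converted to days first so `m` is natively
d⁻¹. On noise-free exponential data this agrees with log-linear OLS to
better than 1e−8 (tested). Increasing or all-zero series fail explicitly.

**Host growth.** Exponential growth between consecutive counts,
`μ = ln(N₂/N₁)/(t₂−t₁)` (d⁻¹). For whole series the pipeline uses OLS of
log-count on time, which pools the day-over-day estimates and is the
maximum-likelihood estimate under the generator's lognormal counting noise.

**Functional response (Holling type II).** Infection percentage versus
zoospore:host ratio x over the plate design 1, 2, 3.5, 5, 10, 20, 50, 100,
fitted to the disc equation written canonically as
`y = a·x / (1 + a·b·x)`, `a, b ≥ 0`: `a` is the attack rate (initial slope,
% per ratio unit) and `b` the handling coefficient, so the saturating
infection level is `1/b`. The raw denominator coefficient `a·b` is also
exposed, because the literature writes the same curve both as `1 + abx` and
as `1 + bx`; either convention is recoverable from the fit object. The
attack rate converts to a daily rate as `a′ = (a/100)·(24/T)` with
`T = 15 h`, the window after release within which zoospores can still
establish infections. `b` from this fit is *not* used as the dynamic
model's handling time (below): these single-cycle plate assays measure only
the time to infect, not the full infection-to-release cycle.

**Zoospore yield.** Ordinary least squares of zoospores released per burst
sporocyte on sporocyte diameter (µm); predictions are clipped at zero for
reporting only, never during fitting. The per-host mean count is the yield
ε used by the dynamic model.

`r_squared` for all nonlinear fits is `1 − SS_res/SS_tot` with `SS_tot`
about the pooled mean (the convention is not universal for nonlinear
models; this is the one used throughout).

## The five-state model

States (cells mL⁻¹): uninfected hosts H₁, H₂; infected hosts I₁, I₂; free
zoospores P.

    dH_i/dt = r_i H_i (K − H₁ − H₂)/K − f_i(H_i) P
    dI_i/dt = f_i(H_i) P − I_i / h_i
    dP/dt   = ε₁ I₁/h₁ + ε₂ I₂/h₂ − f₁(H₁) P − f₂(H₂) P − m P

with the type-II per-zoospore infection rate
`f_i(H) = a_i H / (1 + a_i h_i H)`. Parameters per temperature: host growth
rates r₁, r₂ (d⁻¹); per-parasite attack rates a₁, a₂ (stored at true scale;
the published table prints them ×10³ and the CSV reader applies the ×10⁻³
conversion explicitly); handling time h = the full infection-to-release
generation time (5, 5, 4, 4, 3 d at 13/15/18/20/22 °C, shared by both
hosts); yields ε₁ = 105, ε₂ = 74 zoospores per infected host; zoospore
mortality m = 3 d⁻¹ (grand average); carrying capacity K = 40,000
cells mL⁻¹ shared by the two hosts.

Modelling assumptions worth making explicit:

- Only uninfected hosts occupy carrying capacity (infected cells lose
  motility and sink out of the competitive pool), so total biomass can
  transiently exceed K.
- Zoospore release is continuous at rate ε_i I_i/h_i rather than pulsed at
  sporocyte maturity.
- One unsubscripted attack-rate symbol in the source equations is resolved
  as a₁ by symmetry.
- Two published inconsistencies are resolved, both configurably: K appears
  as both 45,000 (text) and 40,000 (parameter table); the table value is
  the default. The host-2 yield appears as 7494 at 13 °C against 74
  elsewhere and a measured mean of 73 ± 16; 7494 is treated as a
  typographical artifact.

**Integration.** `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
rtol 1e−8, atol 1e−6 cells mL⁻¹, states clipped to zero inside the
derivative so tiny negative excursions cannot feed back; outputs on a
0.05-d grid are clipped at zero and clip events are counted in the run log.
Excursions beyond −100·atol raise. Halving the tolerances moves 30-day
endpoints by < 0.01% of the state scale (tested), and the parasite-free
submodel matches an independently coded two-species logistic-competition
integrator to < 1e−6 relative error.

**Scenarios and horizons.** Six scenarios: each host alone, both together,
each composition ± parasitoid, initialized at 1000 cells mL⁻¹ per host
present and 2000 zoospores mL⁻¹ when the parasitoid is present. Growth-only
scenarios run 14 d, matching the growth experiment. With-parasitoid
scenarios run 30 d: the epidemic peaks by ~12 d and burns out by ~25 d at
every temperature, while at warm temperatures the hosts crash to
numerically-zero densities and would later *regrow from sub-cell remnants*
— the classic "atto-cell" artifact of continuous-state models. A 30-day
window reports the epidemic bloom peak; windows beyond ~37 d would instead
report the artifact regrowth. Both horizons are configurable.

**Summaries.** Per-scenario peak abundances and times; with/without impact
ratio per host (peaks compared over the *same* horizon, using a
parasitoid-free reference run written alongside the epidemic run so every
summary number is recomputable from the trajectory CSV); H₂/H₁ dominance
ratio; grid optima reported as the full argmax set with the lowest
temperature as the single representative (bloom optima are often ranges).
With the bundled parameter table the grid reproduces the study's headline
pattern: growth-only optima at 18 °C (host 2) and the warm end (host 1),
strongest competitive suppression of host 1 at 18 °C, with-parasitoid
maxima shifted to ≤ 15 °C for both hosts (the cold thermal refuge, where
attack rates are an order of magnitude lower), and bloom peaks cut to
roughly one-third (grid mean impact ratio ≈ 0.26 for both-hosts scenarios,
≈ 0.29 for single-host scenarios).

In the two-host scenarios the impact ratio can exceed what "parasitism only
removes hosts" suggests: killing the stronger competitor releases the
weaker one (at 13 °C host 2's ratio is ~0.8–0.97 because infection of host
1 frees carrying capacity). The per-host "with ≤ without" bound is exact
only in single-host scenarios, and is tested there.

## Synthetic data

No raw assay tables are deposited, so the generators in
`parvodyn.synthetic` emulate each experiment's design and a measurement
noise process chosen to mimic the named assay (noise models are not
described in the source study — only replicate counts are):

- decay: the assay age schedule × 3 replicates, Gaussian noise on
  percentages (default σ = 4%), clipped to [0, 100];
- functional response: the 8 plate ratios × 3 replicates, binomial scoring
  of n = 200 cells per well;
- growth: daily counts from 500 cells mL⁻¹ over 14 d, mean-preserving
  lognormal counting noise (default CV 10%), optional logistic saturation;
- yield: 50 sporocytes, linear diameter→count mean plus Gaussian noise
  (counts rounded, floored at 0). Host-1 diameters follow a right-skewed
  shifted gamma and host-2 a uniform window, shaped to the published sample
  envelopes (64–241 around mean 105; 47–98 around mean 73). The host-1
  sample SD (~24) is deliberately below the published 34 so that 50-draw
  samples respect the published range.

Identical config + seed gives bit-identical tables. The bundled
"paper-like" configuration (`parvodyn.paperlike`) is a clearly labelled
*reconstruction*, not data: truths are the published point estimates where
printed (host-2 half-lives 7.03/5.31/8.93 h; growth rates; attack rates
inverted through the daily-rate conversion; yields 105/73) and documented
choices where not (host-1 half-lives unimodal with an 18 °C optimum; disc
saturation b = 0.0115, placing warm-optimum infection at the 50:1 ratio
near the published ~75% median). Fitting the noise-free reconstruction
reproduces the published parameter table to numerical precision for r and
a; yields agree statistically (random diameters). The published grand
average mortality (3 d⁻¹) cannot be recovered from any plausible
reconstruction — the printed host-2 half-lives alone force
exponential-proxy mortalities averaging ~3.9 d⁻¹, and pushing the average
down to 3 would require host-1 mortalities below the published minimum —
so paper-like parameter assembly pins m = 3 as a published constant, the
same way it takes h and K; the mortality fits themselves are still
computed, reported and tested.

What passing the recovery suites shows — and does not. Over 100 seeds at
the documented noise, the 4PL midpoint and the Holling attack slope are
recovered with median relative error ≈ 1–4% (< 10% asserted). That
demonstrates the estimators are unbiased and well-powered *under the
assumed noise processes and design*; real plate data with
replicate-to-replicate variance components, counting biases or model
misspecification could behave worse, and nothing here validates the noise
models themselves.

## Numerical choices and degenerate inputs

- 4PL: if the optimizer lands with the asymptotes inverted, a/d are
  relabelled (and b negated) so `a` is always the upper asymptote.
- Holling: parameters are bounded at zero; an optimum at the bound is
  flagged `at_bound` rather than silently accepted.
- Mortality: fitted m within −1e−10 of zero is truncated to exactly 0
  (constant series); genuinely increasing series fail.
- Impact ratio of an absent host is NaN, of an extinct host 0.
- Grid optima: ties within 1e−9 relative are reported as a set.

## Problem sizes

The full analysis (generate → fit → assemble → 6 × 5 grid) runs in a few
seconds; the recovery suites fit 200 synthetic tables in under two
seconds. These sizes follow the actual study design (three replicates,
five temperatures, 30-day epidemics) — nothing is scaled down from it.

## Limitations

- The model has no nutrient dynamics, irradiance, spatial structure,
  turbulence, zoospore age structure within a release cohort, or dormant
  sporocyte stages; it describes one epidemic wave over one bloom season.
- Temperature enters only through the fitted per-temperature parameters;
  there is no interpolation between grid temperatures.
- The "one-third" impact figure depends on the epidemic horizon (see
  above); it is reported for the 30-day window.
- Rank-based group comparisons are thin wrappers over scipy
  (Kruskal–Wallis, Mann–Whitney); no post-hoc Dunn test is provided.
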