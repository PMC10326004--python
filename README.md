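# bacips

Bayesian shared-frailty survival models and BACIPS effect statistics for
telemetry-monitored wildlife populations exposed to large disturbances.

The package was built around a concrete problem: quantifying the immediate
effect of two large wildfires on the demography of a greater sage-grouse
(*Centrocercus urophasianus*) population monitored by VHF telemetry for 12
years. Because fires strike part of a landscape part-way through a
monitoring series, a naive before/after or inside/outside contrast
confounds the fire effect with pre-existing spatial heterogeneity and
shared temporal trends. The Before-After Control-Impact Paired Series
(BACIPS) design crosses both axes — every nest and every bird-month is
classified before-control (BC), before-impact (BI), after-control (AC) or
after-impact (AI) by overlaying locations with the fire perimeters in space
and the ignition dates in time — and the effect of interest is the change
in the impact:control survival ratio from before to after.

## Models

**Nest survival** — a discrete-time shared-frailty hazard model. Nest *i*
of female *b* in group *g* has daily unit hazard

    UH_i = exp(alpha_g + beta_c + gamma_b),    gamma_b ~ N(0, sigma_gamma)

with survival exp(−d·UH) over d days and cumulative survival reported over
the 37-day laying-plus-incubation window. Fates enter through the standard
known-fate encounter-history likelihood (survive found→last-active, fail
within the closing 3-day visit interval; quick failures keep one assumed
day of survival).

**Adult survival** — the same frailty structure observed at monthly
intervals with time-varying covariates: group log-hazard
`mu + tau·I(impact) + rho·I(after) + delta·I(impact·after)` (the
interaction `delta` is the wildfire effect), sum-to-zero calendar-month
effects, and a yearling offset with graduation to adult on 1 March. Months
without relocations have an unknown group, treated as a latent categorical
parameter with a month-by-group probability-weight prior (pi) estimated
from the observed months and sampled by Gibbs inside the MCMC.

**Effect statistics** — computed per posterior draw and summarized by
median and 95% credible interval: period ratios S_impact/S_control, the
BACIPS ratio R_after/R_before, CI-contribution
|S_AI−S_BI| − |S_AC−S_BC|, CI-divergence |S_AI−S_AC| − |S_BI−S_BC|, and
the posterior mass of the BACIPS ratio below 1.

**Sampling** — an adaptive random-walk Metropolis engine with vectorized
conditionally-independent frailty updates (non-centered), Gibbs imputation
of latent groups, Gelman-Rubin diagnostics (R-hat < 1.1 criterion), and a
grid-quadrature oracle used to validate posteriors on low-dimensional
models. A single seed makes every run bit-reproducible.

**Synthetic data** — a generator that emulates the motivating study's
structure (178 marked females, two mid-study fires, seasonal relocation
effort with winter sparsity, 3-day nest checks, collar-loss censoring)
with ground truth stored for recovery testing. Its defaults reproduce the
study's sample composition: nests split ≈31/44/18/16 and relocations
≈32/35/23/10% across the four groups.

## Worked example

```python
import numpy as np
from bacips import (
    SamplerConfig, build_nest_records, default_study_config,
    derive_group_survival, fit_nest_model, simulate_scenario,
)

config = default_study_config(seed=1)
dataset = simulate_scenario(config)                      # 178 birds, 2 fires
records = build_nest_records(dataset.nests, config.fires)
chains = fit_nest_model(records, SamplerConfig(
    n_chains=3, n_iterations=8000, burn_in=3000, thin=2, seed=11))
for group, draws in derive_group_survival(chains).items():   # T = 37 days
    lo, med, hi = np.percentile(draws, [2.5, 50, 97.5])
    print(f"{group.name}: {med:.3f} ({lo:.3f}-{hi:.3f})")
```

which prints one line per BACIPS group (the scenario's generating truths
were 0.16, 0.19, 0.19 and 0.05):

```
BC: 0.107 (0.036-0.221)
BI: 0.263 (0.139-0.428)
AC: 0.284 (0.108-0.527)
AI: 0.177 (0.013-0.564)
```

Every 95% credible interval covers its generating truth. With only ~110
nests split across four groups the intervals are wide — the after-impact
interval widest of all, since that group holds the fewest nests — which is
exactly why the effect statistics below work with full posteriors rather
than point estimates. The
`examples/` directory walks through the full pipeline: simulating a study,
fitting both models, and deriving the effect statistics — e.g. plugging the
published adult survival medians (0.79, 0.71, 0.77, 0.42) into the effect
layer gives a BACIPS ratio of 0.6069, i.e. a ~40% relative drop in adult
survival inside burned areas.

A thin CLI mirrors the pipeline for shell use:

```
bacips simulate --seed 7 --out data/
bacips fit-nest  --nests data/nests.csv --fires data/fires.geojson --seed 1 --out fit/
bacips fit-adult --telemetry data/telemetry.csv --fires data/fires.geojson \
                 --birds data/birds.csv --seed 1 --out fit-adult/
bacips bacips    --chains fit-adult/chains.csv --model adult --out effects/
bacips report    --results .
```

Every stage writes a `manifest.json` (seed, config, input digests, R-hat
table) sufficient to reproduce it exactly.

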