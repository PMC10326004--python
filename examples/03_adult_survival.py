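"""Fit the adult monthly survival model with latent-group imputation.

Builds monthly encounter histories from telemetry (decision-tree group
resolution, missing winter months), estimates the month-by-group
probability-weight matrix pi, fits the shared-frailty hazard model with
Gibbs imputation of missing BACIPS groups, and prints annual survival per
group.
"""

import datetime as dt

import numpy as np

from bacips import (
    Location,
    SamplerConfig,
    build_adult_histories,
    default_study_config,
    derive_annual_survival,
    estimate_pi,
    fit_adult_model,
    simulate_scenario,
)
from bacips.adult import ADULT_STRUCTURAL
from bacips.grouping import BacipsGroup

config = default_study_config(seed=1)
dataset = simulate_scenario(config)

locations = [
    Location(r.bird_id, dt.date.fromisoformat(r.date), r.x, r.y, r.status)
    for r in dataset.telemetry.itertuples()
]
ages = dict(zip(dataset.birds.bird_id, dataset.birds.age_at_capture))
histories = build_adult_histories(
    locations, config.fires, config.study_months, capture_ages=ages
)
n_months = sum(len(h.months) for h in histories)
n_missing = sum(1 for h in histories for m in h.months if m.group is None)
print(f"{len(histories)} birds, {n_months} bird-months, "
      f"{n_missing} with missing group ({100 * n_missing / n_months:.0f}%)")

pi = estimate_pi(histories, config.study_months)
sampler = SamplerConfig(n_chains=3, n_iterations=9000, burn_in=3000, thin=3, seed=5)
chains = fit_adult_model(histories, pi, sampler, config.study_months)

rhat = chains.rhat_table(ADULT_STRUCTURAL)
print(f"max R-hat over monitored parameters: {max(rhat.values()):.3f} (target < 1.1)")

print("\ngroup   truth   posterior median   95% CRI")
for g in BacipsGroup:
    draws = derive_annual_survival(chains, g)
    lo, med, hi = np.percentile(draws, [2.5, 50, 97.5])
    truth = config.true_adult_annual_survival[g - 1]
    print(f"{g.name:>5}   {truth:.2f}    {med:15.3f}   ({lo:.3f}-{hi:.3f})")

print(
    "\nMissing winter months are imputed from the pi matrix inside the "
    "sampler; the marked drop in the after-impact group is the simulated "
    "wildfire effect."
)
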