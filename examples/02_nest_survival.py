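"""Fit the nest shared-frailty model and report 37-day survival per group.

Simulates a study, builds nest encounter records, runs the MCMC fit, checks
convergence, and prints posterior medians with 95% credible intervals of
cumulative 37-day nest survival for each BACIPS group.
"""

import numpy as np

from bacips import (
    SamplerConfig,
    build_nest_records,
    default_study_config,
    derive_group_survival,
    fit_nest_model,
    simulate_scenario,
)
from bacips.nest import _STRUCTURAL

config = default_study_config(seed=1)
dataset = simulate_scenario(config)
records = build_nest_records(dataset.nests, config.fires)
print(f"fitting {len(records)} nests from {len({r.bird_id for r in records})} females")

sampler = SamplerConfig(n_chains=3, n_iterations=8000, burn_in=3000, thin=2, seed=11)
chains = fit_nest_model(records, sampler)

rhat = chains.rhat_table(_STRUCTURAL)
print(f"max R-hat over monitored parameters: {max(rhat.values()):.3f} (target < 1.1)")

survival = derive_group_survival(chains)  # T = 37 days
print("\ngroup   truth   posterior median   95% CRI")
for g, draws in survival.items():
    lo, med, hi = np.percentile(draws, [2.5, 50, 97.5])
    truth = config.true_nest_survival_37d[g - 1]
    print(f"{g.name:>5}   {truth:.2f}    {med:15.3f}   ({lo:.3f}-{hi:.3f})")

print(
    "\nEach 95% interval should usually cover the generating truth. With "
    "~110 nests split across four groups the intervals are wide — widest "
    "for the after-impact group, which holds the fewest nests — so wildfire "
    "inference rests on the full posteriors, not the point estimates."
)
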