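"""Generate a synthetic wildfire telemetry study and inspect its structure.

Builds the default scenario — 178 radio-marked female sage-grouse tracked
2008-2019 around two large wildfires — and tabulates how nests and
relocations fall across the four BACIPS groups (before/after x
control/impact).
"""

import collections
import datetime as dt

from bacips import (
    Location,
    assign_group,
    build_nest_records,
    default_study_config,
    simulate_scenario,
)

config = default_study_config(seed=1)
dataset = simulate_scenario(config)

print(f"birds: {config.n_birds}")
print(f"relocations: {len(dataset.telemetry)}")
print(f"nests found: {len(dataset.nests)}")

nest_counts = collections.Counter(
    r.group.name for r in build_nest_records(dataset.nests, config.fires)
)
reloc_counts = collections.Counter()
for row in dataset.telemetry.itertuples():
    loc = Location(row.bird_id, dt.date.fromisoformat(row.date), row.x, row.y)
    reloc_counts[assign_group(loc, config.fires).name] += 1

n = sum(reloc_counts.values())
print("\ngroup     nests   relocation share")
for g in ("BC", "BI", "AC", "AI"):
    print(f"{g:>6} {nest_counts[g]:>8} {100 * reloc_counts[g] / n:>12.1f}%")

print(
    "\nThe scenario reproduces the field study's sample structure: most "
    "relocations fall in the before period, and the after-impact group is "
    "the smallest because post-fire mortality thins it."
)
print(f"\ntrue adult BACIPS ratio built into the scenario: "
      f"{dataset.truth.bacips_ratio_adult:.4f}")
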