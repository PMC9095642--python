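"""Generate the synthetic trial cohort and registry pool and summarize it."""

import numpy as np

from glycotrial import CohortConfig, generate_cohort, generate_registry

config = CohortConfig(seed=42)
participants, series = generate_cohort(config)
registry = generate_registry(config)

male = np.mean([p.sex == "male" for p in participants])
age = np.mean([p.age for p in participants])
hba1c = np.mean([p.baseline_hba1c for p in participants])
mod = np.mean([p.mod for p in participants])
dropped = sum(p.dropped_out for p in participants)

print(f"participants: {len(participants)}  registry pool: {len(registry)}")
print(f"male {100 * male:.1f}%  mean age {age:.1f} y  mean baseline HbA1c {hba1c:.1f} mmol/mol")
print(f"MOD subgroup {100 * mod:.0f}%  dropouts during randomization {dropped}")
print("-> baseline marginals track the configured trial population; every")
print("   downstream analysis runs on this fully known ground truth.")
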