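"""Match registry controls and estimate the propensity-weighted contrast."""

import numpy as np

from glycotrial import (
    CohortConfig,
    estimate_propensity,
    generate_cohort,
    generate_registry,
    ipw_weights,
    match_controls,
    weighted_group_difference,
)
from glycotrial.io import participants_frame, registry_frame

config = CohortConfig(n_participants=200, n_registry=2000, seed=8,
                      med_change_rate=0.0)
participants, series = generate_cohort(config)
registry = generate_registry(config)

pf = participants_frame(participants)
active = pf[~pf["dropped_out"]]
match = match_controls(active, registry_frame(registry), ratio=2, seed=8)
print("covariate balance (standardized mean difference):")
print(match.balance.to_string(index=False))
print("-> matching on sex plus Mahalanobis distance pulls every covariate")
print("   SMD toward zero; each participant has exactly two controls.")

# propensity-weighted biweekly-users vs non-users HbA1c contrast
rows = [(s.visits[-1].hba1c - s.visits[0].hba1c, p.usage_class == "biweekly",
         p.age, p.bmi, p.baseline_hba1c)
        for p, s in zip(participants, series)
        if not p.dropped_out and p.usage_class in ("biweekly", "nonuser")]
arr = np.array(rows, float)
y, g, X = arr[:, 0], arr[:, 1].astype(bool), arr[:, 2:]
fit = estimate_propensity(X, g, max_trees=300, n_grid=6, cv_folds=2, seed=8)
w = ipw_weights("user_vs_nonuser", fit.probabilities, g)
res = weighted_group_difference(y, g, w)
print(f"weighted HbA1c contrast {res.estimate:.2f} mmol/mol "
      f"(95% CI {res.ci[0]:.2f} to {res.ci[1]:.2f}), {fit.n_trees} trees")
print("-> inverse-probability weights make frequent users comparable to")
print("   non-users; the generator truth for this contrast is -6.5.")
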