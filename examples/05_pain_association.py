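"""Pain statistics on a synthetic cohort: 72-h trend and association.

Generates default pain trajectories (12 cycles at 6-h spacing, post-NRS
mean declining 0.14 per 6 h from 3.0) for 25 subjects, fits the OLS
trend, and tests the null association between per-subject improvement
and an (independent) temperature-drop covariate.
"""

import dataclasses

import numpy as np

from cryodepth import (
    GeneratorParams,
    generate_cohort,
    generate_pain_records,
    nrs_trend,
    pearson_association,
)

params = dataclasses.replace(GeneratorParams(), n_subjects=25)
subjects, _ = generate_cohort(params, seed=1)
records = [r for s in subjects for r in generate_pain_records(s, params, seed=1)]

trend = nrs_trend(records)
print(f"post-treatment NRS trend: {trend.estimate:+.3f} per 6 h "
      f"(95% CI {trend.ci_low:+.3f} to {trend.ci_high:+.3f}, p = {trend.p_value:.2e}, "
      f"n = {trend.n} cycles)")

rng = np.random.default_rng(1)
drops = rng.normal(10.0, 3.0, len(subjects))  # degC, independent of pain by design
x = []
for s, d in zip(subjects, drops):
    recs = generate_pain_records(s, params, seed=1, simulated_temp_drop=d)
    x.append(np.mean([r.nrs_pre - r.nrs_post for r in recs]))
assoc = pearson_association(x, drops)
print(f"improvement vs temperature drop: r = {assoc.estimate:+.3f} "
      f"(95% CI {assoc.ci_low:+.3f} to {assoc.ci_high:+.3f}, p = {assoc.p_value:.2f}, "
      f"n = {assoc.n} subjects)")
print("\nThe negative trend reflects resolving postoperative pain; with no"
      "\ninjected effect the association CI covers zero, as it should.")
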