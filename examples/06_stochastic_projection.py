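"""Stochastic projection: worst-ten vs best-ten site matrix sets.

Each year of each replicate draws one matrix uniformly from the set (every
site-year of the ten worst or ten best sites), so both spatial and temporal
survival variation propagate into the projected population sizes.
"""

import dataclasses

import numpy as np

from sealpup import (
    DemographyParams,
    build_matrix_sets,
    default_initial_vector,
    estimate_late_survival,
    generate,
    overall_mean_survival,
    pembrokeshire_design,
    stochastic_growth_rate,
    stochastic_project,
)

dataset = generate(pembrokeshire_design(seed=42))
params = dataclasses.replace(
    DemographyParams(),
    s_late=estimate_late_survival(0.48, overall_mean_survival(dataset)),
)
sets = build_matrix_sets(dataset, params)
n0 = default_initial_vector()
print(f"initial vector: {n0.sum():.0f} females (575 pups / 1724 sub-adults / 576 adults)")

for which in ("worst_site_years", "best_site_years"):
    res = stochastic_project(sets[which], n0, years=20, reps=1000, seed=7,
                             compute_growth=False)
    q = np.percentile(res.total_size[:, -1], [2.5, 50, 97.5])
    log_ls = stochastic_growth_rate(sets[which], n0, reps=100, seed=7)
    print(
        f"{which:16s}: year-20 size median {q[1]:8.0f} "
        f"(95% band {q[0]:.0f}-{q[2]:.0f}), log lambda_s = {log_ls:+.4f}"
    )
# log lambda_s > 0 means long-run stochastic growth. The gap between the
# worst-ten and best-ten sets is the cost of monitoring unrepresentative
# sites: the same population looks near-stationary or booming.
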