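"""How fragile is the overall mean to site choice and sample size?"""

from sealpup import (
    generate,
    loo_site_sensitivity,
    pembrokeshire_design,
    required_n,
    sample_size_curve,
    sensitivity_models,
    subset_years_all_areas,
)

dataset = generate(pembrokeshire_design(seed=42))

# leave-one-site-out, on the years in which all three areas are represented
subset = subset_years_all_areas(dataset)
sens = loo_site_sensitivity(subset)
deltas = sorted(sens, key=lambda r: r.delta)
print(f"sensitivity over {len(sens)} sites:")
print(f"  strongest downward pull : {deltas[-1].site_id} ({deltas[-1].delta:+.4f})")
print(f"  strongest upward pull   : {deltas[0].site_id} ({deltas[0].delta:+.4f})")
# delta = mean without the site minus mean with it; a positive delta means
# that site was dragging the overall estimate down.

fits = sensitivity_models(sens)
for fit in fits.values():
    print(f"  {fit.model:18s}: F({fit.df1},{fit.df2}) = {fit.F:.3f}, p = {fit.p_value:.4f}")

# bootstrap sample-size requirement: how many site-year estimates until the
# sample mean is within 10% of the all-data mean with probability 0.8?
for key, (scope, ds) in enumerate(
    [("pooled", dataset)] + [(a, dataset.for_area(a)) for a in dataset.areas]
):
    curve = sample_size_curve(ds, reps=1000, seed=1, scope=scope, scope_key=key)
    n = required_n(curve, threshold=0.80)
    print(f"  required n ({scope:8s}): {n if n > 0 else 'not reached by n=50'}")
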