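"""Where does survival variation live: area, site or year?

Hierarchical partitioning averages each predictor's incremental R^2 over
all entry orders, so the correlated (nested, unbalanced) predictors get
order-independent shares of the explained variance.
"""

from sealpup import generate, hierarchical_partition, pembrokeshire_design

dataset = generate(pembrokeshire_design(seed=42))
part = hierarchical_partition(dataset)

print(f"full-model R^2 = {part.r2_full:.3f}\n")
print(f"{'predictor':10s} {'I (R^2)':>9s} {'J (R^2)':>9s} {'% of I':>7s}")
for p in ("site", "area", "year"):
    print(
        f"{p:10s} {part.independent[p]:9.4f} {part.joint[p]:9.4f} "
        f"{part.percent[p]:6.1f}%"
    )
# A large site share means choosing WHICH beaches to monitor matters more
# than which area or which year — the key data-aggregation warning.
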