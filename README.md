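# sealpup

Tools for asking how **site selection and data-aggregation decisions** shape
population-level inference from heterogeneous wildlife census data, built
around grey seal (*Halichoerus grypus*) pup survival monitoring: three
coastal sampling areas (Marloes, Ramsey, Skomer) containing 46 beach/cave
sites with very unequal year coverage, pup counts of wildly different sizes,
and survey corrections that produce non-integer counts.

It is a library for ecologists and population analysts who must turn such a
patchwork of site-year survival proportions into vital rates for a matrix
population model (MPM), and want to know how much their answer depends on
*which* sites, years and weights they used.

## What it computes

* **Count correction and aggregation.** Site-year records carry early-stage
  pup survival S_E (birth to the ~20-day moulting stage). Counts are rounded
  to the nearest integer; when a survey's double-count adjustment yields more
  survivors than pups, survival is capped at 1. Means are pup-count-weighted:
  for records with survival s_i and pup counts w_i, the aggregate is
  Σw_i·s_i / Σw_i.
* **Hierarchical variance partitioning** (Chevan & Sutherland): each of
  {area, site, year} gets an independent contribution I_j — its incremental
  R² averaged over all 3! orders of entry into an OLS model on indicator
  predictors — with Σ I_j equal to the full-model R² exactly.
* **Leave-one-site-out sensitivity** of the overall weighted mean, plus F
  tests of whether sensitivities differ by area or scale with site size.
* **Bootstrap sample-size curves**: the proportion of 1,000 resamples of
  n site-year estimates (n = 5..50, drawn without replacement) whose mean
  falls within ±10% of the all-data mean, and the smallest n reaching 0.80.
* **Matrix population models.** A 7-stage female-only MPM (pup; prebreeder
  age classes; breeding females with survival 0.95, fecundity 0.9 × sex
  ratio 0.5). The pup entry is S_P = S_E·S_L, where the late-stage survival
  S_L = 0.48/mean(S_E) calibrates the model to a published low-density
  birth-to-age-1 survival of 0.48. Growth rate λ is the dominant eigenvalue.
* **Stochastic projection**: i.i.d. random draws from a matrix set each
  year, 1,000 replicate trajectories, and the long-run stochastic growth
  rate log λ_s.
* **Synthetic census generator** reproducing the monitoring design (46
  sites, 1993–2015, ~450 records) with logit-normal area/site/year/residual
  effects and binomial observation noise, so the whole pipeline runs with no
  external data.

## Worked example

```bash
python examples/05_matrix_models.py
```

prints, for one synthetic realisation of the monitoring design (seed 42):

```
overall early-stage survival S_E = 0.691
calibrated late-stage survival S_L = 0.48 / 0.691 = 0.694

per-site lambda (46 sites): 1.024 .. 1.085
  lambda from Marloes  mean survival: 1.064
  lambda from Ramsey   mean survival: 1.064
  lambda from Skomer   mean survival: 1.071
  lambda from worst    ten sites   : 1.041
  lambda from best     ten sites   : 1.083
```

Reading: about 69% of pups survive the critical first ~20 days; anchoring
birth-to-age-1 survival at 0.48 implies ~69% survive the remainder of year
one. Parameterising the same MPM from different single sites moves the
asymptotic growth rate from 2.4% to 8.5% per year — and monitoring only the
ten worst or ten best beaches (λ = 1.041 vs 1.083) would imply markedly
different population futures for identical demography elsewhere. The other
examples (`examples/01..06`) walk through aggregation, variance
partitioning, sensitivity, sample-size curves and stochastic projection the
same way.

There is also a thin CLI: `sealpup simulate --seed 42 --out census.csv`,
then `sealpup run --input census.csv --seed 1 --outdir results/` writes all
stage tables plus a machine-readable `summary.json`.

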