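# Methods

## Data model and count correction

The unit of observation is a site-year: `n` pups observed at one breeding
site over one season and `k` of them judged to have survived to the moulting
("barrel") developmental stage reached around day 16–20, after which a pup
is independent. The survival proportion S_E = k/n is *early-stage* survival.

Survey protocols that count from cliff tops apply a double-counting
adjustment, which produces non-integer counts and occasionally more
survivors than pups. The cleaning rule is centralised in
`apply_count_correction`: both counts are rounded to the nearest integer
(halves away from zero — the convention is documented here because "nearest
integer" alone is ambiguous at .5), and when rounded survivors exceed
rounded pups the survivor estimate is taken as correct, so survival is set
to 1 and the pup count raised to match. The rule is applied uniformly to
all records, not only to those from the protocol that needs it: for records
whose counts are already consistent integers it is the identity, so
uniformity is harmless and simpler. Site-years whose rounded pup count is
zero have undefined survival and are dropped (the reader logs how many).

Area-comparable statistics (the sensitivity analysis) are computed on the
subset of years in which every sampling area has at least one record;
with the default design that is 2012–2014.

## Weighted aggregation

All means are weighted by the corrected pup count unless stated otherwise:
an "overall mean" is Σ w_i s_i / Σ w_i over site-year records with w_i =
n_pups. Pooling records (rather than averaging per-site means) is used
wherever a mean over a group of sites is needed, so a site contributes in
proportion to the pups actually observed there. The trend test is OLS of
the annual area-level weighted mean on calendar year, with F = r²/(1−r²) ·
(n−2) on (1, n−2) df. Pairwise site correlations use Pearson r on the years
two sites share, for pairs sharing at least 5 years; pairs where either
series is constant are skipped and counted rather than propagated as NaN,
and no multiple-testing correction is applied (the mean raw p is itself the
summary of interest).

## Hierarchical variance partitioning

Goodness of fit is the R² of OLS on indicator-coded categorical predictors
(area, site, year-as-category; year's *linear* trend is a separate
question). Full dummy coding is rank-deficient by construction; the
minimum-norm least-squares solution leaves R² well defined, which matters
because site ⊃ area makes several sub-models singular. For each predictor j
the independent contribution is the average over all 3! entry orders of the
R² increase when j enters, computed by the subset-weighted formula
I_j = Σ_{S ∌ j} |S|!(3−|S|−1)!/3! · [R²(S∪{j}) − R²(S)]; the joint
contribution is J_j = R²({j}) − I_j. The I_j sum to the full-model R²
exactly; independent contributions that are negative by less than 1e−12 are
clamped to zero before percentages are formed. Observations are unweighted
by default (a pup-count-weighted variant is available via a flag) since the
partitioning concerns the site-year estimates themselves.

Two structural facts about this design are worth knowing when reading
partitions of it. With only three areas, the realised spread of the area
effects is a 2-df quantity and varies a lot between realisations. And
because the year coverage is unbalanced (one area spans 1993–2014, the
others start in 2008/2012), the many year indicator levels are partially
confounded with area/site composition, which channels some composition
signal into year's independent share. Site dominance is a robust finding;
the precise area-versus-year ordering is not.

## Leave-one-site-out sensitivity and sample-size curves

Sensitivity for site s is Δ_s = (weighted mean without s) − (weighted mean
with all sites), on the all-areas-represented year subset; positive Δ means
the site was pulling the estimate down. Because the mean is weighted,
Σ Δ_s has no closed-form null — the invariant that *is* guaranteed (and
tested) is Δ = 0 for a site sitting exactly at the overall mean. Two
follow-up models: a one-way F test of Δ on area with (n_areas−1,
n_sites−n_areas) df, and a simple regression of Δ on the site's mean pup
count with (1, n_sites−2) df.

The sample-size curve draws n site-year survival estimates without
replacement (n = 5..50), takes their unweighted mean ("a sample of
estimates", not of pups), and reports the proportion of 1,000 replicates
within ±10% of the all-data weighted mean — pooled, and per area against
each area's own mean. The required n is the smallest n reaching proportion
0.80 (sentinel −1 when the curve never gets there, which legitimately
happens for high-variance areas). Each (scope, n) pair consumes its own
seed substream, so extending the n grid never perturbs existing entries.
Sampling is without replacement and pooled-then-per-area by default; both
choices are config switches because the originating field protocol is
ambiguous on them.

## Matrix model

Seven stages, female-only, birth-pulse. Default preset
`age_structured_6plus`: pup (0–1), five prebreeder age classes (1–5), one
6+ breeding class with a self-loop. Transitions: pup→2 is S_P; classes 2–6
advance with prebreeder survival 0.95; the 6+ class survives in place with
0.95; reproduction is fecundity 0.90 × birth sex ratio 0.5 = 0.45 from the
6+ class into the pup stage, with no adult-survival discount. The
description "four non-breeding stages and two breeding stages" used for the
initial population vector suggests an alternative bookkeeping, provided as
preset `two_breeding_stages` (fecundity on stages 6 and 7, self-loop on 7).
The default was chosen because it matches the "age classes 1–5, breeding
6+" stage description and yields per-area growth rates in the 1.04–1.09
band at survival levels near 0.69, consistent with the motivating system;
the presets differ in λ by under 1% at those levels.

The only census-informed entry is S_P = S_E·S_L. S_L (Stage IV to age 1) is
assumed constant and calibrated as S_L = 0.48 / mean(S_E), anchoring the
model's birth-to-age-1 survival to a published low-density estimate of 0.48
at the overall mean; `estimate_late_survival` raises if the quotient
exceeds 1 (an impossible probability, meaning the census mean is below the
anchor). λ is the dominant eigenvalue via `numpy.linalg.eigvals`; it is
cross-checked in the tests against a characteristic-polynomial root oracle
(Faddeev–LeVerrier + `np.roots`) at 1e−10 and, for built matrices, against
the scalar equation λ⁶(λ−0.95) = 0.45·S_P·0.95⁵.

Matrix sets mirror the aggregation choices: one MPM per site (across-year
weighted mean), one per area, two from the pooled records of the ten worst-
and ten best-performing sites, one per extreme site (20), and per-site-year
sets for the extremes that preserve temporal variation for stochastic
projection. "Worst/best" ranks sites by across-year pup-weighted mean
survival, ties broken by site label; the pooled extreme means pool
site-year records with pup-count weights rather than averaging site means.

## Projection

Deterministic projection is plain matrix iteration. Stochastic projection
draws one matrix per year uniformly at random, i.i.d. with replacement (no
environmental autocorrelation, no stratification by calendar year), keeps
non-integer abundances (no demographic stochasticity), and uses the initial
vector 575 pups / 1,724 sub-adults / 576 adults (total 2,875). The default
preset has five prebreeder classes, so the sub-adult total is spread evenly
over five rather than the four the vector was originally quoted for; the
asymptotic results are insensitive to this split, and the alternate preset
uses the literal four-way split. The visualisation horizon is 20 years;
log λ_s is estimated separately on a long horizon (default 1,000 years,
burn-in 50, 100 replicates) as the mean post-burn-in log yearly growth,
with the stage vector renormalised each step so only its direction is
iterated. Replicates reaching exactly zero are excluded with a warning.

## Synthetic census generator

Latent survival is logit-normal: p = expit(μ + a + b + c + e) with
independent zero-mean normal effects for area (σ_area), site-in-area
(σ_site), year shared across areas (σ_year) and site-year residual
(σ_resid). Pup counts are negative-binomial (mean `site_size_mean`, shape
`site_size_dispersion`, floor 1) and survivors Binomial(n, p), which
automatically produces the small-colony/high-variance pattern. Site-years
are dropped independently with probability `visit_missingness`.

Defaults of the `pembrokeshire_design` preset (the study conditions; chosen
once, not tuned): 18/9/19 sites over 1993–2014 / 2008–2015 / 2012–2015;
μ = 0.8 on the log-odds scale (mean survival ≈ 0.69); σ_site = 1.0,
σ_area = 0.4, σ_year = 0.15 — site-dominant variance with a weaker area
component and a small shared year signal; σ_resid = 0.5 for site-specific
temporal noise, which keeps between-site correlations weak; mean 20 pups
per site-year with shape 1.2 (strongly overdispersed, as colony sizes are);
missingness 0.17 so the expected record count is ≈ 450 (= 0.83 × 544
possible site-years).

What the generator does *not* emulate: spatial covariance between
neighbouring sites, environmental covariates (exposure, topography),
density dependence, observer effects correlated in time, and area-specific
year effects (available behind a flag but off by default). Tests passing on
this generator therefore demonstrate correctness of the *computations* and
qualitative recoverability of the variance structure, not that any
particular published estimate would be recovered from real data.

## Numerical and interface choices

Problem sizes used throughout testing are the design's own (≈450 records,
46 sites; 1,000 bootstrap replicates; 1,000 projection replicates; 100
replicates × 1,000 years for log λ_s), which run in seconds. Random-number
policy: a single root seed; every stage and every (scope, n) resampling
cell derives its own `SeedSequence` substream, so results are reproducible
bit-for-bit and insensitive to which other stages run. Survival R² values
are clamped to [0, 1] against floating-point drift; saturated designs (rows
≤ rank) report R² = 1 with a warning. The CLI is a thin layer over
`run_pipeline`; exit code 2 flags schema/validation problems, 3
computational failures.
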