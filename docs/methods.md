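# Methods

## Energy partition model

The analysis treats one feeding trial of young broilers (balance window
of 3 days, roughly days 12–14 of age) in which each diet is measured by
two kinds of replicate: cages of 8 birds under total excreta collection
(metabolizable energy) and open-circuit respiration chambers of 4 birds
(heat production). All energies are on a dry-matter (DM) basis; air-dry
inputs (diet formulations, assayed diet GE/CP) are converted on load
using the record's own DM.

Per replicate:

- AME (MJ/kg DM) = (GE_feed·FI − GE_excreta·excreta_DM) / FI.
- AMEn = AME − n_correction × TNR_per_kg_feed / 1000, with
  n_correction = 34.39 kJ per g retained N and TNR per kg feed =
  feed N − excreta N × (excreta DM / FI). The correction is applied per
  kg of DM feed; retention per bird-day is reported alongside.
- THP (kJ) = 16.1753·O₂(L) + 5.0208·CO₂(L). These are Brouwer-form
  thermal equivalents treated as kJ per litre of gas; chamber totals are
  divided by bird-days before scaling. RQ = CO₂/O₂.
- Flows are expressed per kg of metabolic body weight (BW^0.70, BW in
  kg) per day. FHP is the allometric constant 450 kJ·kg⁻⁰·⁷⁰·d⁻¹, so in
  the reporting unit FHP = 0.450 and HI = THP − 0.450 identically.
- AMEI = AME × FI(kg DM/bird/d) / mbw; NEI = AMEI − HI; RE = AMEI − THP;
  RE_protein = TNR × 6.25 × 23.85 kJ/g protein (5.7 kcal/g converted to
  kJ); RE_fat = RE − RE_protein. The conservation identities
  AMEI = NEI + HI and RE = AMEI − THP hold to machine precision by
  construction and are asserted on every record.
- Diet NE (MJ/kg DM) = AME × NEI/AMEI: the metabolizable energy
  discounted by the measured heat-increment share of intake. When
  NEI = AMEI (no heat increment above maintenance) NE = AME.

Chamber birds undergo no excreta collection, so a chamber's AME and N
retention come from the paired cage replicate of the same run and diet;
if a run lacks the paired cage, the diet's cross-run mean is used with a
warning.

Negative HI or RE is reported and flagged, never clipped — a negative
HI usually signals an FHP overestimate for the flock at hand and should
be visible downstream.

## Substitution method

Test diets replace 30% (air-dry) of the reference diet with one test
ingredient. On a DM basis, a% of the test diet is reference-origin
energy-yielding material and b% is the test ingredient, so
E_test = E_ref·a/100 + E_ing·b/100 and
E_ing = (E_test − E_ref·a/100)/(b/100) for each of AME, AMEn, NE.

The packaged study constants are a = 67.58, b = 31.32 and are the
default. `substitution_levels` recomputes a and b from the formulations
by DM-weighting the air-dry inclusions, but the minor ingredients' DM
values are unpublished, so the recomputation only approximates the
printed constants (a ≈ 67.6, b ≈ 29–31 depending on the assumed DM of
minerals and additives); the printed pair is therefore preferred for
reproducing the published tables.

Ingredient values are computed per run against that run's own
reference-diet values and then averaged across runs. The cross-run
pooled diet means are not expected to reconcile exactly with the
ingredient table through the substitution formula, and they do not in
the published tables either.

## Statistics

- Pearson correlation matrices with two-sided t-test p-values,
  pairwise-complete.
- One-way fixed-effects ANOVA; pooled SEM = √(MSE/harmonic-mean n);
  Duncan's multiple-range letters with critical ranges
  q*(p, df_error; protection 1−(1−α)^(p−1))·√(MSE/n), quantiles from the
  studentized-range distribution (no table lookups), harmonic-mean n for
  unequal groups (flagged).
- Stepwise regression: bidirectional, α_enter = 0.05, α_remove = 0.10
  (common statistics-package defaults; both configurable). A candidate
  whose inclusion would put two predictors with pairwise correlation
  p < 0.05 into the model is rejected (the published equations were
  built under a "no significant correlation between independents"
  constraint). Selection stops when the fit is numerically perfect
  (R² > 1 − 1e−10), since partial tests on a zero residual are
  meaningless. Fitting is at ingredient-sample level (n = 5 per
  ingredient class) by default because replicate-level NE per sample is
  not published; the machinery accepts any panel, so replicate-level
  fits on synthetic data work unchanged.
- Validation pools training and holdout points (as in the published
  predicted-vs-measured scatters) and reports their Pearson r.

On the published five-sample wheat panel the stepwise procedure selects
{AME, ADF} and OLS reproduces the published coefficients
(1.968, −0.411, intercept −14.227) to three decimals. The wheat-bran
equation's published R² = 0.785 is not reproducible from the five
sample-level points (an exact five-point fit of three predictors has
R² ≈ 0.9); it was almost certainly fitted on replicate-level data that
are not published, so the bran equation is carried as printed constants
rather than refitted.

## Synthetic-data generator

The generator emulates the trial design: 12 treatments (2 reference + 10
test diets), 6 replicate cages of 8 birds and 6 chambers of 4 birds per
treatment, 3-day balance window, start weight ~356 g, feed intake ~56 g
DM/bird/d, FCR ~1.5 with linear gain over the window. Runs are
interpreted as replicate batches — run r holds replicate r of every
diet — so the reference diet is present in every run and run-wise
pairing is always defined. (The emulated design ran 2 diets at a time
across 6 batches, which leaves the run-to-reference mapping ambiguous;
the batch interpretation is this package's choice.)

Observables are back-solved from ground truth (true diet energies
composed by the mixing rule; excreta mass/GE/N from true AME and N
retention; O₂ and CO₂ from true THP and RQ) and then perturbed with
multiplicative lognormal noise parameterized by CV, mean 1. Defaults are
calibrated to the between-replicate relative SDs the emulated study
reports: THP 11.2%, feed intake 7.4%, body weight 5.2%, RQ 3.5%,
excreta mass 5%, excreta GE 2%, excreta N 8%. One seed drives
per-run spawned substreams, so a fixed seed gives bit-identical bundles
and partial re-simulation of a run is reproducible.

What the generator does *not* emulate: within-day gas kinetics and
circadian heat-production patterns, thermoregulatory responses,
bird-level (as opposed to replicate-level) variance components, chamber
hardware drift, and any diet × age interaction. Passing recovery tests
therefore show that the estimator chain is algebraically and
statistically sound under the assumed error model, not that the error
model captures every feature of real chamber data.

Recovery properties (asserted in the test suite): a noise-free
simulation is recovered exactly (energies, RQ, performance); at the
calibrated CVs the mean recovered wheat NE over 500 simulated studies is
within 2% of truth (the single-study spread is large — SD ≈ 1.2 MJ/kg —
because the substitution inversion amplifies diet-level noise by 1/b ≈
3.2 and all ingredients share the reference-diet estimate).

## Numerical and design notes

- Constants live in one frozen `EnergyConstants` object (all strictly
  positive, overridable per run or from config or CLI).
- The protein energy equivalent is stored as 23.85 kJ/g (5.7 kcal/g ×
  4.184); the allometric exponent 0.70 is configurable.
- The published source tables carry two internal inconsistencies that
  the package resolves explicitly: the wheat NDF summary row (mean
  printed as 18.90 with CV 50.20, inconsistent with the per-sample
  values ~34–40 — summaries are always recomputed from per-sample
  values), and a concluding mean NE pair (8.39/3.84) that contradicts
  the tables and abstract (10.29/5.07 — the table-consistent values are
  used). The diet-assay table's GE is treated uniformly as air-dry and
  converted to DM on load; the published reference-diet AME/GE ratio
  appears to have used the unconverted value, a discrepancy of ~4.5
  percentage points in that one ratio.
- Duncan quantiles are cached by (probability, span, df); the
  studentized-range quantile is by far the most expensive operation in
  the pipeline.
- Monte-Carlo problem sizes in the tests (500 simulated studies for the
  bias check, 200 draws for ANOVA power) were chosen so the whole suite
  runs in well under a minute per check on one CPU while keeping the
  Monte-Carlo standard error a small fraction of the asserted
  tolerances.
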