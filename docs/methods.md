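# Methods

## The compositional model

A measured day is the four-part composition **x** = (SED, LPA, MVPA,
sleep), strictly positive and carrying only relative information. All
internal computation happens on proportions (closure constant 1); the
1440-min scale is applied once, at reporting. The canonical part order
(SED, LPA, MVPA, SLEEP) is fixed package-wide because ilr coordinates
are order-sensitive; loaders validate and reorder to it.

Balance coordinates come from a sequential binary partition (SBP). The
sign table is validated as a genuine SBP (the first row splits all
parts; each later row splits a group left intact so far) and the
orthonormal basis is derived from it by the balancing-element formula —
the closed-form expressions for the shipped three-balance movement
partition are used only as independent oracles in the tests. The engine
accepts arbitrary dimensions and user-defined partitions
(`BalancePartition.from_rows`); pivot coordinates and non-balance ilr
bases are out of scope.

## Preprocessing rules

* A *valid day* has at least 600 min (10 h) of waking wear; the boundary
  is inclusive.
* A participant is retained when they have at least 4 valid days at
  every required timepoint (default: baseline and 6 months).
* Days collapse to one composition per subject-timepoint by the
  compositional (geometric) mean, consistent with the package's
  geometry; an arithmetic-mean-of-minutes option is kept behind config
  since the two differ only at second order in the day-to-day
  dispersion (the tests bound the gap at 2% for 2% day noise). Day
  lengths (~1410–1430 min, in-bed time to in-bed time) are never
  renormalised to 1440 before closure; closure makes each day
  self-normalising.
* Ordering: filters → aggregation → imputation of missing parts →
  detection-limit screen → closure → ilr. Imputation operates on the
  subject-timepoint aggregates, i.e. at the same unit as the analysis
  dataset; zero or missing parts therefore pass through aggregation
  (with a warning) rather than erroring, and a `strict` flag is
  available for pipelines that insist on day-level repair.

## Imputation

Missing parts are filled by EM-style iterative regression in pivot ilr
coordinates: the incomplete part is moved to the first coordinate,
regressed on the remaining coordinates over the complete records,
predictions replace the missing entries, and the cycle repeats until
the imputed coordinates move less than 1e-6 (max 50 iterations,
warning + flag on non-convergence). Observed entries are never
modified; at least 10 complete records are required.

Values of one part under a detection limit (MVPA < 0.5 min/day is the
shipped screen) are replaced by a regression prediction in the same
pivot space, taken as the truncated-normal conditional expectation below
an effective ceiling of 2x the limit, floored at the recorded value;
the repaired record is then reclosed to its original total. The
ceiling expresses the prior that a value recorded below the limit is
genuinely small: unconstrained regression would pull it to the cohort
mean. With the 0.5-min screen, replacements land just under one
minute. A simple multiplicative fallback (0.65 x limit, other parts
rescaled) is selectable. The main analysis repairs only exact zeros
(`which="zeros"`); the sensitivity analysis additionally treats every
value under the limit as unobserved (`which="below"`), and the pipeline
emits paired `table3.csv` / `table3_sensitivity.csv` outputs from the
same code path.

## Descriptive layer

Change compositions divide the follow-up composition component-wise by
baseline and reclose; the uniform composition (1/4, …) is "no change".
Ternary exports cover the four 3-of-4 subcompositions on an equilateral
unit-side triangle (affine barycentric projection). Confidence regions
are built in the 2-D ilr plane of each 3-part subcomposition, using the
movement partition restricted to the kept parts (for every 3-of-4
subset the restriction is itself a valid two-balance SBP): center =
coordinate mean, shape = sample covariance, boundary at the squared
Mahalanobis radius

* `mean` regions: 2(n−1)/(n(n−2)) · F(level; 2, n−2) — Hotelling-T²,
  exact under ilr-normality;
* `data` regions: the chi-square(2) quantile.

Both kinds are exported and labelled, defaulting to `mean` (confidence
for the group mean change). Boundaries are discretised at 360 points, 6
significant digits. Regions are perturbation-equivariant: shifting all
points by a fixed composition shifts the region identically (tested).

## Mixed models

One model per coordinate: fixed effects intercept, gender, age, group,
time, group x time; random intercept and random time slope per subject;
REML via statsmodels `MixedLM`. Codings (all configurable): group
control = 0, gender woman = 0, age centered at the sample mean, time in
months (0, 6) by default with a binary (0, 1) option — the months scale
is the package default and is recorded in the design object. Inference
is Wald with a normal reference by default; a t reference (df = n − p)
is selectable.

With exactly two timepoints the unstructured 2x2 random-effect
covariance is not identified (four variance parameters against three
estimable moments); the profiled likelihood has a flat ridge, on which
fixed effects and their standard errors are constant. Fits start from
method-of-moments values (OLS fixed effects; variance components solved
from the per-subject residual covariance over the two times) and fall
back to independent random effects — which are exactly identified in
this design — whenever the unstructured fit fails to converge or its
information matrix is singular; the fallback is flagged in the results.
A constant response degenerates cleanly to an intercept-only fit with
zero variance components. No multiplicity adjustment is applied across
the three coordinates.

## Synthetic trial generator

The generator emulates an activity-tracker trial in recent retirees:
231 subjects (117 intervention / 114 control), sex-stratified 1:1
allocation with ~83% women, age ~ N(65.2, 1.1²) years, 7–8 measured
days per subject-timepoint, day lengths ~ N(1420, 10²) min. Group x
timepoint mean compositions default to the published four-cell table of
the baseline/6-month means. Day-level variation is logistic-normal:
subject coordinate means are the cell means plus a random intercept and
a random time slope, and days scatter with independent ilr noise, so
all parts are positive by construction and geometric-mean aggregation
is exactly arithmetic averaging in coordinate space. Defaults, chosen
once and documented as calibration rather than ground truth:

* between-subject intercept SDs (0.50, 0.37, 0.15) per coordinate —
  back-solved from the published group-contrast CI widths;
* random slope SDs (0.030, 0.034, 0.015) per month — set so simulated
  interaction standard errors sit within ~2x the published CI widths;
* day-to-day ilr noise SDs (0.45, 0.40, 0.20) — implying a day-level
  MVPA log-SD of ≈ 0.37, i.e. roughly 40% of its mean.

Blemishes are injected at configurable rates: invalid days (wear drawn
under the 600-min rule), one behavior missing for a whole record, and
near-zero MVPA records (the record's days rescaled so the aggregate
lands in (0.05, 0.45) min, freed minutes moved to SED). Ground truth —
the fixed-effect vector per coordinate, every subject's random effects,
and each corrupted record's pre-corruption value — is returned for
recovery tests. All randomness derives from one seed through per-stage
substreams, so changing one rate does not reshuffle the other draws;
identical configs give byte-identical CSV output.

`inject_effect` adds a known group x time shift on one coordinate
(leaving the others untouched); `null_interaction_config` rebuilds the
intervention follow-up cell from the control change so the true
interaction is exactly zero while group and time effects remain.
`simulate_coordinate_panel` draws directly at analysis resolution
(aggregate noise = day SD / sqrt(days)), which is
distribution-identical to the day-level route for clean records
(asserted by test) and is what the replicated experiments use.

What the generator does **not** emulate: raw acceleration, posture
misclassification, seasonal or weekday structure, informative missing-
ness or dropout, and any dependence of behavior on covariates (true
gender/age effects are zero). Passing tests therefore demonstrate the
pipeline's correctness and calibration under logistic-normality, not
robustness to those real-data features.

## Experiment sizes and numerical choices

The replicated experiments use: 2000 datasets x 100 points for
confidence-region coverage; 1000 full-size null trials for the type-I
error of the interaction test; 200 trials with beta = 0.02/month on the
LPA-vs-MVPA coordinate for recovery bias and CI coverage. Tolerances:
closure checks at 1e-9 relative; ilr round-trips at 1e-9; the
general-formula-vs-closed-form oracle at 1e-12; optimizer defaults from
statsmodels with lbfgs and warm starts. Degenerate inputs (constant
response, singular covariance, empty cells, all-missing records) raise
informative errors rather than propagating NaN.

## Known limitations

* Two-timepoint designs cannot identify the unstructured random-effect
  covariance; reported variance components are then one point on the
  ridge (fixed effects are unaffected). With three or more timepoints
  the full structure is identified and used as-is.
* Single imputation only; imputation uncertainty is not propagated.
* The detection-limit ceiling (2x the limit) is a modelling choice; the
  qualitative behavior (sub-limit values raised to about one minute
  under a 0.5-min screen) is tested, but other ceilings are defensible
  and configurable.
* Wald inference is first-order; with far fewer subjects than the
  defaults, the t option (or a future Satterthwaite correction, out of
  scope) would be preferable.
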