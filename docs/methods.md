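# Methods

## The growth model and its assumptions

The package treats a uveal melanoma as a population of cells growing
exponentially with a constant doubling time `T`: `N(t) = 2^(t/T)` from a
single founding cell. A tumor of `N` cells at diagnosis therefore initiated
`log₂(N)·T` days earlier. The subpopulation of cells with lost BAP1
expression is treated as a clone within that population, assumed to grow at
the *same* doubling time; dating it is the same inversion applied to the
mutant count. The estimator deliberately makes no allowance for a growth or
survival advantage of the mutant clone — that bias is quantified separately
by the forward simulator (below), not folded into the estimates.

Assumptions worth keeping in mind:

* growth is exponential at constant rate — no Gompertzian deceleration, no
  dormancy, no cell death term;
* the tumor is a semi-ellipsoid (`V = (π/6)·t·lbd²`) and cells are prolate
  spheroids (`v = (π/6)·a·b²`). Calipers are full diameters; with semi-axes
  `a/2, b/2` this is the classical `(4/3)π·(a/2)(b/2)²` rotating-ellipsoid
  volume. Treating calipers as semi-axes instead would inflate every cell
  volume 8-fold and is inconsistent with measured UM cell volumes
  (~1.6–2.7 × 10³ μm³);
* one mutant clone; other UM driver events (*SF3B1*, *EIF1AX*, 8q gain) are
  not modelled;
* the doubling time is an exogenous scenario, not estimated from the data.
  Literature medians for primary UM span 128–511 days (median 292); results
  are always reported per scenario and never averaged across scenarios.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| doubling-time scenarios | 128, 292, 511 | days | back-dating scenarios |
| mean cell volume | pooled per-cell mean, else 2105 | μm³ | volume → cell count |
| year length | 365.25 | days | day → year reporting |
| classification cutoff | 33 | % BAP1-positive cells | low vs high expression |
| logistic upper bound | 100 | % | logistic curve family |
| zero-crossing search bound | max observed volume | mm³ | root acceptance window |

Printed worked examples round doubling counts to one decimal before
multiplying by the doubling time (e.g. 27.3 × 128 = 3494.4 → 3494 days);
`mutation_timing(..., doubling_decimals=1)` reproduces that display
convention, while the default carries full precision.

## Curve fitting

Eleven families are fitted by OLS on their linearizing transformations
(`curves.py` docstring has the full table); R², F and p are reported on the
transformed scale, with `F = (R²/k)/((1−R²)/(n−k−1))`. A family "could not
be fitted" exactly when its transformation is undefined for at least one
observation (any 0% tumor kills all ln-y families) or the design matrix is
singular. Note the inverse family (`y = b0 + b1/x`) only needs positive
volumes, so it survives zero-percent tumors even though ln-y families do
not. The zero-crossing volume is the smallest root of the fitted curve in
`(0, search_max]`; linear/logarithmic/inverse roots are analytic, polynomial
roots come from eigenvalue root-finding, and strictly positive families have
none. Bounding the search by the observed volume range keeps a cubic's
far-out root (≈ 6 × 10³ mm³) from overriding the in-range answer of 0.

## Survival analysis

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
(Greenwood variance, log-log confidence band; the median CI is where the
band crosses 0.5, Brookmeyer–Crowley style). The median SE is derived from
the CI half-width under a normal approximation — an SE for a KM median is
not uniquely defined, and this matches the convention of mainstream
statistics packages; ignore it and use the CI where that convention is
unwanted. Anchored analyses add each patient's *own* back-dated offset
(their tumor's doubling counts under the chosen scenario) to their follow-up
time, so the anchored curves inherit the between-patient spread of the
offsets; a single cohort-mean shift would not. Death from other causes is
treated as censoring at last follow-up. Patients with BAP1 expression in
100% of tumor cells have no mutant clone to date and are excluded from
mutation-anchored curves; wild-type tumors likewise pass through as a typed
"no mutant clone" result rather than an error.

## The synthetic cohort

The generator emulates an enucleation cohort:

* **Dimensions** — independent normals, thickness 7.2 (SD 4.0) mm and LBD
  13.8 (SD 4.8) mm, rejection-sampled to thickness ≥ 1 mm, LBD ≥ 3 mm and
  thickness ≤ LBD. The rejection step shifts the accepted LBD mean up ~1 mm
  and trims thickness slightly; volumes come out right-skewed with mean
  ≈ 800 mm³ and SD ≈ 790 mm³.
* **Mutation status** — Bernoulli(0.34), the mutation prevalence among
  sequenced UM.
* **Percent BAP1-lost** — for mutant tumors, `clamp(29.03 + 0.017·V + ε, 0, 100)`
  with `ε ~ N(0, 36²)` percent; wild-type tumors get a half-normal (SD 5%)
  floor, since immunohistochemical grading is not perfectly dichotomous.
  The noise SD of 36% is a calibration: with the cohort's volume SD it puts
  the linear fit's R² near 0.14 at n = 61. The clamp attenuates the OLS
  slope by roughly 20% (≈ 2.9 single-fit SEs at n = 1000) — a real property
  of bounded-percent data that the recovery tests measure on the seed-averaged
  slope.
* **Cell calipers** — cell volumes from two log-normals moment-matched to
  lost 2657 (SD 1283) μm³ and retained 1593 (SD 602) μm³, mixed per tumor by
  its percent lost; calipers recovered via a log-normal aspect ratio
  (median 1.4, log-SD 0.2, floored at 1). Log-normals were chosen because
  calipers are positive and right-skewed; only the first two volume moments
  are constrained by data.
* **Survival** — exponential metastasis times matched to medians 2.4 y
  (mutant) and 16.0 y (wild-type), censored uniformly on [0, 25] years.

What the generator does **not** emulate: correlation between tumor size and
mutation status (group volume contrasts are therefore not a generator
target), measurement error in calipers, intratumor spatial heterogeneity,
non-exponential hazards, and cohort-specific censoring patterns. Passing
tests show the estimators recover what this structure encodes — not that
real cohorts satisfy the structure.

## Forward simulator and recovery

`simulate_growth` is the deterministic mean-field counterpart of the
estimator: a founding cell doubles every `T_wt` days; at generation `g`, one
of the `2^g` cells present converts to the mutant clone, which doubles every
`T_mut` days thereafter; growth stops when total volume reaches the end
volume (stopping time found by bracketed root-finding, `brentq`, tolerance
1e-9 days). Carving the seed out of the existing population keeps the total
exactly `2^(t/T)` under equal rates, which is what makes the inversion exact
there: `recovery_experiment` confirms zero bias on equal-rate grids and a
systematically *positive* bias in the mutation's age when the clone grows
faster than the bulk — i.e. ignoring the clone's advantage makes the
mutation look older, so the equal-rate estimates are conservative upper
bounds on mutation age.

## Numerical choices and degenerate inputs

* Cell counts round to the nearest integer; doubling counts keep full
  precision except for the explicit display convention above.
* Ties at the 33% classification cutoff go to "high" (the cutoff is ≥).
* Cohen's κ uses marginal-product expected agreement; degenerate marginals
  (expected agreement 1) yield κ = None / band "undefined" rather than 0/0.
* Sample SDs use ddof = 1; a single observation reports SD 0.
* Thickness > LBD is flagged with a warning, not rejected (mushroom-shaped
  tumors exist).
* All generator randomness flows from one `numpy` `default_rng(seed)`;
  identical config ⇒ byte-identical output.

## Problem sizes

Calibration checks run at the sizes that make their targets meaningful while
staying light: R² calibration averages 50 cohorts of 61 tumors; slope
recovery averages 10 cohorts of 1000; distributional calibrations use one
cohort of 10⁴ tumors; recovery grids cover 3 × 3 parameter combinations per
scenario. The full suite runs in a few seconds.

## Known limitations

* Constant doubling time over decades of growth is a strong idealization;
  the 128- and 511-day scenarios should be read as bracketing, not as a CI.
* The zero-crossing extrapolates a curve fitted on 10–2000 mm³ tumors down
  to ~mm³ scale, far outside the data.
* The volume-based classifier is weak by construction (volume explains
  ~10–15% of percent-lost variance); κ in the "fair" range is the expected
  regime, not a failure of implementation.
* The estimator's equal-rate assumption biases mutation ages upward whenever
  the mutant clone actually outgrows the bulk — the direction, but not the
  magnitude, is established by the recovery experiments.
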