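# Methods

## Grids and geometry

A dose grid is a 2D scalar field with cell-center geometry: cell `(i, j)`
sits at `origin + (i · row_spacing, j · col_spacing)` mm, 0-based,
row-major.  Grids are `absolute` (Gy) or `relative` (% of the distribution
maximum, max exactly 100).  Comparisons pair a fine *reference* (planned,
1 mm) grid with a coarse *evaluated* (measured, 10 mm) grid; every evaluated
cell center must lie within the reference extent, and neither grid is ever
interpolated.  The measured lattice is treated as an unwrapped plane: a
cylindrical diode array's wrap-around adjacency is not modeled, because the
object of study is the comparison mathematics, not detector geometry.

The lower dose threshold (LDT) is always taken on the **planned** dose, as a
fraction of the planned maximum, evaluated at the reference cell nearest
each measured point.  Thresholding on the plan is the dominant clinical
convention and keeps the evaluation mask independent of measurement noise;
the alternative (thresholding on the measurement) would couple the mask to
the very errors under study.  Excluded points appear in no numerator and no
denominator.

## Gamma search

Gamma is computed for each measured point by searching the discrete
reference lattice.  Searching the fine grid from the coarse one bounds the
discretization error of the spatial term by half the reference spacing
(0.5 mm).  The search starts in a window of radius `3 · DTA` and doubles the
radius until the best gamma found satisfies `γ ≤ radius / DTA` (or the
window covers the whole grid); any point outside the window is farther than
the radius in at least one axis, so its spatial term alone already exceeds
the current best.  The result is therefore *exactly* the exhaustive minimum
— the expansion rule is a speed optimization, not an approximation — and an
`exhaustive=True` flag retains the brute-force path as a self-check.  The
test suite additionally compares against an independent full-grid
broadcasting oracle.

Numerical conventions: the pass test is `γ ≤ 1` inclusive; ties in the
minimization are harmless (a minimum over a finite set) and the minimizing
location is not reported.  Under local normalization, reference candidates
with zero dose are skipped; if every candidate is skipped the point's gamma
is `+inf` and it fails.  Both normalizations are invariant under a common
rescaling of the two grids.

## MADD

Dose differences, tolerances and gradients are all expressed in percent of
the reference maximum ("global" units).  This is the one genuinely open
convention in the method; it is isolated in a single normalization constant
(the reference maximum in `ndd_map`/`dose_gradient`), and the regional
criteria's own design arithmetic (a 7% local difference at the 70% isodose
≈ 4.9% of maximum) supports maximum-dose units as the common currency.  The
gradient is computed on the fine reference grid with `numpy.gradient`
(central differences in the interior, one-sided at borders — exact for
linear fields) and sampled at the reference cell nearest each measured
point, ties toward the lower index; the 10 mm measured lattice undersamples
penumbra gradients, so measuring the gradient there would be meaningless.
MADD has no spatial search by construction, which is precisely its claimed
resolution insensitivity.  `box ≥ quadrature ≥ ΔD` holds pointwise
(`a + b ≥ √(a² + b²)` for non-negative `a, b`), so the box pass rate can
never fall below the quadrature one.

## Divide-and-conquer regional gamma

Region membership is frozen from the reference dose (nearest reference
cell, % of reference maximum) before any comparison; a point's region never
depends on the measurement.  Boundaries are lower-inclusive,
upper-exclusive: `[90, ∞)`, `[50, 90)`, `[20, 50)`, `[10, 20)`, below 10%
excluded.  The tabulated per-region dose criteria exist for base values 1,
2, 3 and 5% only; there is no interpolation between rows.

Two choices the regional method leaves open are made here and are
configurable: the regional gamma runs with **local** normalization by
default (the criteria table was designed so each region's local tolerance
matches about the same maximum-dose fraction; a `normalization="global"`
switch supports sensitivity analysis), and the overall index **pools pass
counts across regions** (count-weighted) rather than averaging the four
region percentages.  Pooling makes the overall index collapse exactly to
the plain gamma pass rate when all four criteria coincide — an identity the
tests assert to 1e-12 — and matches the definition of %GP as a fraction of
points.  An empty region is reported with count 0 and an undefined pass
rate, not an error.

## Synthetic cohorts

Plans are analytic: a rectangular plateau with error-function penumbra
(scale 8 mm; 10–90% falloff over ≈ 14 mm, typical of a linac field edge)
modulated by 1 + a sum of Gaussian lobes.  Defaults: 20 × 20 cm extent at
1 mm; 3 lobes, relative amplitude 0.25–0.6, width 14–28 mm; plateau dose
2 Gy; field edges jittered ±5 mm per plan.  The jitter matters: clinical
field sizes vary, and without it every penumbra would sit at the same phase
of the 10 mm detector lattice, leaving the 5–10% dose band systematically
unsampled and the two standard thresholds (5%, 10%) indistinguishable.
Because the plan is a closed form, a rigid shift is re-sampled exactly from
the shifted field — distance-to-agreement behavior is tested free of
interpolation artifacts.  The generator validates that all four isodose
bands are populated.

Error injection applies, in order: rigid shift, multiplicative scaling,
Gaussian blob perturbations (amplitude in % of the plan maximum), additive
Gaussian detector noise.  Doses are clamped at zero.  The measurement is a
point sample at the 10 mm detector pitch — no volume averaging, angular
response or calibration drift; passing tests therefore say nothing about
those detector-physics effects on real measurements.  Relative-dose
(tomotherapy-like) pairs normalize both grids to their own maxima after
error injection, as relative measurement does.

The default cohort is 100 plans with 12% errored, mirroring the failure
fraction a clinical QA audit reports.  Errored plans always carry two
low-dose-region blobs (centers where the planned dose is 6–10% of maximum,
amplitudes 5–10% of maximum) — matching the observation from measured
cohorts that large percent dose differences are most prevalent in low-dose
regions — plus one secondary error (1.5–3.5 mm shift or an in-field blob)
and 0.2–0.5% detector noise.  Uniform dose-scaling errors are deliberately
not part of the default mix: under global normalization a pure scale error
puts its failures in the high-dose region and its best agreement in the
low-dose band, the opposite of the low-dose-dominated structure this cohort
models (and it reverses the usual direction of the pass rate's response to
raising the LDT).  Scaling errors are studied explicitly through a custom
`error_sampler` in the sensitivity experiment, where they show the expected
ordering: local gamma degrades far more than global gamma, which degrades
more than MADD box.  Clean plans use the identity error model (zero noise),
so a clean pair yields γ = 0 and NDD = 0 exactly under every technique.

All generation is a pure function of parameters and seed; the cohort
manifest stores seeds, plan specs and error models, and every file
regenerates bit-identically from it.

## Correlation study

Each plan × (technique, criteria, LDT) cell holds one agreement index; the
D&C columns exist only at the 10% threshold, which its region definitions
imply, and only for tabulated base criteria — other cells are flagged
missing and dropped pairwise, never imputed.  Simple OLS (scipy's
`linregress`) supplies R² and the slope's two-sided t-test p-value; R² of
simple regression equals the squared Pearson correlation and is symmetric
in the pair, so direction matters only for the (unreported) slope.  A
constant predictor raises a degenerate-input error; a constant response
returns R² = 0, p = 1 by convention.  The multiple-comparison family
defaults to all pairs within one report table; its size m sets the Šidák
level `1 − (1−α)^(1/m)`, which lies strictly between α/m and α.

## Problem sizes and tolerances

Default analyses use 100-plan cohorts (201 × 201 reference, 21 × 21
measured grids), 200 random pairs for the search-oracle cross-check and 50
for the regional-equivalence check — sizes at which the full suite and the
acceptance script each run in well under a minute per sweep on one CPU
while exercising every code path at clinically shaped data.  Exact
identities (oracle equivalence, regional pooling) are asserted at 1e-12;
directional cohort statements (LDT response of the mean global pass rate,
technique orderings) are asserted on the cohort mean at fixed seeds.

## Known limitations

2D grids only; no cylindrical wrap-around; no sub-point interpolation of
the reference during the gamma search (discretization ≤ 0.5 mm); MADD's
normalization convention is fixed to maximum-dose units rather than
inferred; the synthetic generator does not emulate MLC sequences,
Monte-Carlo dose noise, detector calibration or volume averaging, so
quantitative pass-rate levels on real QA data will differ even where the
qualitative orderings carry over.
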