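# Methods

This note documents the models and numerical choices behind
`graphoscale`: what each stage computes, which knobs matter, what the
synthetic data do and do not emulate, and where the design was
genuinely open.

## Pen recordings and stroke model

A recording is an ordered list of *strokes* — maximal pen-down
intervals — each a series of samples `(t, x, y, pressure, azimuth,
altitude)` at a nominal 60 Hz. Coordinates are device points with y
growing downward; pressure is any non-negative device scale (some
digitizers normalize to [0, 1], some do not — all downstream statistics
are scale-covariant and the norm curves absorb the convention). The two
pen-orientation angles are constrained to [0, 180] degrees. In-air
motion is not recorded; the in-air time ratio is inferred from the gaps
between consecutive strokes.

Strokes with fewer than 2 samples are dropped on read with a warning
(they carry no displacement information); non-monotone timestamps are a
hard error.

**Line segmentation.** Static features bin points *within a line of
text*. When the input does not label lines, strokes are grouped by
1-D single linkage on their median y: after sorting, a new line starts
when the gap between consecutive median-y values exceeds 1.5× the
median stroke height. The rule is parameter-light and exact on
well-separated copy-text lines; explicit `line_id` labels in the input
always win, and the result is independent of the temporal order of
strokes.

## Spectral machinery

All "…Frequencies" features share one estimator. A 1-D series is split
into consecutive non-overlapping bins of 600 points (incomplete
trailing bin dropped); each bin is mean-removed and discrete-Fourier
transformed; magnitude spectra are averaged point-wise and normalized
to sum 1. Choices worth knowing:

* the DC line is excluded — the series mean carries no tremor/fluency
  information and would dominate the normalized vector;
* *magnitude* (not power) spectra are averaged and the average is
  normalized to **sum** 1 (not max 1); both are conventions, fixed and
  documented here, and the norm curves absorb them;
* bins never span a pen-away gap longer than 1 s (a page change). For
  derived series timestamped at bin midpoints (the 6 Hz rate series),
  a sub-second pen lift inflates the apparent timestamp gap by up to
  two bin widths, so the cut triggers at gap > 1 s + 2× the series'
  median sampling interval;
* an all-zero average (e.g. a constant signal) maps to the uniform
  spectrum with a warning rather than a division by zero.

The five summaries are: **90% bandwidth** — width from the lowest
occupied frequency line to the smallest line where cumulative power
reaches 0.9 (zero for a one-line spectrum); **spectral median** —
smallest frequency with cumulative power ≥ 0.5; and, against a
cohort-average reference spectrum on the same grid, **entropy**
(Kullback–Leibler divergence with ε = 1e−12 smoothing — the paper-trail
notion of "entropy between two distributions" is underdetermined, and
KL(writer ‖ cohort) is the information-theoretic divergence that is 0
iff the writer matches the cohort), **correlation** (Pearson) and
**distance** (Euclidean).

**Tremor residual.** Consecutive samples define local displacement
vectors; each run of 10 local vectors defines a global
writing-direction vector (their mean); the residual is |local ×
global| for the run's central local vector. It is purely geometric
(time-parameterization invariant) and scales quadratically with
coordinate units.

## The 62-feature catalogue

Feature ids run 1–36 and 38–63 (37 is unassigned; the numbering is the
one users of this feature set know, so it is kept). Static 1–12,
kinematic 13–23, pressure 24–36, tilt 38–63 (the pressure block
mirrored onto azimuth and altitude). Decisions where the definitions
were open:

* **(1), (2)** use 300-point bins *within one line*; a line's trailing
  partial bin is dropped; (2) averages bin bounding-box areas over
  bins so the feature is comparable across text lengths.
* **(3)** is the spatial pen-lift displacement (last sample of a
  stroke to first sample of the next), not the temporal gap — the
  temporal side is already captured by (23).
* **(4)** counts samples per *occupied* 20-pixel grid cell, grid
  anchored at the trace's bounding-box corner (this makes the feature
  translation invariant).
* **(5)** is a circular mean of arctan2 step directions — an
  arithmetic mean of angles is wrap-around sensitive.
* **(7)** uses scipy's Qhull convex hull; the hull area does not
  depend on the algorithm.
* **Rate-of-change blocks** (27–29 and tilt mirrors): the series is
  cut into consecutive 10-sample bins within each stroke (never across
  a pen lift), each summarized by mean value and mid time; the rate is
  |Δ mean| / Δ mid-time — value difference over time spent, the
  conventional rate (the reciprocal reading diverges for equal bins).
* **Inversions per second** (31, 52, 53) count strict sign changes of
  consecutive non-zero first differences, divided by the elapsed
  recording time.
* **(17)** smooths the speed series with a generalized-Gaussian window
  (M = 3, p = 0.5, σ = 2), normalized to unit sum, applied with
  reflect padding; strict local maxima and minima of the smoothed
  series are counted and divided by elapsed time.
* Velocity is computed within strokes only — never across pen lifts.

A feature that cannot be computed (too few points for a bin, series
shorter than one spectral bin, no reference spectrum provided) is
flagged `insufficient_data`; it never receives a fabricated value, and
scoring omits it.

The entropy/correlation/distance features compare a writer to the
cohort, so cohort extraction is two-pass: collect every writer's
spectra, average them into the reference, then extract against it.

## Norm curves and feature scores

Per feature and gender, the reference population's mean is fitted as a
least-squares cubic of age (age continuous — handwriting evolves
faster than annually). Dispersion is fitted by taking SDs of the
residuals in 1-year age bins and passing a cubic through the bin
centers. Numerical safety:

* the SD curve is only evaluated inside the bin-center range it was
  fitted on (evaluation clamps to it): extrapolating a cubic even half
  a year beyond its support produced >25% dispersion errors in
  simulation;
* the SD is floored at 1e−6 × the cohort feature SD (1e−9 absolute
  for constant features) so z-scores stay finite;
* ages outside the fitted support are clamped to its boundary with a
  warning — norm curves must not be extrapolated;
* rank-deficient designs (fewer than 4 distinct ages) fall back to a
  lower polynomial degree with a warning.

Fitting requires ≥ 20 children per gender over ≥ 3 distinct ages and
uses the school-labeled rows (the reference population), falling back
to all rows when labels are absent. Norm models are country/curriculum
specific (school systems start handwriting at different ages); fit one
per cohort and persist it as JSON — there is deliberately no mixing
logic.

The score map e^(−α·Z^β) needs a calibration; α = ln 2, β = 2 makes a
child 1 SD from the norm score 0.5 and 2 SDs score 0.0625 — smooth,
strictly decreasing, and easy to explain. Both parameters are stored
in the model and configurable.

## Severity scales

The scale input is the matrix of *signed* standardized deviations
(value − f_mean(age)) / f_std(age) — not raw values (age and gender
effects would masquerade as handwriting variance) and not the bounded
scores (the exponential compresses exactly the tail the scale must
resolve). Sign is kept because principal axes need direction. The
matrix is standardized with the fitting cohort's per-feature center
and spread, projected on its 3 leading principal axes, and clustered
with K-means (k = 2, k-means++, 50 restarts, fixed seed). Fixing k = 2
keeps the clusters interpretable as typical/atypical writing.

The *typical* centroid is the one holding the majority of
school-labeled children (ties broken toward the larger cluster);
`d_ref` is the mean distance of school children to it. The global
score e^(−d / d_ref) is this package's choice of distance-to-score
map: bounded in (0, 1], equal to 1 exactly on the centroid and to
e^(−1) at the reference distance. Absolute score values are therefore
calibration-dependent and not comparable across differently fitted
scales; orderings and threshold semantics are.

Severity thresholds are set by rank counts over the reference scores:
the threshold for fraction p is the smallest reference score with at
least ⌈p·n⌉ scores at or below it, so realized fractions are exact for
distinct scores and can only overshoot (never undershoot) under heavy
ties. Quantile-interpolation variants were rejected for auditability.
The default fractions 2 / 8.6 / 15 / 25 % band the scale into five
levels (very severe, severe, moderate, light, typical); both the count
and the values are configurable — they are conventions, not facts
about handwriting. The number of retained axes is likewise
configurable, but changing it invalidates fitted thresholds (a warning
says so).

Sub-scales repeat the construction on one category's features;
`profile` combines global, category and per-feature scores.
`evaluate_clustering` reports sensitivity (fraction of
dysgraphic-labeled children in the atypical cluster) and specificity
(fraction of school-labeled children in the typical cluster).

## Synthetic data

The generator targets the *feature distributions* of real pen data, not
legible glyphs. A recording is 4 lines × 4 strokes × 440 samples at
60 Hz (~2 minutes of writing — long enough that even the 6 Hz
pressure/tilt rate series yield a complete 600-point spectral bin, so
all 62 features are finite), built from sinusoidal letter-like
oscillations advancing in x with in-air gaps between strokes.

Planted structure:

* baseline speed follows a cubic age trend (rising over ages 5–12, the
  default cohort age range) while speed variability and path tremor
  shrink with age; a small gender offset separates the per-gender norm
  curves;
* four per-writer deficit severities (0 = typical) monotonically
  distort their family: kinematic (velocity jitter and jerk, extra
  8–15 Hz path tremor, slower mean speed, longer pen lifts), pressure
  (larger SD, more sign inversions), tilt (wobblier angles), static
  (wavier lines, irregular letter size);
* cohorts draw ages uniformly, label writers school/dysgraphic, and
  give atypical writers log-normal per-category severity spread around
  the profile (default kinematic 3, pressure 3, tilt 1, static 1 —
  atypical writing differing chiefly in kinematic and pressure
  characteristics).

All randomness flows from one seed through spawned seed sequences;
identical seeds give byte-identical cohorts.

**What passing tests do and do not show.** The generator's populations
are well-separated by construction, so perfect cluster recovery on
synthetic cohorts demonstrates the pipeline's correctness, not a
clinical accuracy claim; real cohorts overlap (some school-recruited
children write poorly, and deficits are continuous, not planted).
Likewise the generator has no letter shapes, no orthography, no fatigue
drift, and its noise is stationary within a stroke — feature values are
plausible in scale and structure but not drawn from children.

## Problem sizes

The test suite fits norms on 400 writers per gender (table-level
simulation) and runs the trace-level pipeline on cohorts of 120–250
writers; the acceptance script uses 390 + 58 writers, mirroring a
realistic school-plus-clinic study. These sizes give stable estimates
for every fitted object (≥ 50 children per 1-year age bin at the norm
stage; ≥ 100 reference scores at the threshold stage).

## Known limitations

* No laterality-conditional norms (laterality is recorded but not
  modelled), and no longitudinal within-child modelling.
* The spectral frequency grid assumes the nominal sampling rate;
  recordings with heavy jitter around 60 Hz will smear spectra.
* Severity thresholds are reference-cohort quantiles: with very small
  or tie-heavy reference cohorts they are coarse (a warning is
  logged below 50 distinct scores).
* The deviation-space PCA is linear; strongly non-linear feature
  interactions would need a different embedding.
* Scores from differently fitted scales (different cohorts, axes or
  calibrations) are not comparable.
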