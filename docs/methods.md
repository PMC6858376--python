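# Methods

## The measurement problem

In highly myopic eyes the posterior wall bows backwards into a posterior
staphyloma. How sharply the wall curves at the fovea — not just how long
the eye is — appears to matter for which macular complication develops:
eyes with myopic traction maculopathy (MTM) have steeper foveal curvature
than eyes with myopic choroidal neovascularization (mCNV) or uncomplicated
high myopia, at comparable axial lengths. `staphycurve` implements the
measurement layer for that comparison: three per-eye curvature parameters
computed from the retinal pigment epithelium (RPE) line of fovea-centered
horizontal and vertical OCT B-scans, the eligibility rules of such a
study, and the group-comparison statistics — exercised end to end on
synthetic cohorts, because patient-level OCT datasets of this kind are not
publicly deposited.

The input is a per-eye pair of RPE elevation profiles z(x): lateral
position x in µm (fovea at 0; negative = nasal on horizontal scans,
inferior on vertical scans) and RPE elevation z in µm, increasing
anteriorly and re-centered so the subfoveal RPE sits at z = 0. Profiles
are assumed already traced (manual or automated segmentation is out of
scope).

## Magnification correction

Lateral distances on an OCT image are magnified by the eye's optics. The
package uses the single-variable Bennett-type correction

    t = 3.382 × 0.01306 × (AL − 1.82) × s

where s is the on-image measurement, t the actual dimension, and AL the
axial length in mm. The factor is exactly 1 at AL ≈ 24.46 mm and linear in
AL. Only the lateral coordinate is corrected; OCT axial (depth) sampling is
set by the interferometer, not by ocular magnification, so elevations are
taken as true after 1:1 µm conversion. All "3 mm from the fovea" landmarks
are interpreted in actual (post-correction) lateral µm. Re-applying the
correction is a state error, so it can never be applied twice.

## The three curvature parameters

**Staphyloma heights.** H_side = z(±3000 µm) − z(0), one per side (nasal,
temporal, superior, inferior), signed: negative exactly when the
peripheral RPE lies posterior to the subfoveal RPE (e.g. on the downhill
side of a tilted scan). Horizontal sum H_N + H_T, vertical sum H_S + H_I,
total = all four. For a pure parabola z = a·x² each height is a·3000² and
the horizontal sum is 2a·3000² exactly — a useful cross-check between
parameters.

**Coefficient a.** The profile is resampled by linear interpolation on the
fixed 21-point grid −3000, −2700, …, +3000 µm and a·x² + b·x + c is fitted
by ordinary least squares. a (µm⁻¹ with x in µm) measures steepness; the
fit is deterministic and recovers an exact quadratic to machine precision.
An `x_unit_scale` option rescales the abscissa before fitting for users
who need a in other export units (a scales as the inverse square); the
package default keeps everything in µm, which is the only internally
consistent choice — note that published magnitudes of a (~3–4.5 × 10⁻⁴)
and staphyloma heights (~1000–2600 µm) cannot both arise from one parabola
in µm units, so coefficient-a values from different sources are only
comparable within one unit convention.

**Curvature index.** The full-resolution polyline is clipped to
[−3000, +3000] µm with linearly interpolated endpoints; the index is the
polyline arc length divided by the Euclidean distance between the two
endpoints. The chord includes the elevation difference of the endpoints
(it is a straight segment in the scan plane, not a horizontal distance),
so a tilted straight profile still scores exactly 1.0. The index is ≥ 1
with equality iff the samples are collinear, is invariant under elevation
translation, and for a parabola equals
[u√(1+u²) + asinh(u)] / (2u) with u = 2aX, X = 3000 µm — the closed form
used as an independent oracle in the tests. The arc is measured on the
traced polyline, not on the fitted quadratic: the 300 µm grid exists only
for the polynomial fit, mirroring the two distinct procedures. On the
21-point grid the polyline underestimates the true parabola arc by < 0.1%
for a ≤ 2 × 10⁻⁴ µm⁻¹ (verified against quadrature), so grid density is
not a practical accuracy limit.

**Severity measures.** Foveoschisis height (MTM severity) is the ILM-to-RPE
distance at x = 0; with a full-thickness macular hole the ILM elevation at
the fovea is the straight bridge between the ILM at the two hole edges.
Subfoveal choroidal thickness is averaged over the two scan orientations.
CNV area (in disc areas) is carried as an input field.

## Eligibility rules

High myopia: axial length ≥ 26.5 mm (boundary inclusive) or spherical
equivalent ≤ −6.0 D. Pseudophakic eyes never qualify via refraction, since
post-surgical refraction no longer reflects the native eye; they are also
excluded from all refractive-error statistics.

Dome-shaped macula (an exclusion): an inward RPE bulge strictly greater
than 50 µm above a line tangent to the RPE at the bottom of the
staphyloma. The "presumed tangent" is operationalized as the lower convex
hull of the profile: a purely staphylomatous (convex) profile has zero
bulge by construction; a central dome lifts samples above the hull
segment bridging it, and the bulge is the maximum elevation above that
hull. The construction is invariant under elevation translation and
lateral reflection, and the threshold is a strict inequality (a 50.000 µm
bulge does not qualify). One geometric subtlety: a broad dome is partly
absorbed by the staphyloma's own convexity, so the measured bulge is
smaller than the dome's nominal amplitude (numerically, a 60 µm Gaussian
dome of σ = 600 µm on an a = 7 × 10⁻⁵ µm⁻¹ staphyloma bulges < 1 µm above
the hull). The measured bulge, not the generative amplitude, is what the
clinical rule thresholds.

Remaining exclusions (coexisting exudative disease, prior buckle, both
MTM and mCNV, extrafoveal staphyloma, prior treatment, poor image quality)
are chart-review judgements carried as input flags. After screening, one
eye per patient is kept — the right eye whenever both qualify.

## Synthetic cohorts

Two generator modes, deliberately separate (see the unit note above):

**Metric-level** cohorts draw per-eye clinical variables and curvature
parameters directly from per-group distributions whose defaults are the
published three-group summary statistics (n = 72/58/69; e.g. MTM total
height 2614.0 ± 944.3 µm, coefficient a × 10⁴ 4.33 ± 2.35, curvature index
1.066 ± 0.048; categorical frequencies for sex, staphyloma type, myopic
maculopathy category, pseudophakia). Bounded variables (index ≥ 1,
coefficient ≥ 0, thicknesses ≥ 0) are lower-truncated Gaussians whose
underlying location/scale are solved numerically so that the *truncated*
distribution has exactly the configured mean and SD — the configured
numbers are observed sample moments, so the generator must realize them
as moments; naive truncation at the printed location would, for example,
bias the MTM curvature-index mean upward by ≈ 0.008. The three curvature
parameters share a Gaussian copula with pairwise correlation 0.65 by
default; this is a documented stand-in motivated by the strong published
pairwise correlations (r ≈ 0.63–0.70), not an estimate — per-group
covariances were never published. Per-side heights are fixed fractions of
the drawn total (the published side means), and orientation splits use the
published horizontal/vertical half-differences, clipped so both
orientation indices stay ≥ 1. Foveoschisis height (350 ± 150 µm) and CNV
area (1.2 ± 0.8 disc areas) are clinically plausible choices, as no group
summaries were published for them.

**Geometry-level** cohorts build actual RPE polylines
z(x) = a·x² + tilt·x + dome(x) + noise, centered so z(0) = 0 before noise,
over ±3300 µm at 50 µm spacing, and feed them through the full measurement
pipeline. Defaults: a ∈ [5 × 10⁻⁵, 1 × 10⁻⁴] µm⁻¹ (which reproduces
realistic heights of ~900–1800 µm per orientation and indices of
~1.015–1.06), tilt ∈ ±0.05, Gaussian dome σ = 150 µm when present,
tracing noise 5 µm SD. At that noise level the recovered coefficient is
unbiased to < 1% over 500 replicates.

What the generators emulate: the marginal group statistics, the positive
inter-parameter correlation, the parabola-dominated staphyloma shape with
tilt, dome perturbation and tracing noise, and seeded byte-identical
reproducibility. What they do not emulate: real segmentation artefacts,
spatially correlated tracing error, asymmetric or multi-lobed staphylomas,
the rectangle-transform distortion of B-scan geometry, and any
patient-level covariance beyond the three-parameter copula. Passing tests
therefore demonstrate the correctness of the measurement and statistics
machinery under the published distributional conditions, not clinical
validity on real OCT data.

## Statistics

Continuous variables: classical one-way ANOVA (zero within-group variance
is flagged degenerate rather than raised); post-hoc pairwise Student
t-tests (equal-variance, the SPSS-era default; Welch available) with
Bonferroni adjustment — raw p × number of pairs, capped at 1. Categorical
variables: Pearson chi-square without continuity correction and without
exact tests, which reproduces the published table p-values exactly
(0.418, 0.592); expected counts below 5 produce a warning, not a switch
to an exact test. Correlations: Pearson with two-sided t-based p
(Spearman available) — the published scatter-with-regression-line
presentation implies Pearson, but this is a documented default, not an
asserted fact about the original analysis. Refractive-error rows exclude
pseudophakic eyes; foveoschisis correlations are restricted to MTM and
CNV-size correlations to mCNV.

A note on power: under the published group means/SDs and sizes, the
expected noncentrality of the curvature-index ANOVA is λ ≈ 20.5, which
gives ≈ 0.80 power at α = 0.001 (≈ 0.99 at α = 0.05). A single synthetic
cohort therefore usually, but not always, reproduces the headline
p < 0.001; simulations in the acceptance suite report the honest
replicate rate rather than assuming it is 1.

## Numerical choices

- Linear interpolation everywhere a profile is read between samples;
  never extrapolation (out-of-span queries are errors naming the span).
- Quadratic fit via `numpy.linalg.lstsq` on the raw Vandermonde columns;
  at 21 points over ±3000 µm conditioning is harmless and exact
  quadratics are recovered to ~1e-15 relative.
- Height identities (horizontal = nasal + temporal, etc.) are enforced as
  validation invariants at 1e-6 µm; curvature indices are validated ≥ 1.
- Degenerate inputs: axial length ≤ 1.82 mm is a domain error for the
  magnification formula; all-zero contingency rows/columns, zero-variance
  correlations and < 2-point groups are validation errors.
- All randomness flows from `numpy.random.default_rng` seeds; the
  pipeline splits one root seed per stage via SHA-256, and cohort files
  written twice from the same seed are byte-identical.

## Problem sizes

Simulated cohorts in tests and the acceptance script use the published
group sizes (72/58/69); replicate counts are 200 for the ANOVA
separation-rate check, 400–500 for unbiasedness/type-I-error checks, and
10,000 for sampler moment convergence — sizes chosen so Monte-Carlo error
is well below each assertion's tolerance.

## Known limitations

- Only the macular ±3 mm window is quantified; staphyloma curvature
  beyond the scan (3–6 mm) is known to carry additional signal.
- The single-variable magnification formula ignores corneal power and
  lens status; whether the original landmarks were placed before or after
  magnification correction is not documented, so the post-correction
  interpretation used here is a stated convention.
- The RPE polyline is treated as a single curve; inner vs. outer boundary
  of the hyperreflective band is left to the data producer.
- Metric-level synthetic cohorts reproduce printed group *moments*, not
  patient-level joint structure; conclusions about correlation magnitudes
  beyond the configured copula are outside what the generator supports.
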