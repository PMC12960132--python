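# Methods

This note documents the models, estimators and design choices behind
`facenorms`, and what the synthetic-data presets do and do not emulate.

## Geometry and measurements

Coordinates are right-handed, in mm: +x toward the subject's anatomical
right, +y superior, +z anterior.  The default landmark template has 19
midline and 25 paired (left/right) landmarks; a measurement registry
maps landmark tuples to scalar values.  Four kinds are supported:

- **distance**: Euclidean norm between two landmarks; bilateral
  definitions are computed per side and averaged;
- **angle**: interior angle at the middle of three landmarks (degrees);
- **depth**: signed distance from a reference plane (midsagittal by
  default);
- **asymmetry**: distance between the left landmark and the mirror
  image of the right landmark across the midsagittal plane, so a
  perfectly symmetric pair scores 0.

The midsagittal plane is the total-least-squares plane through the
usable midline landmarks (SVD of the centred coordinates; the normal is
the direction of least spread, oriented toward +x).  At least three
non-collinear midline points are required; collinearity is detected via
the second singular value.

Depth and asymmetry conventions are this package's own definitions:
clinical tools report these measurement kinds without publishing their
formulas, so the implementations here are standard geometric
constructions rather than verified equivalents of any particular tool.
The shipped registry contains eight Farkas-style interlandmark
distances (palpebral fissure length ex–en, innercanthal width en–en,
bizygomatic width zy–zy, nasal protrusion sn–prn, nasal bridge length
n–prn, facial height n–gn, labial fissure width ch–ch, philtral length
sn–ls); users can extend it to a fuller measurement battery.

Placement QC compares a candidate landmark set against ground truth and
fails iff any per-landmark Euclidean discrepancy **strictly** exceeds
5.0 mm ("more than 5 mm" read as exclusive; a discrepancy of exactly
5 mm passes).  An excluded landmark invalidates only the measurements
that reference it.

## Growth-curve references

For each (measurement, sex) stratum with at least `min_stratum_n = 30`
usable records (the per-band minimum the power calculation supports),
the mean value as a function of age x is fitted by least squares over
five candidate families: exponential decay `y = a(c − e^(1−bx))` and
polynomials of degree 1–4.  The study design is cross-sectional (one
record per subject), so plain regression — not longitudinal mixed
models — is the appropriate tool.

**Exponential-decay fitting.**  The model is linear in `(a·c, a)` once
b is fixed, so fitting is a 1-D profiled minimisation over b: closed
form 2×2 normal-equation solves on a log-spaced grid b ∈ {0.05…2}
(25 points) followed by bounded scalar refinement between the
neighbouring grid points (tolerance 1e-10).  On noiseless
family-generated data this recovers coefficients to ~1e-4 with RSS
below 1e-8, verified against an independent brute-force grid-search
oracle.  Growth rates in that grid cover times-to-plateau from a few
months to decades, which spans craniofacial growth.

**Selection.**  The default criterion in `select_model` is minimum RSS
with ties broken toward fewer coefficients, mirroring the simplest
reading of "minimise residual error".  Raw RSS is degenerate across the
nested polynomials (the quartic can never lose), so the pipeline's
default configuration uses AICc, under which the exponential-decay
family wins on exponentially-shaped growth data — consistent with prior
comparative model-fitting in craniofacial measurements, where models
with an exponential early-childhood component perform best.  Both
criteria are exposed.

**Age-varying SD.**  Residual spread varies with age because sampling
density and growth-phase variance do.  `SD(g) = sqrt(Σᵢ wᵢ rᵢ² / Σᵢ wᵢ)`
with Gaussian weights `wᵢ = exp(−((xᵢ−g)/h)²/2)` on a 0.5-year grid
over the sampled range; bandwidth h defaults to 2.0 years — narrow
enough to track the childhood-to-adult variance transition, wide enough
that a 30-per-band cohort keeps tens of effective points per grid age.
Grid points whose Kish effective sample size falls below 3 are flagged
low-confidence rather than dropped.  Beyond the sampled range the
profile clamps to its edge values and assessments are marked
extrapolated.

**Outlier loop.**  Points with |residual| **strictly** above 3·SD(age)
are flagged; the study workflow this models sent such cases back for
landmark re-appraisal, which software cannot do, so flagged points are
excluded and the model refitted.  The loop runs to a fixed point (no
new flags; at most `max_iter = 5` passes).  Under Gaussian noise ~0.3%
of clean points are expected beyond 3 SD, so a handful of legitimate
removals per large stratum is normal; injected gross outliers (10 SD)
are removed completely in one or two passes.

**Confidence bands.**  Whether the original CIs were analytic or
resampled is not documented, so the package uses a subject-level
nonparametric bootstrap (default B = 500): resample rows with
replacement, refit the selected family, and take the percentile band of
the refitted curves at each grid age (half-width = half the 2.5–97.5
percentile distance).  More than 10% refit failures aborts with an
error.  Simulated coverage at n = 760 and σ ≈ 7 mm is 96% over 200
replicates (nominal 95%), computed by the test suite.

**Sample size.**  Under the one-sample normal approximation, resolving
a mean shift of `effect_sd` SDs needs
`n = ⌈((z₁₋α + z_power)/effect_sd)²⌉` usable subjects, inflated by the
expected fall-out rate: `⌈n/(1−fallout)⌉` recruits.  The one-sided form
is used because with the defaults (α = 0.05, power = 0.80,
effect = 0.5 SD, fall-out 15%) it yields 25 usable → 30 recruited per
age/sex band, the planning figure the pipeline enforces as
`min_stratum_n`; the two-sided variant gives 38.

## Assessment

`z = (value − mean(age)) / SD(age)` with the SD interpolated linearly
on the profile grid.  Displayed Z-scores round half away from zero to
one decimal.  A measurement is flagged atypical iff `|z| > 2`
**strictly** (±2 SD bounds ≈95.45% of a normal population, so
in-distribution subjects flag each measurement at ≈4.6%).  One flag per
measurement at most; richer multi-criterion trait inference used by
clinical software is unpublished, so only the 2 SD criterion is
implemented.  The flag labels are an illustrative, editable
phenotype-term table in the style of Human Phenotype Ontology terms —
not the ontology itself — with a "decreased/increased <measurement>"
fallback.  Bilateral measurements are assessed on their bilateral mean.

Comparing two reference sets scores every subject under each and
reports per-subject flag counts with medians and ranges (even-sized
medians are the central-pair midpoint).  No significance test is
attached.

## Synthetic cohorts

The generator draws age from a mixture — uniform(0, 18) with weight
`w_child = 0.86`, uniform(18, 55) otherwise — matching a pediatric-heavy
recruitment (≈86% under 18); sex is Bernoulli(0.5).  Each measurement
is its sex-specific exponential-decay curve plus Gaussian noise with the
preset's (possibly age-varying) SD.  Gaussian noise is consistent with
SD-based thresholds bounding ≈95% at ±2 SD.  Distance values are
clipped at 0 mm (relevant only at ~1e-4 probability for the smallest
measurement).  Everything is deterministic under the cohort
specification's seed, to the byte in the TSV output.

**Chinese preset calibration.**  The female bizygomatic curve is
(birth 78 mm, asymptote 125 mm, rate 0.181/yr); the male curve is the
exponential decay passing exactly through female + {3.5, 5.2, 7.2} mm
at ages {5, 10, 15} (asymptote 135.81, drop 52.09, rate 0.1365).
Bizygomatic SD interpolates the anchor triples (6.8, 6.6, 6.7 mm female
and 7.4, 7.2, 7.6 mm male at ages 5, 10, 15).  The palpebral-fissure
curves share drop and rate so the male-minus-female gap is exactly
1.0 mm at every age.  The remaining six measurements use
field-realistic birth/adult values and rates at the Farkas scale of
magnitude; they anchor nothing quantitative downstream.

**European preset.**  Chinese curves plus uniform vertical offsets in
the direction of published cross-ancestry comparisons — bizygomatic
−8 mm (narrower), palpebral fissure +2.6 mm, innercanthal +4 mm, nasal
protrusion +3 mm, nasal bridge +4.5 mm, facial height and labial
fissure 0 — and a faster philtral growth rate (0.28 vs 0.15/yr, same
birth and adult values).  A vertical shift keeps the exponential-decay
form exactly.  Magnitudes are configurable; the defaults are set at
1–2 residual SDs so the two references are clearly separated, as the
published comparisons describe, without being caricatures.  They are
this package's constructions, not reprinted external reference tables.

Preset defaults use no injected outliers and no fallout: the modelled
data stream is the *corrected* measurement table (gross placement
errors re-appraised upstream, unusable images already screened).  Both
injection mechanisms exist and are exercised by tests with explicit
rates; the 15% fall-out figure enters the power calculation as a
recruitment-planning assumption rather than a generated data property.

A subject's drawn measurement values can be realised as a 3D landmark
set: the symmetric template face is scaled isotropically to the
subject's overall size, then the landmarks referenced by the eight
shipped measurements are repositioned along template directions so each
target is met exactly (round-trip error < 0.1 mm through the
measurement code; optional Gaussian placement noise on top).  Unusable
records are represented by excluding one operand landmark.

**What the generator does not emulate.**  Real cohorts have non-uniform
per-year age histograms, measurement-to-measurement correlation within
a face (the generator draws measurements independently given age and
sex), non-Gaussian tails, secular trends, and landmark errors that are
spatially correlated on the surface.  Passing tests therefore validate
the estimators under the stated statistical model, not the biology of
any real population.

## Problem sizes and numerical choices

Validation experiments use 10 cohorts of 760 subjects (the scale of a
single-ancestry pediatric cohort), 200 replicates at B = 500 for
bootstrap coverage, 2 000 subjects for flag-rate calibration, and 100
subjects for the reference-switch direction check.  Seed-averaged
recovery of the dimorphism anchors is accurate to ~0.1–0.4 mm; a single
760-subject cohort carries ≈0.45 mm standard error on a fitted
bizygomatic mean at one age (residual SD ≈7 mm, ≈380 per sex), which is
why per-seed sub-0.5 mm claims are only meaningful for low-noise
measurements such as palpebral fissure length (SD 1.3 mm).

Ties and boundaries are all strict by construction: QC fails strictly
above 5 mm, outliers strictly above 3 SD, flags strictly above 2 SD.
RSS ties in model selection are resolved within a 1e-9 relative margin
toward fewer coefficients.  Ages are decimal years (written to 3
decimals); reference JSON round-trips all coefficients and grids to
better than 1e-9.

## Known limitations

- The registry ships 8 of the ~58 measurements a full clinical battery
  extracts; the machinery is measurement-agnostic but the presets only
  calibrate these 8.
- Outlier handling excludes rather than re-appraises; if many outliers
  were in truth correctable placements, reference SDs are slightly
  underestimated.
- Quantile-based reference methods (LMS/GAMLSS) are out of scope; the
  package models mean + SD under approximate normality.
- Cross-ancestry offset magnitudes in the European preset are
  calibrated choices, so cross-preset experiments demonstrate direction
  and mechanism, not published effect sizes.
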