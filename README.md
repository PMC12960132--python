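# facenorms

Normative craniofacial anthropometry from 3D facial landmarks.

Clinical dysmorphology screens an individual's facial measurements
against population reference ranges, and those ranges are strongly
ancestry-specific: a child scored against norms derived from a different
ancestry group can accumulate spurious "atypical" findings.  `facenorms`
is a library for building and using such reference ranges.  It is aimed
at researchers constructing population-specific 3D-facial norms
(e.g. from pediatric photogrammetry cohorts) and at anyone who needs a
tested, reproducible implementation of the associated statistics.

The package covers the full workflow:

1. **Anthropometry** — interlandmark distances, angles, depths and
   left/right asymmetries from 3D landmark coordinates (19 midline + 25
   paired landmarks by default; 8 named Farkas-style measurements ship,
   the registry is user-extensible), with a 5 mm placement-QC rule and
   per-landmark exclusion that propagates only to dependent
   measurements.
2. **Reference construction** — per measurement and sex, the expected
   value as a function of age is fitted by least squares over five
   candidate families

   - exponential decay `y = a(c − e^(1−bx))`,
   - linear, quadratic, cubic, quartic polynomials,

   selected by residual sum of squares (tie to fewest coefficients) or
   AICc.  Residual SD varies with age and is estimated with a Gaussian
   kernel (`SD(x) = sqrt(Σ wᵢ rᵢ² / Σ wᵢ)`); points beyond 3 SD of the
   fitted mean are excluded and the model refitted to a fixed point; a
   subject-level bootstrap gives 95% confidence bands for the mean
   curve.  A power helper reproduces the per-age/sex-band sample size
   (half-SD effect, one-sided 5%, 80% power, 15% fall-out → 30
   recruits).
3. **Assessment** — age- and sex-matched Z-scores
   `z = (value − mean(age)) / SD(age)`; measurements with `|z| > 2`
   (±2 SD bounds ≈95% of a normal population) are flagged with
   phenotype-style labels, and cohorts can be compared across two
   reference sets to quantify the effect of switching references.
4. **Synthetic cohorts** — a calibrated generator (Chinese- and
   European-ancestry presets) that inverts the model above, so every
   stage is testable end to end without patient data.

## Worked example

`examples/02_fit_reference_curves.py` simulates a 760-subject
pediatric-heavy cohort from the Chinese-ancestry preset and fits per-sex
bizygomatic-width references:

```
sex M: expdecay model on 387 subjects, 0 outliers removed
sex F: expdecay model on 369 subjects, 4 outliers removed
  age    5: M-F fitted bizygomatic gap = 2.34 mm (male 95% CI half-width 1.03 mm)
  age   10: M-F fitted bizygomatic gap = 4.44 mm (male 95% CI half-width 0.99 mm)
  age   15: M-F fitted bizygomatic gap = 7.03 mm (male 95% CI half-width 0.96 mm)
  female SD profile at age 10: 6.39 mm
```

The exponential-decay family wins model selection in both sexes; the
fitted male-minus-female facial-width gap grows through childhood toward
the preset's calibrated 3.5/5.2/7.2 mm anchors at ages 5/10/15 (a single
cohort recovers them with ~0.5 mm sampling error; averaging seeds
tightens this), and the age-10 female SD estimate sits near the preset's
6.6 mm.  The other examples cover landmark measurement (`01`), scoring
an individual (`03`, printing Z-scores and the one flagged trait),
the reference-switch experiment (`04`, median flags per subject dropping
from 2.0 to 0.0 when the ancestry-matched reference is used), and
power/QC (`05`).

A thin CLI mirrors the workflow for shell use:

```sh
facenorms simulate --preset chinese --n 760 --seed 1 --out cohort.tsv
facenorms fit-reference cohort.tsv --seed 1 --out ref.json
facenorms assess subjects.tsv --reference ref.json --out reports.json
facenorms compare subjects.tsv --reference-a eu.json --reference-b cn.json --out cmp.tsv
facenorms report ref.json --out-dir plots/
```

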