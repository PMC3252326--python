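# Methods

## Reference frame and component decomposition

The frame is built from the three midsagittal skull landmarks only, so
the measurement is external to (and unbiased by) the endocast. The
anterior axis is the unit vector from inion to glabella along L1; the
origin is the orthogonal projection of basion onto L1; the superior axis
is the unit vector from basion to that origin (L2 is taken as the unique
perpendicular from basion to L1 — the only line through basion orthogonal
to L1 that stays in the midsagittal plane); the right axis is
anterior × superior. G, I and B are midsagittal and cannot distinguish
left from right, so the right axis is oriented by a labelled right-side
pole (RFP, falling back to ROP); a warning is emitted if another
right-labelled pole then lands on the negative side, which usually means
swapped labels during digitisation.

Signed components are differences of pole-pair projections: frontal AP
positive when the right pole is more anterior, occipital AP positive when
the right pole is more *posterior* (each lobe's protrusion direction),
vertical positive when the right pole is more superior, lateral positive
when the right pole lies farther from the midplane. The construction is
rigid-motion equivariant, so components are invariant under any rotation
plus translation of the specimen (asserted to < 1e-9 mm over random
motions) and flip sign under mirror reflection with R/L label swap.

The "lateral position of the poles" is computed as the mean of the two
unsigned distances to the midplane; it is reported both raw (mm) and
size-corrected, since the published group means are interpretable either
way.

Degeneracy tolerances: 1e-6 mm for |G−I| and the basion-to-L1 distance;
a relative 1e-9 of the configuration scale for the midplane/orientation
check. Coordinates are unitless floats interpreted as mm; no unit
auto-detection is attempted.

## Size correction

EV is supplied in cc and converted to mm³ before the cube root, so
`x / (1000·EV)^(1/3) · 100` is dimensionless and invariant under
isometric scaling. This convention reproduces the published raw/corrected
FA11 pair (19.2 mm at ~1400 cc → ≈ 17.2) to about 1%, which is why cc→mm³
conversion (rather than the cube root of cc) is used.

## Asymmetry tests and classification

* **DA**: two-tailed one-sample t-test of mean (R − L) = 0 — the standard
  reading of a mean-departure test in the fluctuating-asymmetry
  literature. Because normality of (R − L) is itself part of the FA model
  a nonparametric alternative (Wilcoxon signed-rank) is available behind
  `da_test="wilcoxon"`.
* **Skewness / kurtosis**: bias-corrected g1 and g2 with large-sample
  standard-error z tests (SE(g1) = √(6n(n−1)/((n−2)(n+1)(n+3))),
  SE(g2) = √(24n(n−1)²/((n−3)(n−2)(n+3)(n+5)))). Kurtosis is tested
  one-tailed in each direction; antisymmetry is flagged by the
  platykurtic tail only. Printed critical-value tables used historically
  for these tests are not reproducible from available sources, so the
  normal approximation is used and recorded in the report metadata; at
  the group sizes involved (n ≥ 45) the approximation is adequate, and
  the type-I calibration is verified by simulation in the test suite.
  Both tests require n ≥ 8.
* **Multiple testing**: Holm step-down within the family of six traits,
  separately per test type (DA family, skewness family, platykurtosis
  family), implemented via `statsmodels.stats.multitest`.
* **Verdicts**: DA if the Holm-adjusted DA p < α; antisymmetry if the
  adjusted platykurtosis p < α; both → "DA+antisymmetry"; otherwise FA.
  FA1/FA4a carry a bias flag whenever DA or antisymmetry is detected,
  since both indices overestimate developmental noise in that case.
* **Ties** (R − L = 0 exactly): excluded from the %R/%L denominators so
  the two percentages sum to 100, and reported as a separate count.
* **Missing traits**: complete-case per statistic — a specimen missing a
  pole pair drops out of that trait's tests and out of FA11 (which is
  computed over specimens complete for all six traits), mirroring fossil
  samples where frontal and occipital subsamples differ.

## Comparative layer

Hotelling's two-sample T² uses the pooled covariance and the exact F
conversion; Mardia's multivariate skewness/kurtosis (χ² and normal
approximations) and Box's M (χ² approximation) are reported as
assumption diagnostics. All multivariate procedures refuse to run when
the pooled covariance condition number exceeds 1e10, protecting
fossil-sized groups from numerically meaningless answers. Sex comparison
reuses the same T² on male/female submatrices. Grubbs' outlier test uses
the two-sided single-outlier statistic with the exact t-based critical
value; iterative removal is opt-in. Fronto-occipital patterns are scored
from the signs of the two AP components; zero or missing components
leave a specimen "undetermined" and excluded from the four-category
percentages (which therefore sum to 100 over determined specimens).

## Synthetic cohorts

Per-trait (R − L) draws: FA → N(0, σ); DA → N(μ, σ); antisymmetry → a
balanced mixture of N(+μ, σ) and N(−μ, σ), the minimal model in which
the larger side varies randomly among individuals. The ±3σ balanced
mixture has population excess kurtosis (138/100 − 3) = −1.62, which the
platykurtosis screen detects essentially always at n = 110.

Each specimen is realised geometrically in a canonical skull frame
scaled by ∛EV (G and I at ±0.75·∛EV on the AP axis, B below the origin),
with poles placed so the six drawn components and the two pole positions
are met exactly, then passed through a seeded Haar-random rotation and
translation. A single global seed spawns a per-specimen seed sequence
(`numpy` `SeedSequence.spawn`), so cohorts are bit-reproducible and
stable under partial regeneration. If a drawn lateral component would
put a pole across the midplane, the pole-pair distance is widened to
|lat|/2 + 0.5 mm; direct calls with explicit infeasible targets raise
instead.

### Preset calibration

Presets are *emulations*: raw specimen coordinates are unpublished, so
parameters are chosen to echo the published group-level anchors, not to
reproduce individuals.

| preset | n | EV (cc) | trait σ (mm), order (f_ap, f_vert, f_lat, o_ap, o_vert, o_lat) | DA effects |
|---|---|---|---|---|
| AMH | 45 | 1400 ± 120 | 2.7, 3.5, 4.5, 2.7, 3.5, 4.5 | o_ap μ = −2.7 (−1.0σ), o_lat μ = +3.6 (+0.8σ) |
| GA | 110 | 380 ± 60 | 1.45, 2.2, 2.0, 1.45, 1.9, 2.3 | o_ap μ = −0.44 (−0.30σ), o_lat μ = +0.40 (+0.17σ) |
| fossil | 23 | 1100 ± 300 | 2.1, 2.7, 3.5, 2.1, 2.7, 3.5 | o_ap μ = −2.1, o_lat μ = +2.8 |

σ values are set so the expected FA11 (Σ E|R−L|, with
E|N(μ,σ)| = σ·[√(2/π)·e^(−d²/2) + d·(2Φ(d)−1)], d = |μ|/σ) lands at the
published group levels of roughly 19.2, 9 and 15 mm, and so the
magnitude ordering of trait FA1 values (lateral > vertical > AP in
humans; vertical-dominant frontal petalia in apes) is respected. EV means
span the published ~4× volume range; within-group EV spreads are not
published and are plausible assumptions (wide for the heterogeneous
fossil sample). Pole-position anchors (7.4/10.7 AMH, 5.5/14.4 GA,
6.6/13.8 fossil, size-corrected units) come from the published group
means.

The AMH occipital DA effect sizes are a deliberate design choice: the
published side frequencies (77%L AP, 73%R lateral) would imply
|μ|/σ ≈ 0.74 and 0.61, under which exact six-trait classification
recovery at n = 45 with Holm correction has only ~85% probability. The
preset instead uses −1.0σ and +0.8σ — keeping the AP effect the stronger
of the two — which yields ≥ ~95% recovery while implying side
frequencies of ~84%L / ~79%R. Passing recovery tests therefore
demonstrates the pipeline's power at these calibrated effect sizes, not
the parameters of any real population. A related consequence: with
frontal AP generated as pure FA (mean zero), the two left-occipital
patterns RF/LO and LF/LO are equiprobable in the AMH preset (~42% each),
whereas real human samples show a right-frontal bias that makes RF/LO
modal; emulating that would require a sub-threshold frontal DA, which
would conflict with recovering "FA" on that trait.

## Problem sizes and numerics

The simulation-based checks run at the sizes that make their claims
meaningful: 10⁶ draws for the FA4a constant (agreement with FA1 within
0.5%), 10,000 replicates for DA type-I calibration at n = 45 (binomial
99% band around α = 0.05), 1000 replicates for the antisymmetry screen
at n = 110, 1000 random cohorts for the geometric round-trip (max error
well below 1e-6 mm; observed ~1e-13) and 100 end-to-end cohorts for AMH
preset recovery. All randomness flows from explicit seeds; reports embed
config, seed, package version and per-test method metadata, and repeated
runs are byte-identical.

## Known limitations

* Skulls are reduced to seven landmarks; no surface geometry, Procrustes
  superimposition or semilandmarks, and no modelling of landmark
  placement error (repeatability ANOVA is out of scope).
* The generator's skull is a schematic frame, not a biomechanically
  realistic shape; only the quantities the pipeline measures are
  realistic. Allometry beyond ∛EV scaling is not modelled.
* The g1/g2 normal-approximation tests are slightly conservative for
  platykurtosis at moderate n (the left tail of the g2 sampling
  distribution is light), so antisymmetry false-positive rates run below
  nominal α.
* Group comparisons assume independent specimens; no phylogenetic
  correction.
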