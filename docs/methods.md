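# Methods

This note documents the models behind `rescover`: what the synthetic
data generator emulates, how each measurement chain is implemented, the
parameters that matter, and the numerical conventions.

## The measurement problem

A plot's crop residue cover (percent of soil surface covered by straw
or stover) determines conservation-agriculture adoption status at the
conventional 30 % threshold, with graded classes 30–60, 60–90 and >90 %
used in international statistics. The package emulates a
method-comparison experiment: seven measurements of the same quantity
per plot — a line-transect benchmark (LT), four survey instruments
(M1–M4), a drone image-processing estimate (M5) and a satellite tillage
index (M6) — over 314 plots belonging to 197 households in five
enumeration areas.

## Survey generator

### Margins

The benchmark margin is `100 · Beta(a, b)` with `a = 3.133872`,
`b = 2.193869` — the unique solution of the two calibration constraints
*median = 60 %* and *P(cover > 90 %) = 4 %*, solved once with a root
finder and frozen in `config.py`. The support reaches both 0 and 100.

Every other method's margin is a strictly monotone power transform of
the same Beta quantile:

    Q_m(u) = 100 · Q_beta(u)^γ_m,   γ_m = ln(med_m/100) / ln(0.6)

which places each method's median exactly at its calibrated offset
(M1 = 30, i.e. 30 points under the benchmark; M2 = 32.5; M5 = 55;
M6 ≡ LT) while keeping the support (0, 100) and introducing no ties —
important because rank correlations are a calibration target. A
shift-and-clip margin would have produced an atom at zero and biased
sample Spearman correlations downward. The published record fixes only
these median statements, so margins beyond them (e.g. M3's centre,
set equal to M1's) are conventions, not data.

The visual-aid instruments (M3, M4) report one of six ordered
categories. The reference-photo scheme is not published; the package
uses cut points {10, 25, 40, 60, 80} % with reported category values
{5, 17.5, 32.5, 50, 70, 90} — a monotone scheme whose category values
bracket the 30 % adoption threshold (two categories below, four above).

### Dependence

The only published dependence information is the 7×7 Spearman matrix,
so the joint law is the minimal completion consistent with it: a
Gaussian copula. For continuous margins the copula parameter that
yields rank correlation ρ_s is exactly ρ = 2 sin(πρ_s/6). For a
discretised margin the ties shrink attainable Spearman correlation, so
the parameter is calibrated by bisection against a Monte-Carlo
evaluation of the post-discretisation Spearman (default 300,000 draws
per iteration, tolerance 0.0025, seeded and repeatable); the LT–M4
target of 0.76 calibrates to ≈ 0.80, against a continuous-link value of
0.775 and an attainable maximum of ≈ 0.96. Unattainable targets fail
loudly with the attainable maximum reported.

The full 7-method matrix assembled entry-wise from the pairwise map is
not guaranteed positive definite; it is repaired by alternating
projections (eigenvalue clipping / unit-diagonal restoration, in the
spirit of Higham's algorithm). For the calibrated matrix the repair
moves no pairwise entry by more than 0.05. Bivariate draws — used for
all calibration checks — bypass the repair entirely.

### Measurement error

Covariates drive measurement error through two channels that both
preserve margins exactly (so the calibrated medians and tails are
untouched at any modulation strength):

1. **Attenuation.** Each survey method's latent normal score is blended
   with fresh noise, `z' = √(1−λ_i) z + √λ_i ε`, with the noise load
   λ_i a logistic function of standardised log field size (+),
   standardised log distance (+, interviewee methods only) and slope
   severity (−), centred so the average load is modest
   (`noise_base = −2.2`, coefficients 0.8). M6 instead loads on
   vertisol soils (moist dark clays perturb SWIR reflectance); M5 is
   left unmodulated because its error process is physical and is
   emulated by the imagery modules instead.
2. **Misreporting.** Interviewee methods (M1, M3) additionally report
   the wrong side of the 30 % adoption threshold with probability π_i,
   log-linear in the same covariates (base rate 0.25, coefficients 0.9,
   0.9, −1.5, clipped at 0.9). The swap reflects the latent percentile
   across the threshold's quantile with a measure-preserving map; for
   M1 the threshold coincides with the median, so the margin is
   preserved exactly.

The second channel exists because attenuation alone cannot produce
strongly detectable covariate effects: with the M1 margin centred 30
points below the benchmark, the misclassification probability ranges
only from 0.43 (full coupling) to 0.50 (independence), leaving too
little dynamic range for a regression at n = 10,000 to resolve three
simultaneous effects reliably. Adding a threshold-crossing misreport
channel widens the range to ≈ 0.57 and makes the configured signs
(field size +, distance +, slope −) recoverable with |t| > 2 across
seeds. Channel magnitudes are design constants of the generator, fixed
in `GeneratorConfig`.

A consequence worth stating plainly: the *realised* rank correlations
in a generated survey table sit below the population inputs for the
modulated methods (LT–M1 around 0.3–0.45 at n = 314 rather than 0.60).
The population dependence targets are properties of the copula
machinery (verified on unmodulated bivariate draws); the survey table
is the error-afflicted experiment built on top of it.

### Covariates, counts, missingness

Counts follow the experiment: 197 households (first 117 contribute two
plots, the rest one → 314 plots), five enumeration areas, M5 observed
on 182 plots and M6 on 251, missing completely at random with exact
subset sizes. Covariate centres follow the published sample means
(field size 2139 m², distance 433 m, farm 1.2 ha, head age 46.2,
education 3.3 y, herd 2.8 TLU, 49.4 % male heads, 50 % trained; soil
and residue shares as published). Dispersions are not published; field
size and distance are log-normal with σ = 0.5 and 0.55 — a realistic
smallholder spread chosen once, with the practical benefit that
raw-scale regressors are not dominated by a handful of extreme plots.
Slope shares (50/35/15 flat/slight/steep), the 20 % rocky-plot share
and a Poisson(1) phone count are likewise unpublished conventions.

### Repeat-visit decay

The benchmark's reliability check — re-measuring fields after two
months — is emulated by multiplying cover by (1 − d) with d drawn from
a Beta distribution with mean `decay_mean` (default 0.25) and standard
deviation `decay_sd` (default 0.10). The reduction is always in (0, 1),
so the second visit never exceeds the first, and the mean proportional
reduction equals the configured 25 % exactly in expectation. With
`decay_sd = 0` the reduction is deterministic.

## Imagery

### Drone scenes

Straw strokes (hard-edged rotated rectangles, no anti-aliasing) are
stamped onto a soil canvas until the counted cover reaches the target;
a final-stroke trim guarantees |true − target| ≤ 1 point, and the
stored cover is always the counted one, so ground truth is exact by
construction. Default scene 1024 × 768 at 0.27 cm/pixel (the drone
footprint); the pipeline default is 320 × 240, which preserves the
stroke-to-pixel geometry at a fraction of the cost.

Colours: straw is pale yellow (205, 200, 80); soils are
cambisol (125, 90, 88), leptosol (152, 132, 115), luvisol (145, 85,
92), vertisol (70, 55, 62) — vertisol darkest. Two colour-design
constraints matter and were chosen deliberately:

* Texture is dominated by *common-mode* illumination noise (σ = 18
  levels, identical across channels, as shadows and relief are in real
  photos) plus a smaller independent per-channel noise (σ = 4). The
  common mode cancels exactly in 2G−R−B and keeps the per-channel
  value spans wide and similar.
* Soil blue values sit near the straw blue. The colour-balance step
  rescales each channel to full range, so a channel with a narrow span
  receives an outsized gain; a large straw–soil blue gap combined with
  such a gain can collapse the index separation entirely at extreme
  cover fractions.

A scalar `contrast` parameter interpolates the straw colour between the
soil mean (0: indistinguishable) and full straw (1: separable),
emulating the altitude- and lighting-dependent colour shifts that broke
segmentation on real aerial photographs; an optional `color_cast` adds
a global channel shift.

### Spectral scenes

Two-band SWIR reflectance rasters at 30 m/pixel:
`swir2 = swir1 · (1 − k · cover/100) + noise` with k = 0.4, so NDTI is
strictly increasing in cover in the noise-free limit (cellulose
absorption depresses SWIR2 under residue). Per-soil SWIR1 baselines
put vertisol lowest (0.16, moist dark clay), and vertisol plot pixels
receive extra perturbation — the soil-driven error route for the
satellite method. Reflectances are surface reflectance in [0, 1]; no
atmospheric modelling. GeoTIFF I/O writes two float32 bands with the
standard ModelPixelScale/ModelTiepoint geolocation tags.

## Measurement chains

**Segmentation** (drone): per-channel linear percentile stretch
(default saturation 0.007, i.e. 0.35 % per tail, the common default of
the image-processing software the protocol is based on) → signed
excess-green index 2G−R−B (range ±510, no 8-bit overflow) → threshold →
100 × residue pixels / total. The default threshold is Otsu's split,
computed by exhaustive search over the distinct index values (the grid
is small-ranged integers, so the search is exact and deterministic;
ties break toward the lower cut). The residue convention is strict
`index > t`; ties fall to soil. A fixed-threshold mode covers any
preset cut. Known limitations, both verified in tests: Otsu assumes
bimodality, so on near-pure scenes (one class under roughly 4 % of
pixels) it splits the majority mode and the estimate collapses — the
±5-point accuracy property is therefore stated for covers in
[5, 95] %; and on a residue-free scene an automatic threshold is
meaningless (a fixed cut at half the straw index keeps the estimate
under the measured ≈ 3 % noise floor).

**Line transect**: at each field corner a rope runs along the inward
diagonal (toward the opposite corner), clipped to the rope length, with
30 marks at the centres of equal intervals (a 30 m rope has marks at
0.5, 1.5, …, 29.5 m). A mark scores iff its containing grid cell is
residue — point sampling, no mark width. The field estimate is the mean
of the four per-transect percentages, hence a multiple of 100/120, and
is unbiased for homogeneous cover (each mark samples a Bernoulli(p)
cell). Fields smaller than the rope clip the transect to the diagonal
with a warning and rescale mark spacing; overlap of corner transects in
small fields is accepted behaviour.

**NDTI**: (SWIR1−SWIR2)/(SWIR1+SWIR2) per pixel; pixels with zero band
sum are flagged invalid (NaN) and propagate as missing. Scaling to
0–100 is the fixed affine map (raw + 1) × 50 — deliberately *not* an
empirical calibration. A provenance flag prevents double scaling. Plot
values default to the single containing 30 m pixel (boundary points
belong to the pixel whose half-open footprint contains them); an
optional 3 × 3 mean mode exists because whether the original analysis
used one pixel or a neighbourhood average is unknown. Mixed-pixel
dilution is a documented limitation, not corrected.

## Comparison framework

Spearman matrices use pairwise-complete observations (so LT–M5 uses
182 plots, LT–M6 251) with average ranks for ties; an all-tied vector
yields an undefined (NaN) correlation, flagged rather than smuggled
through. Adoption is `cover ≥ 30` (inclusive — "at least 30 %").
Graded categories use lower-inclusive half-open bins [0,30), [30,60),
[60,90), [90,100]. The measurement-error outcome is 1 iff the
30 %-threshold classifications disagree; rows missing the method value
are excluded, which reproduces the per-model n of 314/182/251.

The linear probability models are plain OLS with non-robust standard
errors and significance stars at 0.1/0.05/0.01 (a robust-SE option
exists but is off by default). Dummy coding uses reference levels male
head, teff residue, leptosol soil, flat slope. Household covariates and
distance enter only the interviewee-method models (M1, M3); field
characteristics enter all models. Rank-deficient designs are an error;
separation is not (this is OLS, not logistic). Coefficient
*magnitudes* are not reproduction targets — the original regressions'
per-unit scaling is unknown and several published coefficients round to
0.00 — only sign and significance patterns are asserted, on synthetic
data.

## Problem sizes and reproducibility

Calibration checks use 500,000-draw samples (Monte-Carlo standard error
of a Spearman estimate ≈ 0.0014, comfortably inside the ±0.01
tolerance); decay uses 100,000; LPM power checks use 10,000 plots;
segmentation properties use 50 scenes at 160 × 120 — sizes at which
every check is stable across seeds while the whole suite runs in a few
minutes on one CPU. All randomness flows from a single integer seed per
run through `numpy.random.Generator` streams; pipeline runs are
byte-reproducible, stage-resumable, and log seed, config digest and row
counts per stage.

What passing tests do and do not show: the generator reproduces the
published *summary* statistics by construction (that is its calibration
contract, and the tests verify the construction); it does not validate
the field experiment itself. Real-data quantities that depend on the
unpublished plot data — the 84/83/80 % accuracy levels, regression
coefficient magnitudes, and the drone method's real-world failure
(negative correlation with the benchmark under uncontrolled lighting) —
are out of reach by design and are asserted only qualitatively: error
grows monotonically as scene contrast degrades, and the configured
covariate signs are recoverable.
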