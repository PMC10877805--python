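# Methods

## ALPS engine

The index is evaluated on co-registered Dxx/Dyy/Dzz scalar volumes on a
2-mm RAS template grid. Four 6-mm spherical ROIs (left/right ×
projection/association fibers) are placed at configurable template-mm
centers; because no canonical coordinates exist for these ROIs, the
defaults (±26 and ±36 mm lateral, −6 mm posterior, 28 mm superior) are a
documented, overridable configuration (`RoiSet`, YAML-loadable), chosen
to sit lateral to the lateral-ventricle body with association fibers
lateral to projection fibers.

Voxel membership is **voxel-center-in-sphere**: a voxel belongs to an ROI
iff its center is within `diameter/2` of the ROI center. This rule is
deterministic and testable by brute-force enumeration (a 6-mm sphere
centered on a voxel center of a 2-mm grid contains exactly 19 voxels).
The anterior–posterior battery shifts each center by −2…+2 whole template
voxels along y; the middle placement (shift 0) is the default analysis
index. Left and right indices are
`(Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)` on mask-mean
diffusivities; the average is their mean. QC flags mark non-positive
mean diffusivities and indices outside [0.5, 3.0]; a non-positive
denominator is an error, not a silent NaN.

No registration, tensor fitting or per-subject manual ROI correction is
performed: inputs are assumed template-space. The chin-up rule (AC-PC
angle strictly greater than 20°) is exposed with the other exclusions.

## Tensor phantoms

Phantoms place homogeneous axis-aligned slabs of anisotropic diffusivity
around each ROI in an isotropic background. Projection slabs set
`Dyy = d_perp`, `Dzz = d_axial`; association slabs set `Dzz = d_perp`,
`Dyy = d_axial`; both set `Dxx = alps_truth * d_perp`. The index then
equals `alps_truth` exactly for any ROI inside its slab, at every
y-shift, which makes the engine testable to machine precision over the
whole plausible range (0.5–2.5). Slabs rather than curved tracts are
deliberate: the index reads only ROI-mean diffusivities, so curvature
adds nothing testable. Optional i.i.d. Gaussian noise on all three
components emulates tensor-estimation noise; the slab validator rejects
configurations whose slab cannot contain the shifted ROI sphere, naming
the offending ROI. Defaults: d_perp 0.7, d_axial 1.4, background 0.8
(all 10⁻³ mm²/s), 64×64×40 grid at 2 mm.

## Cohort generator

A linear-Gaussian structural-equation model with probit-style
thresholding for the ordinal PVS grades — the minimal generative model
under which every downstream fit (OLS residual partial correlations,
proportional-odds models, linear mediation) is correctly specified.

Each continuous endogenous variable (WMH burden, SUVR, ALPS, normalized
choroid volume, four cognitive composites) is
`loc + scale * (γ·C_std + s·z)` with standardized covariates `C_std`
(age, sex, education, APOE ε4, TIV), covariate slopes `γ`,
`s = sqrt(1 − |γ|²)`, and a unit-variance structured score `z` that is a
linear combination of eight independent shocks. **Effect sizes are
injected as covariate-adjusted correlations**: the loading vectors are
back-solved analytically so that each targeted pair's residual
correlation equals the requested value, and infeasible combinations
(implied covariance not positive semi-definite) are rejected at
construction. Because the scores are independent of all covariates, the
injected values are the population partial correlations under any
covariate subset, which is what the estimators measure.

Defaults worth knowing:

- Exposure→marker adjusted correlations: WMH→ALPS −0.458, Aβ→ALPS
  −0.249, WMH→choroid 0.294, Aβ→choroid 0.223. Marker→cognition:
  ALPS 0.470/0.358/0.223/0.419 and choroid −0.315/−0.321/−0.233/−0.261
  for memory/executive/visuospatial/language.
- Exposure→cognition adjusted correlations are back-solved from the
  mediation decomposition so that the implied WMH-through-ALPS indirect
  effects land at −0.203 (memory), −0.149 (executive), −0.041
  (visuospatial), −0.188 (language) on the residual-correlation scale,
  and the Aβ-through-ALPS effects at −0.093 (memory), −0.052
  (executive), −0.085 (language). The Aβ–visuospatial cell is set to a
  feasible −0.200 directly: back-solving an indirect effect of −0.169
  there would require an adjusted correlation of magnitude 1.66, which
  no correlation matrix admits, so that published-scale combination is
  unrealizable in any standardized linear model. `implied_mediation_effects`
  computes the exact standardized decomposition the defaults imply
  (e.g. WMH→ALPS→memory −0.212 after total-SD standardization).
- Covariate effects are restricted to age, sex and APOE ε4 — the
  covariates common to every adjustment set used downstream — so the
  injected adjusted correlations are identical across model 1/2 and the
  cognition/mediation models. TIV and education are drawn and available
  as covariates but affect no endogenous variable by default.
- The two exposures are conditionally independent given covariates, so
  single-exposure mediation models are unconfounded by the omitted
  exposure, matching the separate-model analysis design.
- SUVR in the positive cohort is a monotone transform of its structured
  Gaussian score onto a normal truncated above 1.11 (mean 1.35, SD 0.18),
  so amyloid positivity holds by construction; the reference group is
  truncated below 1.11 (mean 1.024, SD 0.047). The transform perturbs
  Pearson correlations involving SUVR by well under 0.01 at the default
  truncation mass (~9%).
- PVS grades: cumulative-logit latent model on the raw exposures with
  slopes (BG: Aβ −1.212, WMH 0.489; WM: Aβ −0.754, WMH −0.054) and
  increasing cutpoints placed so grades span 1–4 with mass at 2–3.
- Demographics: age N(75, 8.5), education N(16, 2.4), TIV N(1465, 160) ml,
  male Bernoulli(0.38), APOE ε4 Bernoulli(0.5); vascular risk flags at
  prevalences 0.45/0.08/0.48/0.17/0.12. Diagnoses (48 CN+, 26 MCI+,
  19 AD+ at n = 93) are assigned by rank of mean cognitive impairment,
  so group contrasts emerge without double-counting the injected
  correlations. QC fields are drawn inside the keep-region by default;
  exclusion-rule tests construct violating records directly.

What the generator does **not** emulate: site/scanner heterogeneity,
non-Gaussian marker tails, floor/ceiling effects in composites,
measurement error correlated across markers, longitudinal structure, and
selection effects in who receives PET. Passing recovery tests therefore
shows the estimators are correct and unbiased under a well-specified
linear model at study scale — not that the original cohort estimates are
reproduced from real data.

## Statistics

- **W-scores** fit OLS of a marker on age, sex and TIV in the CN−
  reference only (residual SD with `n − p − 1`); scores are
  `(obs − pred) / SD_ref`, ALPS negated first so higher always means more
  abnormal. Degenerate (zero-residual) models are flagged and refuse to
  score. The default covariate set mirrors model 1.
- **Partial correlation** is the correlation of OLS residuals, p from a
  t-distribution on `n − k − 2` df. The rank variant transforms x and y
  only (covariates numeric) — the common implementation convention; a
  fully-ranked variant is a one-line change upstream of the call.
- **Ordinal fits** use statsmodels' `OrderedModel` (logit link, BFGS);
  cutpoints are recovered from the threshold parameterization, and
  non-convergence is carried on the result. No random effects by
  default: the synthetic cohort has no grouping structure; a
  site-random-intercept extension would slot behind the same interface.
- **FDR** is Benjamini–Hochberg via statsmodels, tested against the
  step-up definition on all orderings of six p-values.
- **Continuum curve**: stages ordered CN− < CN+ < MCI+ < AD+ on an
  integer axis; a natural cubic spline interpolates the stage means (so
  fitted stage values are exactly the means, preserving monotonicity
  checks) with a seeded within-stage bootstrap percentile band.
  Requires ≥ 4 observations per stage.

## Mediation

Single-exposure product-of-coefficients: `a` from `m ~ x + C`; `b`, `c′`
from `y ~ x + m + C`; `c` from `y ~ x + C` (covariates: age, sex, APOE ε4
by default — TIV and education deliberately excluded to match the
adjustment set used for the cognition-linked mediation chain).
`c = c′ + a·b` holds exactly by OLS algebra and is asserted in tests.
Variables are z-scored by default so effects are on a standardized β
scale. Inference: case-resampling bootstrap of `a·b` (default 5000
replicates; fewer than 100 is an error), **percentile** 95% CI — the
simplest faithful reading of "bootstrap confidence interval" — with BCa
(bias-corrected, jackknife acceleration) behind `ci_method="bca"`.
The bootstrap p-value is `2·min(P(θ* ≤ 0), P(θ* ≥ 0))`. The bootstrap is
vectorized (batched normal equations), so 5000 replicates at n ≈ 100
take about a second. The battery runs 2 exposures × 4 outcomes per
mediator with BH-FDR across each mediator's eight indirect-effect
p-values; per-cell seeds derive deterministically from the battery seed.

## Problem sizes in the shipped checks

The validation suite uses 200 simulated cohorts of n = 93 for effect-size
recovery (tolerance ±0.05 on means), 500 simulations at n = 500 with 500
bootstrap replicates for CI coverage (accepted band 92–98% at nominal
95%), n = 5000 for ordinal slope recovery (±0.15), n = 10000–50000 for
generator moment checks, and 100 noisy phantoms for index unbiasedness.
The acceptance script averages 500 cohorts of n = 93. These sizes give
Monte-Carlo standard errors several times smaller than each tolerance.

## Known limitations

- ROI default coordinates are plausible template positions, not a
  validated atlas; real-data use should supply project-specific centers
  (and ideally per-subject visual QC, which this package does not do).
- The pipeline consumes fitted diffusivity maps; no preprocessing,
  registration, segmentation or SUVR extraction is included.
- The ordinal model is single-level; multi-site grades would need the
  random-intercept extension.
- Bootstrap p-values have resolution `2/n_boot`; FDR on them inherits
  that granularity.
- The continuum curve is descriptive (interpolated stage means), not a
  parametric trajectory model; it does not order subjects within stage.
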