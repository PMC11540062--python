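# Methods

## The bi-tensor free-water model

Each voxel's diffusion-weighted attenuation is modelled as a mixture of a
tissue compartment with symmetric tensor `D` and an isotropic free-water
compartment with fixed diffusivity `d_w`:

    A(b, g) = (1 − f) · exp(−b gᵀ D g) + f · exp(−b d_w)

`f ∈ [0, 1]` is the free-water volume fraction. `d_w` defaults to
3.0×10⁻³ mm²/s, the accepted diffusivity of unrestricted water at body
temperature. The acquisition emulated by the default protocol is a
single-shell clinical research scan: five b=0 volumes and 32 directions
at b = 1000 s/mm². Vendors rarely publish their gradient tables, so the
package ships a fixed electrostatic-repulsion 32-direction set (minimum
angular separation ≈ 24.8°), frozen once for reproducibility.

### Identifiability and constraints

With one non-zero shell the model is ill-posed for isotropic tissue: any
mean diffusivity between the tissue band and `d_w` can be explained by a
continuum of (f, D) pairs. Anisotropy breaks the degeneracy — the angular
profile of a mixture differs from that of any single tensor — so the fit
is well-posed exactly where FA-based biomarkers are meaningful. The
implementation therefore:

- constrains tissue eigenvalues to [0.1, 2.5]×10⁻³ mm²/s (spectral
  projection after the fit; `clipped` flag when active),
- bounds `f` in [0, 1] with boundary solutions flagged,
- flags voxels with conventional FA below 0.05 as `degenerate_isotropic`
  and reports their `f` from the initialisation heuristic instead of an
  arbitrary point on the ridge. `fit_bitensor_voxel` detects the same
  condition internally from the attenuation profile.

### Optimisation

Per voxel, bounded nonlinear least squares (scipy `trf`, analytic
Jacobian) on (f, L) with `D = L Lᵀ` a Cholesky factorisation — positive
semidefiniteness holds by construction. Cost tolerance 1e-10, at most 200
function evaluations, deterministic for fixed inputs. Initialisation from
the conventional log-linear tensor fit:

- `f0` interpolates the observed `exp(−b·MD)` between a typical-tissue
  value (MD = 0.6×10⁻³ mm²/s) and the free-water value, clamped to
  [0.01, 0.99];
- `D0` is a log-linear refit of the f0-corrected attenuations, eigenvalues
  clamped into the tissue band.

Per-voxel fitting is the default (`regularization="none"`); the
`smooth_init` option (Gaussian σ = 1 voxel on the f0 map before fitting)
acknowledges that production free-water pipelines usually regularise
spatially, without making the default depend on neighbourhood context.
Negative or zero signals are floored at 1e-6 of the voxel's b=0 level
before logs or ratios.

Measured behaviour: noiseless anisotropic voxels recover `f` and
FA_FWcorr to ~1e-6; at Rician SNR 30 (defined as S0/σ on the b=0 signal)
the per-voxel estimate scatters along the single-shell ridge (including a
mode at f=0) but the mean over 2000 voxels stays within ≈0.03 of the true
0.3. This scatter is a property of unregularised single-shell free-water
estimation, not of the optimiser; ROI means, which the biomarkers use,
average it away.

## ROI biomarkers

- **Hippocampal volume**: left + right, TIV-adjusted by the residual
  method (volume regressed on TIV within a reference subset, conventionally
  the cognitively unimpaired; everyone's adjusted value is the residual).
- **Signature composites**: weighted means over AD-vulnerable regions.
  The published signature weights are external to this package; the
  shipped defaults weight entorhinal, fusiform, inferior temporal and
  middle temporal equally (thickness), and the McEvoy-style variant adds a
  hippocampal-volume term with every term z-scored across participants
  first (thickness in mm and volume in mm³ are not commensurable).
  `SignatureDefinition` accepts arbitrary weights.
- **Diffusion signatures**: FW / FA_FWcorr averaged per region (left and
  right averaged before weighting), then combined with the signature's
  thickness-region weights — a combination of region means, not a pooled
  voxel mean.
- Degenerate-flagged voxels are included in ROI means by default;
  exclusion is an option.

## Statistical models

All predictors are standardised on baseline-visit statistics before
modelling (so a participant's standardised baseline biomarker is constant
across visits); outcomes are untouched and the transform is recorded.

**Baseline**: OLS of each cognitive score on biomarker + age, sex,
education, race/ethnicity, APOE-ε4 positivity, baseline diagnosis
(CU/MCI) and FSRP (age points excluded), listwise deletion, two-sided t
p-values. Rank-deficient designs raise an error naming the aliased terms.

**Longitudinal**: linear mixed model with the same fixed effects and
correlated random intercept + age slope per participant, fit by REML,
Wald z inference. Age (chronological, at each visit) is centred at the
baseline-sample mean for numerical stability. Convergence fallback
ladder, recorded on the result: correlated random effects → uncorrelated
→ intercept-only, each attempted with lbfgs, then bfgs, then Powell.
Passing a biomarker as outcome and diagnosis as predictor yields the
diagnosis-to-biomarker longitudinal analysis.

**Interactions**: the product term is formed after standardisation;
moderator `age` routes to the longitudinal model (predictor × centred
age), other moderators to the baseline model.

**FDR**: Benjamini–Hochberg step-up adjustment. The family defaults to
the full biomarker × outcome grid; a per-biomarker family (one outcome
column at a time) is available, since published tables are often laid out
that way.

## Competitive analysis

For each outcome, `R²_adj` (Ezekiel adjustment) of a covariates-only
model and of covariates + biomarker, fit on identical rows;
`ΔR²_adj = R²_adj(full) − R²_adj(covariates)`. For mixed models `R²` is
computed from fixed-effects predictions only (random effects at zero) and
then adjusted with n = observations, p = fixed-effect terms; a
variance-partition formulation was considered, but the residual-based
definition composes directly with the OLS formula and reduces to it in
the no-cluster limit (verified to 1e-3).

Bootstrap: participants resampled with replacement — baseline rows for the
cross-sectional mode, whole participants with all visits (cluster
bootstrap) for the longitudinal mode, which is required for valid
resampling of correlated visits. Every model in a replicate is refit on
the same resample, so between-biomarker differences are paired; resampled
clusters get fresh ids so duplicated draws stay distinct groups. B
defaults to 1000; all replicate draws derive from one seed. Replicates
that fail to fit are dropped and counted; more than 10% dropped aborts
the analysis.

Two tests are reported:

- **beats_covariates**: a basic (centred) bootstrap test on the biomarker
  coefficient. ΔR²_adj itself is boundary-degenerate under the null — its
  null distribution is a shifted χ²-type variable with a hard lower bound,
  and its bootstrap distribution is upward-biased with inflated spread —
  so tail tests on ΔR²_adj replicates are either hopelessly conservative
  (measured type-I ≈ 0.00) or wildly anticonservative when centred
  (≈ 0.59). The coefficient is a regular statistic; its centred bootstrap
  test is calibrated (measured type-I 0.05 at n=300, B=200). ΔR²_adj with
  its bootstrap SD remains the reported effect size.
- **pairwise**: two-sided tail test `2·min(Pr(d ≤ 0), Pr(d ≥ 0))` with a
  (count+1)/(B+1) correction on paired replicate differences of ΔR²_adj
  between two biomarkers. Pairing cancels the shared overfit bias, so the
  degeneracy argument above does not apply; for identical biomarkers the
  difference is exactly zero and the test never rejects.

**Tertiles**: participants ordered by (baseline biomarker, participant
id — a deterministic tie-break) and cut into three groups whose sizes
differ by at most one; per tertile, the outcome's age slope from a
random-intercept mixed model.

## Synthetic data

**Phantoms** partition a grid into slab regions, each with an `f` range,
tissue eigenvalues and an orientation rule (axis-aligned, fixed vector,
or per-voxel random). Signals follow the forward model exactly; Gaussian
or Rician (default — magnitude MRI) noise is added on top with
SNR = S0/σ. Identical arguments including seed reproduce volumes bit for
bit. Scanner artefacts (motion, eddy currents, susceptibility) are not
simulated: phantom tests validate the fitting mathematics, not robustness
to acquisition defects.

**Cohorts** emulate a four-visit (0, 1.5, 3, 5 years) memory-and-aging
study: age ~ Normal(73, 7) truncated at 60; sex, race/ethnicity and
APOE-ε4 Bernoulli (ε4 more frequent under MCI: 40% vs 25%); education
Normal(16, 2.5); FSRP Normal(11, 4) truncated at 0; a configurable MCI
fraction (default 40%). One latent pathology factor per participant
(shifted +0.8 SD under MCI) drives the nine biomarkers through
configurable loadings, with unique noise filling each biomarker's
variance to 1. Outcomes follow the longitudinal model's own data
generating process — fixed effects on the observed target biomarker
(default hippocampal FW) and the covariates, plus correlated random
intercept/age-slope and residual noise, independently per outcome. Using
the observed biomarker (not the latent factor) in the linear predictor
means recovery tests are not attenuated by measurement error, which is
what makes exact coverage checks possible. Retention defaults to
(1, .87, .76, .44) per visit, missing completely at random; an
outcome-dependent dropout mode (worse memory → higher dropout) exists for
sensitivity analyses but is not the default, since the analysis models
assume MAR-ignorable attrition. Cognitive outcomes are generated directly
as composite scores; raw subtest simulation is out of scope.

The variance-partition generator used by the competitive checks builds an
outcome with exact population variance shares: covariates jointly 0.50,
plus per-biomarker orthogonal unique shares, so each biomarker's
population incremental R² equals its configured share.

## Problem sizes and numerical checks

- Phantom recovery: 504 noiseless voxels across f = 0 … 0.8 (all within
  0.02 of truth; measured ~1e-6); noise robustness at 2000 voxels,
  Rician SNR 30.
- The zero-variance mixed-model limit is checked at residual SD 0.005:
  REML variance estimates on null data are positive O(1/n), which shifts
  GLS fixed effects by ~1% at outcome-scale noise no matter the
  implementation; the small-noise regime approaches the stated limit.
- CI coverage: 200 cohorts of n=300 in the test suite (150 in the
  acceptance script), Wald 95% intervals.
- Competitive recovery: n=1000 per run. Sizing from the sampling SD of
  the paired ΔR²_adj difference (≈ 0.028·√(300/n) against a true
  difference of 0.06): n=300 yields ~65% power and cannot support a
  ranking check, n=1000 yields >95%.
- Calibration: 500 null simulations (300 in the acceptance script) at
  B=200.
- BH adjustment is verified exactly against a brute-force step-up oracle
  on 1000 random vectors, and the realized false-discovery proportion of
  null association grids stays at the nominal 0.05.

## Known limitations

- Single-shell estimation is intrinsically ridge-shaped; per-voxel `f` at
  clinical SNR is noisy and near-isotropic tissue is unidentifiable. The
  package surfaces (rather than hides) this via flags. Multi-shell and
  spatially regularised variants are out of scope.
- Signature weights are placeholders, not the published values.
- Registration, segmentation and dMRI preprocessing are upstream of this
  package: label maps are assumed aligned to the diffusion grid.
- Mixed-model inference is Wald/z; no Satterthwaite or likelihood-ratio
  options.
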