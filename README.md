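# fwbio

Free-water diffusion MRI biomarkers and their association with cognition
in aging and Alzheimer's disease research.

Conventional diffusion tensor imaging conflates tissue microstructure with
extracellular fluid: a voxel's apparent anisotropy drops when free water
contaminates it, not only when axons degrade. `fwbio` fits the two-
compartment (bi-tensor) signal model on standard single-shell DWI,

```
A(b, g) = (1 − f) · exp(−b · gᵀ D g) + f · exp(−b · d_w)
```

where `f` is the free-water (FW) volume fraction, `D` the tissue diffusion
tensor, and `d_w = 3.0×10⁻³ mm²/s` the diffusivity of free water at body
temperature. From the fitted tissue tensor it derives FW-corrected
fractional anisotropy (FA_FWcorr) alongside conventional FA. The package
then turns maps and morphometry into nine per-participant biomarkers —
hippocampal {TIV-adjusted volume, FW, FA_FWcorr} and two AD-signature
meta-ROI composites with their FW / FA_FWcorr analogues — and evaluates
each biomarker's association with cognitive performance:

- **baseline**: `score ~ biomarker + age + sex + education + race + APOE4 +
  diagnosis + FSRP` (OLS),
- **longitudinal**: the same fixed effects plus correlated random
  intercept and age slope per participant (`(1 + age | participant)`,
  REML), with Benjamini–Hochberg FDR correction across each model family,
- **competitive**: the unique variance ΔR²_adj each biomarker explains
  beyond the covariates, with participant-level (cluster) bootstrap SDs,
  significance tests, and pairwise biomarker comparisons on shared
  resamples,
- **tertile trajectories**: per-tertile age slopes of an outcome, split on
  a baseline biomarker.

Because the cohort data such analyses run on is access-controlled, the
package ships a first-class synthetic-data module: DWI phantoms with known
per-voxel `f` and `D`, and longitudinal cohorts (four visits, attrition,
known fixed effects and variance components) so that every stage is
testable against ground truth.

## Worked example

```python
import numpy as np
from fwbio import (default_protocol, make_dwi_phantom, compute_fw_maps,
                   make_cohort, fit_longitudinal_model, bootstrap_competitive)
from fwbio.phantom import RegionSpec

# 1. a phantom with 30% free water and anisotropic tissue, fitted back
regions = [RegionSpec(1, (0.3, 0.3), (1.5e-3, 0.4e-3, 0.4e-3), "random")]
dwi, truth = make_dwi_phantom(shape=(6, 6, 3), regions=regions,
                              protocol=default_protocol(), snr=np.inf, seed=0)
maps = compute_fw_maps(dwi)
print(f"FW: true 0.300, fitted {maps.fw[dwi.mask].mean():.3f}")

# 2. a longitudinal cohort; hippocampal FW predicts memory decline
cohort, biomarkers, gen = make_cohort(300, seed=42)
merged = cohort.merge(biomarkers, on="participant_id")
res = fit_longitudinal_model(merged, "hippocampal_fw", "memory_composite")
print(f"beta = {res.beta:.3f} (generating value {gen.fixed_effects['biomarker']}), "
      f"SE = {res.se:.3f}, p = {res.p:.2e}")

# 3. unique variance beyond covariates, bootstrapped
cr = bootstrap_competitive(merged, ["hippocampal_fw"], "memory_composite",
                           B=200, seed=1)
d = cr.delta["hippocampal_fw"]
print(f"dR2_adj = {d:.3f} +/- {cr.delta_sd['hippocampal_fw']:.3f}, "
      f"p = {cr.beats_covariates_p['hippocampal_fw']:.4f}")
```

prints

```
FW: true 0.300, fitted 0.300
beta = -0.311 (generating value -0.3), SE = 0.042, p = 8.84e-14
dR2_adj = 0.081 +/- 0.024, p = 0.0100
```

The fitted FW matches the phantom truth exactly in the noiseless case; the
mixed model recovers the generating biomarker effect within one standard
error; and the bootstrap puts the biomarker's unique variance (~8 points
of adjusted R²) clearly above zero.

A command-line pipeline chains the stages (`simulate → fwmap → biomarkers
→ associate → compete`) with a manifest of seeds and output hashes:

```
fwbio run-all --seed 7 --out myrun
fwbio simulate --seed 3 --out sim_only
fwbio validate --config run.yaml
```

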