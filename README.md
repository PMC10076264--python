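# dscmicro

Dual-echo dynamic-susceptibility-contrast (DSC) MRI analysis of cerebral
microvascular function, with a synthetic phantom and cohort generator for
validation. The package targets studies of white-matter microvascular
disease — the motivating setting is cerebral adrenoleukodystrophy, where
blood-brain-barrier breakdown and capillary flow dysregulation precede
lesion growth — but the estimators are generic DSC tools.

## What it computes

From a 4D dual-echo DSC series (gradient-echo and spin-echo EPI acquired
during a gadolinium bolus):

- **Perfusion** — relaxation-rate curves ΔR2\*(t) = −ln(S(t)/S0)/TE are
  deconvolved by an automatically selected arterial input function (AIF)
  using truncated SVD, giving CBF, CBV (area ratio, threshold-free) and
  MTT = CBV/CBF·60.
- **Transit-time heterogeneity** — a vascular model
  C_t(t) = (CBF/60)·Δt·(AIF ⊛ R) with residue R(t) = 1 − CDF of a gamma
  transit-time distribution h(t) is fitted per voxel. Its moments give

      MTT = ∫ t·h(t) dt = αβ,   CTH² = ∫ (t−MTT)²·h(t) dt = αβ²,
      RTH = CTH/MTT = 1/√α,

  where CTH is the capillary transit-time heterogeneity and RTH its
  relative (scale-free) form; RTH > 1 (α < 1) marks microvascular flow
  dysregulation.
- **Barrier leakage** — the apparent leakage constant K_app per voxel from
  the two-regressor model ΔR2\*_voxel ≈ k1·ΔR̄2\* − K_app·∫ΔR̄2\*, with the
  reference curve ΔR̄2\* built from screened non-leaky normal-appearing
  white matter (NAWM).
- **Vessel architecture** — the vortex area (VA): the area of the loop
  traced by pairwise (ΔR2\*(tᵢ), ΔR2(tᵢ)) points over the bolus, computed
  with the shoelace formula, plus peak-ratio vessel caliber and density
  indices.
- **Cohort statistics** — lesion volumetry, 24/72-voxel ROI extraction
  with nine-ROI NAWM normalization, monthly relative change rates,
  optimal 1:1 age matching, iterative Grubbs outlier screening, Hedges'
  g, and a battery of Welch ANOVA + Dunnett, t tests, linear and
  logistic regression.

The `synthgen` module renders all of this forward: gamma-variate bolus,
gamma-residue tissue curves, signed leakage injection, GRE/SE temporal
decoupling (scale κ, lag δ) that opens the vortex loop, Gaussian or
Rician noise, and longitudinal cohorts with configurable treatment and
gene-dose (vector copy number) effects — so every estimator can be tested
against known ground truth.

## Worked example

```python
import numpy as np
from dscmicro.synthgen import PhantomSpec, make_phantom
from dscmicro.kinetics import select_aif, signal_to_delta_r2, deconvolve_svd
from dscmicro.hemodynamic import fit_vascular_model

study = make_phantom(PhantomSpec(shape=(12, 12, 1), lesion_radius=2.5,
                                 snr=np.inf, seed=7))
p, truth = study.protocol, study.truth
aif = study.aif_true                      # or select_aif(study)

idx = tuple(np.argwhere(truth.mask("perilesional"))[0])
conc = signal_to_delta_r2(study.signal_gre[idx], p.te_gre,
                          p.baseline_frames, p.times)
fit = fit_vascular_model(conc, aif)
s = fit.stats
print(f"true MTT {truth.mtt[idx]:.2f} s  fitted {s.mtt:.2f} s")
print(f"true RTH {truth.rth[idx]:.3f}    fitted {s.rth:.3f}")
```

prints

```
true MTT 5.48 s  fitted 5.48 s
true RTH 0.862    fitted 0.862
```

i.e. on noiseless data the voxel-wise fit recovers the transit-time
distribution exactly: this perilesional voxel has RTH ≈ 0.86, elevated
relative to the NAWM class (≈ 0.5) — the heterogeneity contrast the maps
are built to show.

A CLI mirrors the library: `dscmicro simulate phantom`, `dscmicro
simulate cohort`, `dscmicro fit deconvolve|cth|kapp|vai`, `dscmicro
cohort-stats`.

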