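# Methods

## Signal model and units

All analysis is performed in relaxation-rate units. For each echo,
S(t) = S0·exp(−TE·ΔR2(t)) and the inverse conversion is
ΔR2(t) = −ln(S(t)/S0)/TE with S0 the mean of the pre-bolus baseline
frames. No conversion to molar concentration is attempted: the
contrast-agent relaxivity is not calibrated, so all concentration-scale
quantities (and hence absolute CBF/CBV) are defined up to a global
constant and are interpreted as relative values — consistent with the
nine-ROI NAWM normalization used downstream. Time grids are uniform with
t = 0 at the first frame; units are seconds throughout. The default
protocol is the 3 T dual-echo acquisition: TR 1.5 s, TE 40 ms (GRE) /
96 ms (SE), 80 dynamics, 10 baseline frames.

Non-positive signal samples abort the conversion unless clamping is
explicitly enabled (they are then replaced by the smallest positive
observed value); silent clamping hides corrupt data, so it is opt-in.

## Tissue forward model and its discretization

A voxel's intravascular curve is
C_t(t) = (CBF/60)·Δt·(AIF ⊛ R), with residue
R(t) = 1 − CDF of a gamma(α, β) transit-time distribution. The discrete
residue vector uses exact cell averages
r_i = (1/Δt)·∫_{t_i}^{t_i+Δt} R(τ)dτ (closed form via incomplete gamma
functions) rather than point samples: at TR = 1.5 s, left-endpoint
sampling of the decaying R overestimates the tracer mass by ~19%,
whereas cell averaging conserves it exactly, so the area ratio
area(C_t)/area(AIF) equals CBV = CBF·MTT/60 up to window truncation. The
same discretization is used in the fitting model, making noiseless
recovery exact to machine precision. Against the continuous closed-form
convolution the scheme converges first order in Δt (~0.25% of peak at
Δt = 0.02 s).

## Transit-time statistics

With h(t) gamma(α, β): MTT = αβ (first moment), CTH = √α·β (standard
deviation), RTH = CTH/MTT = 1/√α. RTH = 1 exactly at the exponential
limit α = 1, and RTH > 1 ⇔ α < 1, the regime read as microvascular flow
dysregulation. The gamma family is chosen because it is the standard
parametric family in the capillary transit-time heterogeneity framework
and yields these closed forms; numerical quadrature of the defining
moment integrals reproduces them to < 1e-6 over α ∈ [0.5, 20],
β ∈ [0.1, 10] s.

## Voxel-wise vascular fitting

Bounded least squares over (CBF, α, β), α ∈ [0.1, 50], β ∈ [0.01, 30] s,
CBF ∈ [0, 600], multi-started from α ∈ {0.8, 2, 6} with β = MTT_svd/α
seeded by a quick SVD deconvolution of the same voxel. Voxels whose peak
is below 3 baseline SDs fail the bolus gate and are flagged undefined
(NaN in maps) rather than raising. Least squares is used rather than a
Bayesian scheme; fits at realistic noise are therefore information-
limited, with two practical consequences verified on synthetic data:

- α (hence CTH/RTH) is far better identified where heterogeneity is
  high: at concentration-curve SNR 50 (noise SD = curve peak/50) the
  median |Δα|/α is ≈ 8% for perilesional-like physiology (α = 1.5,
  MTT = 5 s) but 10–13% for NAWM-like α = 4, where the residue shape
  saturates. Recovery Monte Carlos therefore use the elevated-CTH voxel
  class — the physiology the biomarker targets.
- identifiability improves with bolus sharpness; the phantom's default
  AIF (gamma-variate, r = 3, b = 0.8 s, first-pass FWHM ≈ 4 s) models a
  compact power-injected pediatric bolus at 5 mL/s.

ROI summaries of noisy RTH maps use the median, which is robust to the
heavy-tailed α errors of individual fits.

## AIF selection and deconvolution

Candidate voxels (baseline signal ≥ 10% of the study median) are scored
peak²/(positive area·(time-to-peak + TR)) — tall, narrow, early — and
the AIF is the mean of at most five candidates within 50% of the best
score, so a single dominant artery is not diluted by tissue curves. Ties
break on the lowest linear voxel index. The concrete scoring rule is this
package's own; published automatic AIF searches do not document theirs.

Deconvolution builds the lower-triangular convolution matrix
A[i,j] = Δt·Ca[i−j] (optionally block-circulant with 2n padding for
delay insensitivity), truncates singular values below 0.1·σmax
(configurable; the conventional default), and reads CBF from the peak of
the deconvolved flow-scaled residue. CBV is computed as the raw area
ratio and is therefore exactly threshold-invariant; MTT = CBV/CBF·60.
The phantom's artery voxel is rendered at 5× the tissue concentration
scale (a blood-pool voxel against per-100g tissue units), so CBF from
the *selected* AIF carries that partial-volume calibration factor, as in
real DSC; recovery tests use the true bolus as kernel.

## Leakage (K_app)

Two-regressor linear model per voxel:
ΔR2*_voxel(t) ≈ k1·ΔR̄2*(t) − K_app·∫₀ᵗ ΔR̄2*(τ)dτ, solved by OLS.
Positive K_app depresses the late curve relative to the intravascular
reference (T1-dominant extravasation); negative K_app is the
T2*-dominant regime; the magnitude quantifies barrier permeability in
either case. The reference is the mean over mask voxels passing a bolus
gate and two tail screens over the last quarter of the series: linear
trend < 5% of peak/min, and tail mean within 2.5% of peak. The offset
screen is the sensitive one — extravasation accrues mostly during bolus
passage, so a leaky curve plateaus at a shifted baseline instead of
continuing to drift.

Known properties, measured on synthetic data: the estimator is exactly
linear in the injected leakage and recovers it exactly when the voxel's
intravascular curve is proportional to the reference (the model's
assumption); transit-shape mismatch between voxel and reference biases
K_app by up to ~10% of its value at the default class separation; a
reference estimated from a finite noisy study couples all voxels
through its noise and adds a ~3e-4 s⁻¹ second-order bias (≈ 3% of
lesional K_app) — tolerable for relative and ordering analyses, which is
how the maps are interpreted. An alternative regressor basis built from
deconvolved residue functions is available behind a flag.

## Vortex area

The paired-echo parametric plot (ΔR2*(tᵢ), ΔR2(tᵢ)) is closed
last-to-first over the bolus window — the union of both echoes' first
passes at the 5% level, so a lagged spin-echo curve is not clipped
mid-loop — and VA = |shoelace sum|/2, with orientation from the sign and
a peak-product-normalized variant for scale-free comparisons. Exported
group values use |VA|; orientation is kept as metadata.

For the generator's decoupling mechanism (SE = κ·GRE delayed by δ), the
loop area equals κ·|R′(δ)| with R the curve autocorrelation: VA grows
with δ only while δ stays below the curve's decorrelation width, peaks
near it, and falls beyond. Lag-monotonicity checks therefore use
long-transit, high-CTH physiology (MTT 9 s), whose wide curves keep
multi-sample lags inside the growing regime. The gamma-variate-smoothed
path agrees with the raw path within 5% on noiseless data.

Vessel caliber index = √ADC·(peak ΔR2*/peak ΔR2)^{3/2} and density
index = peak ΔR2/(peak ΔR2*)^{2/3} follow the standard vessel-size
imaging constructions; both are relative indices.

## Synthetic phantom

Concentric geometry: central lesion disc, 2-voxel perilesional shell,
NAWM elsewhere, one designated artery voxel, a small background rim at
2% of S0. Class physiology is parameterized by (CBF, α, MTT) ranges with
β = MTT/α, so heterogeneity and MTT are controlled independently;
defaults: NAWM CBF 20–28 mL/100g/min, α ≈ 4, MTT ≈ 4 s (RTH ≈ 0.5);
perilesional α ≈ 1.5, MTT ≈ 5 s (RTH ≈ 0.82); lesion α ≈ 2 at NAWM-like
MTT with K_app 0.006–0.014 s⁻¹. Leakage is injected on the GRE curve as
−K_app·∫C̄ with C̄ the NAWM population-mean shape (stored with the study
for exact verification); K_app is zero outside the lesion unless
configured — the end-to-end ordering study configures a continuum of
mild NAWM leakage (0–0.006 s⁻¹), reflecting barrier impairment beyond
lesions, which also anchors the screened reference at the non-leaky end
of the distribution. The SE series is the GRE relaxation curve scaled by
κ = 0.5 and delayed by δ (default 1.5 s), the minimal mechanism that
opens a vortex loop. Noise is Gaussian on the signal (default baseline
SNR 100; Rician optional); all randomness flows through explicit seeds.

What the phantom does **not** emulate: anatomy (no atlas), bolus delay
and dispersion between artery and tissue, motion and ghosting, partial
volume beyond the artery scale factor, T1 shine-through dynamics beyond
the linear leakage term, and scanner drift. Passing recovery tests shows
the estimators invert the stated forward model at realistic noise — not
that they are robust to all properties of clinical data.

## Synthetic cohort

One row per subject-visit: groups GT (n = 13), allo-HSCT (6), HEM (11,
flat over time by construction), CON (7, single normative visit); visits
at days 0/45/365/730. Treated subjects accrue the configured effects
(defaults: RTH −1 SD, VA +1 SD, K_app −1.5 SD, lesion-growth −1.5 SD)
linearly over the first year; in the GT arm the vector copy number
reduces monthly lesion growth (4 %/month per VCN) and FA decline. Lesion
volume integrates the piecewise-constant growth rate; within-subject
residual SD is 0.35 of the between-subject SD. Under null effects the
battery holds its nominal 5% type-I rate (verified over 1000
replicates), and the default 1-SD RTH drop gives ≈ 100% paired-test
power at n = 13 — so group sizes of the emulated design are adequate for
the perfusion effects, matching the power reasoning of such studies.

## Statistics

Welch's ANOVA is implemented directly (verified against R's
`oneway.test` to printed precision) with Dunnett many-to-one comparisons
from scipy; t tests are Welch by default when unpaired. Iterative
two-sided Grubbs screening (α = 0.05) removes the most extreme value
while G exceeds the critical value, never below n = 3. Hedges' g uses
the pooled SD and the J = 1 − 3/(4N − 9) small-sample correction; a zero
pooled SD with differing means returns NaN. Optimal 1:1 age matching
solves the assignment problem (Hungarian algorithm) on |Δage| — verified
equal to exhaustive enumeration for small cohorts and never worse than
greedy matching. Monthly relative change uses a 30.44-day month:
100·(v₂−v₁)/(v₁·(t₂−t₁)/30.44) %/month. Logistic regression (statsmodels)
reports the odds ratio with Wald CI, likelihood-ratio p and McFadden
pseudo-R²; perfect separation is flagged in the output rather than
raised.

## Verification problem sizes

The standard battery (see `scripts/acceptance.py`) uses: 50 random
(α, β) draws for quadrature agreement; a 32×32×3×80 noiseless phantom
for the forward-inverse identity; 200 Monte-Carlo replicates at curve
SNR 50 for vascular recovery; ≥ 600 voxels for the K_app null
calibration (against the noiseless population reference, so estimates
are independent and the standard error is valid); 1000 null cohorts for
type-I calibration; 500 replicates for power; and 200 end-to-end
16×16×1 phantom replicates for the ordering study. These sizes give
stable estimates of each quantity while keeping the full battery at a
few minutes on one CPU.
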