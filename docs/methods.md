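# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind `fmdwi`, in the spirit of the methods
documentation of packages like statsmodels or msprime.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model

The fractional-motion (FM) model describes water displacement as an
H-self-similar process with α-stable stationary increments.  For a
pulsed-gradient spin-echo (PGSE) measurement with gradient amplitude G0,
pulse duration δ and separation Δ, the magnitude signal is

    S/S0 = exp( −η(α, H, δ, Δ) · D_{α,H} · γ^α · G0^α · Δ^(α+αH) ).

The Noah exponent α ∈ (0, 2] indexes the stability of the increment
distribution (α = 2: Gaussian), the Hurst exponent H ∈ (0, 1) the
self-similarity of the trajectory, and the memory parameter μ = H − 1/α
the increment correlation (negative: anti-persistent).  μ is *always*
computed from (α, H) — in parameter maps, in synthetic subjects, and in
summary tables — never estimated or sampled independently, so the identity
μ = H − 1/α holds exactly everywhere by construction.

### The η factor

Published FM theory determines η from (α, H, δ, Δ), but its exact
finite-pulse expression varies between theoretical treatments.  `fmdwi`
makes η a pluggable strategy (`eta_model`); the shipped default is the
narrow-pulse factorisation

    η = (δ/Δ)^α,

chosen because it (i) makes the decay exponent reduce to
D·γ^α·G0^α·δ^α·Δ^(αH), (ii) reproduces the mono-exponential model
*exactly* at α = 2, H = ½ with b = γ²G0²δ²Δ, and (iii) keeps the G0 and Δ
exponents — through which α and H are identified — untouched.
Consequences users must be aware of: simulation and fitting must use the
same η strategy, and absolute D values are only comparable within one η
convention; α, H and μ are convention-independent within this family.  At
the default protocol's δ/Δ ≈ 0.40–0.76 a finite-pulse η would rescale D
but not the exponent structure.

### Units

The decay exponent is evaluated with G0 expressed in T/mm, so D_{α,H}
carries units mm^α·s^(−αH) and coincides numerically with ADC (mm²/s,
b in s/mm²) in the Gaussian limit.  All other internal computation is SI;
interfaces accept the clinical ms / mT·m⁻¹ conventions.  b-values follow
Stejskal–Tanner, b = γ²G0²δ²(Δ − δ/3), computed at full precision and
rounded only for display.  The proton gyromagnetic ratio defaults to
2.6752218744×10⁸ rad·s⁻¹·T⁻¹ and is overridable.

## Acquisition scheme

The default protocol crosses Δ ∈ {27.060, 39.560, 52.060} ms with six
gradient amplitudes geometrically spaced over 15.67–49.00 mT/m (even
spacing on a log axis spreads b-values log-evenly, since b ∝ G0²), at
fixed δ = 20.676 ms, three orthogonal directions, and 12 b=0 volumes: 66
volumes, 18 distinct non-zero b-values ≈151–3317 s/mm².  Volume order is
fixed (b0 first, then Δ ascending, G0 ascending, direction x/y/z) so the
scheme maps one-to-one onto the 4th axis of the 4D volume.

## Voxelwise fitting

1. **Normalisation.** S0 is the arithmetic mean of the b=0 volumes.  Each
   (Δ, G0) cell's three directional attenuations S/S0 are combined by
   their geometric mean (= arithmetic mean of log-attenuations), which
   removes any per-direction multiplicative factor exactly and minimises
   the influence of residual anisotropy; an arithmetic-mean option exists.
   Attenuations are clipped to ≥ 10⁻⁶ before logs.  Voxels with S0 ≤ 0
   are flagged unfittable, not fatal.
2. **Estimation.** (ln D, α, H) minimise the signal-domain sum of squared
   residuals under scipy's trust-region-reflective solver with bounds
   D ∈ [10⁻⁸, 10], α ∈ [0.5, 2.0], H ∈ [0.05, 0.95] — deliberately wider
   than plausible tissue values; the α and H bounds also keep the
   exponents numerically stable.  D is fitted on a log scale for
   conditioning.  The fit is multi-started from the grid
   α ∈ {1.0, 1.5, 2.0} × H ∈ {0.3, 0.5, 0.7}; each start seeds D by
   matching the decay exponent at the median-b cell to a Gaussian-limit
   log-linear ADC estimate.  The lowest-SSE start wins, ties resolving to
   the first in grid order, which makes maps bit-deterministic.  Cost
   tolerance 10⁻¹⁰, at most 1000 function evaluations per start; the
   narrow-pulse path uses an analytic Jacobian.
3. **ADC.** The two-point estimate ln(S_b0/S_b)/b uses the
   direction-averaged signal of the single weighted cell whose b lies
   nearest a configurable target (default 954 s/mm²; with the default
   protocol this selects the b ≈ 964 cell, ties resolving to the lower b).
   Negative ADCs under noise are kept but counted in QC.

Degenerate inputs: fewer than three (Δ, G0) cells, all-floor signals, or
S0 ≤ 0 yield an unfittable flag (NaN in maps, counted in the QC report).
A constant signal S = S0 drives D to a negligible value (the cost surface
is flat below D ≈ 10⁻⁶, so the solver stops within cost tolerance of the
lower bound).

## Synthetic cohorts

The generator emulates a three-group hippocampal aging/dementia study.
Default group specifications (healthy controls n = 11, mild AD n = 12,
moderate AD n = 12; 35 subjects) carry per-hemisphere means ± SD of α
(≈1.588/1.563/1.531 left, 1.604/1.562/1.519 right), H (≈0.46–0.49) and
ADC (≈1.04–1.39 × 10⁻³ mm²/s), with α decreasing and ADC increasing with
severity, plus ages (≈65–72 ± 4–10 y), MMSE and MoCA scores (no MoCA for
controls).  Each parameter is drawn from a normal distribution truncated
to its legal range; parameters are mutually independent except a positive
coupling between cognitive scores and α (default target r = 0.45 per
hemisphere — a modelling choice in the plausible range for a
severity-tracking biomarker, implemented through the bilateral α latent
with weight r√2, valid for r ≤ 0.7).  D is derived from (α, H, ADC) by
matching the FM decay to exp(−b·ADC) at the median-b cell, keeping
phantom contrast realistic across parameter combinations.

Phantoms are abstract block geometry: a 16×16×4 volume with two disjoint
3×3×2 ROIs ("left"/"right") at S0 = 1000 in a low-amplitude background,
Rician noise |S + n₁ + i·n₂| with per-channel σ = S0/SNR applied to every
volume (default SNR 50, a typical 3T EPI regime).  The nominal
1.875×1.875×5 mm voxel size is recorded but computationally inert.
Reproducibility: subject j draws from `SeedSequence([seed, j])`.

What the phantoms deliberately omit — anatomy, partial-volume mixing, EPI
distortion/ghosting, motion, per-direction anisotropy — means passing
recovery tests demonstrate estimator correctness under the stated noise
model, not robustness to scanner artefacts.

## Statistics

* **t-tests**: pooled-variance Student's test by default (Welch by
  config); also computable directly from (mean, SD, n) summaries, with an
  exact subgroup-pooling identity to combine published subgroup rows into
  one group.  Sample SD (n−1) throughout.  Zero variance in both groups
  with equal means returns p = 1 by convention.
* **ROC**: empirical curve; ties collapse into one threshold step so the
  trapezoidal AUC equals the Mann–Whitney concordant-pair fraction with ½
  per tie.  Orientation is auto-chosen so AUC ≥ 0.5 and reported.  The
  Youden threshold maximises sensitivity + specificity − 1 over midpoints
  between adjacent distinct scores plus ±∞ (positive call: oriented score
  ≥ threshold; ties toward the smallest threshold).
* **Marker combination**: unregularised maximum-likelihood logistic
  regression (intercept, ≤100 iterations, tol 10⁻⁸); its linear predictor
  is the combined score.  Under (quasi-)perfect separation the ML optimum
  diverges, so the fit falls back to a ridge-stabilised direction
  (penalty 10⁻⁶) with a warning — only the score ordering feeds the ROC.
  Features are standardised internally; this affine map does not change
  the ROC.
* **Partial correlation**: residual method (least-squares regression of
  both variables on the covariates with intercept, Pearson r of
  residuals), p from t = r√((n−2−k)/(1−r²)); reduces exactly to plain
  Pearson with no covariates.  Age is the default covariate.
* **FDR**: Benjamini–Hochberg step-up (via statsmodels), applied to the
  correlation family (4 parameters × 2 ROIs × 2 scales = 16 tests); group
  comparisons are reported with raw p.

The orchestrated report sorts subjects by id before computing, making
every number invariant to input row order.

## Problem sizes and thresholds in the test suite

Noiseless round-trips assert 0.1% parameter recovery.  Noisy recovery uses
500 voxels at SNR 50 (median |α̂−α| and |Ĥ−H| < 0.05).  Cohort-level
ordering (moderate ᾱ < mild ᾱ < control ᾱ) is evaluated on the bilateral
(left/right-averaged) group means over 20 seeded cohorts, requiring ≥ 18
successes; the bilateral average is used because single-hemisphere group
gaps of ≈0.03 at SD ≈0.04 and n ≈ 11–12 leave non-trivial probability of
a sampling-order inversion per hemisphere even for a perfect estimator.
Null calibration draws 200 cohorts with identical group specifications
and checks the t-test battery rejects at ≈5% (accepted band 2–8%,
reflecting dependence among the 16 tests per cohort).  Statistical
operations are verified against independent brute-force oracles (pair
counting, exhaustive threshold search, closed-form partial-correlation
identity, literal BH step-up) on 100 random instances each.

## Known limitations

* The narrow-pulse η is a convention, not the unique finite-pulse FM
  result; fitted D is η-convention-specific.
* S0 is fixed from the b=0 mean rather than fitted; with 12 b=0 averages
  its sampling error is negligible relative to Rician effects, and it
  removes one free parameter from an 18-observation fit.
* The model is isotropic by design (direction-averaged); no tensor or
  per-direction fitting.
* Rician bias at the highest b-values (attenuation approaching the noise
  floor) biases α slightly downward at low SNR; at SNR 50 the effect is
  within the tested tolerances.
* No motion/eddy/distortion correction: inputs are assumed preprocessed.
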