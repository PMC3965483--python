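# Methods

This note documents the models, numerical choices and limitations of
`copebuoy`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where design
decisions were genuinely open.

## Morphometric quantification

All internal units are mm / mm² / mm³; microns appear only at the
pixel-calibration boundary (`apply_scale`, factor μm·px⁻¹/1000 for
lengths, squared for areas).

* **Prosome.** Projected area is the ellipse (π/4)·L·W on the measured
  length and width; volume is a prolate spheroid about the long axis with
  the dorso-ventral (third) axis set equal to the width, (π/6)·L·W².
  The third axis is not observable in a single projection; equating it to
  the width is standard copepod morphometric practice and is the single
  assumption behind every volume here.
* **Oil droplets.** Independent circles in projection (Σ πd²/4) and
  spheres in volume (Σ πd³/6).
* **Oil sac, measured as an ellipse.** Same ellipse/prolate-spheroid pair
  on the sac axes.
* **Oil sac, digitised as a contour.** Area is the absolute shoelace sum
  (orientation-independent; self-intersecting contours are rejected via a
  segment-crossing check, never silently repaired). For volume, the
  contour is replaced by the ellipse with *exactly* its area and the
  aspect ratio of its second-moment (covariance) ellipse — the polygon's
  central second moments have closed forms, and the construction
  preserves area to machine precision — then the spheroid formula is
  applied. The authors of the measurement scheme do not state their
  volume construction for digitised sacs; this equivalent-ellipse choice
  is the minimal one consistent with the parametric path (for
  ellipse-shaped contours the two routes agree within 1%) and is isolated
  in one function so it can be swapped.
* **% lipid area** = 100 · lipid area / prosome area; invariant under
  uniform scaling and under change of pixel calibration (property-tested).
  `lipid_area > prosome_area` raises; a lipid volume fraction ≥ 0.8 is
  flagged because it exceeds the non-tissue volume budget of the density
  model.

## Body-density model

A copepod is a volume mixture of three phases whose fractions sum to 1
exactly (asserted to 10⁻¹²):

ρ_cop = f_lipid·ρ_lipid + f_tissue·ρ_tissue + (1 − f_tissue − f_lipid)·ρ_water

* **Tissue**: f_tissue = 0.2, ρ_tissue = 1.08 g/cm³, both constant and
  overridable in config for sensitivity analysis. These constants force
  the f_lipid = 0 limit ρ_cop = 0.216 + 0.8·ρ_w.
* **Internal water** tracks the ambient seawater density. This is the
  model's strongest assumption; it is violated by species using ion
  replacement for buoyancy regulation, and no such mechanism is modelled.
* **Seawater**: EOS-80 (UNESCO 1983; Millero & Poisson one-atmosphere
  polynomial plus the secant-bulk-modulus pressure correction),
  implemented directly because its check values are published and
  self-contained; the implementation reproduces them to 10⁻⁵ g/cm³.
  `density_at_depth` accepts any `(T, S, P) → g/cm³` callable through its
  `eos` hook (e.g. a TEOS-10 implementation); in the study's shallow,
  oceanic T/S/P range the two formulations differ well below the model's
  other uncertainties. Pressure uses the 1 dbar/m approximation (<1%
  error above 100 m), isolated in `pressure_at_depth`.
* **Lipid phase**: linear PVT response
  ρ_lipid = ρ0·(1 − α(T − T0) + κ(P − P0)), adequate over the ≤70 dbar
  range used. Defaults (config, not measured constants):
  ρ0 = 0.902 g/cm³ at T0 = 0 °C and P0 = 0 dbar, α = 7.0e-4 °C⁻¹,
  κ = 9.0e-6 dbar⁻¹ — representative wax-ester values, both response
  coefficients well above seawater's (≈2.5e-4 °C⁻¹ and ≈4.3e-6 dbar⁻¹
  relative responses). Note the compressibility margin required by the
  differential-compressibility mechanism: with internal water tracking
  ambient and incompressible tissue, the water-minus-copepod density gap
  of an individual with lipid fraction f shrinks with depth only when
  f·(κ·ρ0 − ∂ρ_w/∂P) > f_tissue·∂ρ_w/∂P. At f = 0.4 this needs
  κ·ρ0 ≳ 6.6e-6 g·cm⁻³·dbar⁻¹; the default κ satisfies it, and the
  property is asserted as a sign test (not a magnitude) on an isothermal
  0–70 dbar column.
* All densities are g/cm³ throughout; the kg/m³ → g/cm³ conversion
  happens once, inside the seawater EOS. Wax-ester PVT properties have
  been measured on high-latitude species; applying them to warm-water
  copepods with different lipid compositions makes those density outputs
  gross estimates only.

## Statistical layer

* **Depth-effect test.** The observed statistic is the sequential-SS F
  for the depth factor entered after sampling date in an additive linear
  model (orthonormal design bases via SVD; F defined as 0 when both the
  residual and the depth SS vanish, +∞ when depth explains a perfect
  fit). The null distribution permutes the response *within* date strata
  — exact exchangeability under the null given additive date effects.
  Strata lacking a depth contrast are dropped with a logged warning.
  When the stratified arrangement count (product of per-stratum
  multinomial coefficients) is ≤ `exhaustive_limit` (default 20,000) the
  space is enumerated exhaustively via multiset permutations and the
  exact proportion reported; otherwise `iterations` Monte-Carlo
  permutations (default 5000) are drawn and p = (1 + #{F* ≥ F_obs}) /
  (1 + iterations), which cannot return 0. Ties against F_obs are counted
  with a tolerance of 10⁻⁹ relative to |F_obs| to absorb float noise in
  the enumerated null. This restricted-permutation scheme differs from
  lmPerm's residual-permutation with sequential stopping; the two agree
  asymptotically, and no early-stopping rule is emulated (iteration
  counts in results are always the number actually evaluated).
* **Multiplicity.** Step-down Holm–Bonferroni with monotonicity
  enforcement and capping at 1, applied across species *within* one
  response family (% lipid area; absolute lipid area as the
  ratio-robustness variant; body density), mirroring separately adjusted
  result tables. Cross-checked against `statsmodels.multipletests`.
* **Kruskal–Wallis** on midranks with the tie correction
  1 − Σ(t³−t)/(N³−N); all-tied data returns H = 0, p = 1; χ² reference
  with k−1 df. On tie-free data it equals the uncorrected formula to
  10⁻¹²; cross-checked against `scipy.stats.kruskal`.
* **Two-way ANOVA** (depth × stage, additive): type-I sequential SS with
  each factor reported entered after the other (statsmodels OLS +
  `anova_lm`); the two orderings coincide only for balanced designs.
* **Regression**: OLS of absolute lipid area on prosome length with R²
  and the slope t-test.
* The depth factor used in the study-level tests is a two-level
  shallow/deep dichotomy, splitting each species' nominal tow depths at
  their range midpoint — sites towed at slightly different nominal
  depths on different dates (6 vs 8 m), and the scientific contrast is
  the layer, not the metre value. "Date as a covariate" is implemented
  as a categorical factor (dates are labels, not distances).

## Synthetic-data generator

The generator defines the conditions under which the pipeline is
exercised:

* **Populations.** Prosome lengths are normal, truncated at ±4 SD and at
  0, with per-group means/SDs and sample sizes taken from the field
  study's sampling table (seven species/stage groups, 1091 individuals
  before filtering). Widths are length × a per-species config ratio
  (published data report lengths only) with 2% multiplicative noise.
  The per-individual % lipid area is drawn from a normal truncated to
  [0, 95] — the simplest model matching reported mean ± SE summaries; an
  optional moment-matched lognormal switch exists because the true
  variance structure is unknown — and the sampled percentage is realised
  *exactly* by constructed geometry (1–3 Dirichlet-split droplets, or a
  sac ellipse of aspect ≈3 capped at 90% of prosome length, or a
  48-vertex jittered polygon rescaled to the target area).
* **Lipid levels and depth effects are illustrative configuration**, not
  figure readings: deeper-richer in the Red Sea groups and the Arctic C5
  (shallow ≈2–18%, deep ≈3.5–24% by group), shallower-richer in the
  Mediterranean groups, and no effect in the Arctic C4 (the built-in
  null). Effect sizes of roughly 0.6–1 within-group SD at the published
  group sizes give near-certain detection for five groups and high power
  for the weakest (C5 right).
* **CTD archetypes**: warm near-isothermal Red Sea (≈25 °C, S≈40.5),
  weakly stratified Mediterranean, and a strongly stratified Arctic fjord
  (5.5 °C fresh surface lens over 0.5 °C saline water below 30 m), on a
  0–80 m grid with configurable Gaussian perturbation (default SD 0.05)
  per site-date cast. Shapes emulate the field settings; values are
  editable config.
* **Micrographs**: axis-aligned filled ellipse (prosome, intensity 0.55)
  on dark background (0.15) with brighter oil bodies (0.90), additive
  Gaussian noise, 16-bit quantisation; truth fields are the analytic
  areas of the rendered shapes, and pixel-count areas agree with them
  within 2% for shapes ≥50 px across. Not emulated: optical blur,
  uneven illumination, specimen tilt (the field protocol physically
  suppressed tilt with a depression slide), appendages, gut content,
  touching specimens. Passing imaging tests therefore demonstrate the
  measurement logic, not robustness to real histological imagery.

All generators are pure functions of (spec, seed); study-level seeding
derives per-stage streams from one root seed via `SeedSequence.spawn`.

## Problem sizes and tolerances

The default verification sizes: type-I error is estimated from 500 null
replicates at 1000 permutations each (accepted band [0.03, 0.07] at
α = 0.05); Holm FWER from 2000 seven-test null families (bound 0.05 plus
three binomial SEs); geometry oracles use ≥100 px rasterisations (1%)
and 10⁶-point Monte-Carlo polygon areas (≤1%); the imaging round trip
uses 50 images at noise SD 0.03 (median relative error ≤5%, typically
≈0.1%); the end-to-end study runs all 21 species × response permutation
tests at 5000 iterations in a few seconds thanks to a vectorised
permutation kernel (the within-stratum residual sum of squares is
permutation-invariant, so only two orthonormal-basis projections per
permutation batch are needed).

## Known limitations

* Volumes inherit the unobservable third-axis assumption; no tilt
  correction is applied.
* Density outputs for warm-water species assume high-latitude wax-ester
  PVT properties and are estimates, not measurements.
* The imaging module handles single, roughly centred, high-contrast
  specimens only — by design.
* The exhaustive permutation path enumerates arrangements of *values to
  cells*; with heavily tied responses the enumeration remains correct
  but conservative tie-handling makes exact p-values slightly larger.
* lmPerm-style adaptive stopping is intentionally not reproduced.
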