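# Methods

`spheromech` analyzes two complementary biomechanical assays on
multicellular spheroids — fusion of spheroid pairs and spherical-tip
nanoindentation — and combines them into tissue-scale material parameters.
This note records the models, the numerical choices, what the synthetic
generators do and do not emulate, and the design decisions taken where the
problem was genuinely open.

## Fusion kinetics: the liquid-drop coalescence model

Two spheroids in contact are treated as coalescing, highly viscous liquid
drops driven by effective surface tension Γ against viscosity η. The order
parameter is the neck radius r₀(t) normalized by the initial average pair
radius R₀:

    (r₀/R₀)² = 2^(2/3) · (1 − e^(−t/τ)),      τ = 2^(2/3) · R₀ · η/Γ.

The prefactor 2^(2/3) is the volume-conservation plateau for two equal
drops merging into one. The ratio Γ/η (µm/h), the *visco-capillary
velocity*, is the size-independent measure of fusion speed; the package
reports it as 2^(2/3)·R₀/τ̂ per pair.

**Fitting.** τ is the sole free parameter; the plateau is fixed (a
free-amplitude mode exists for model checking — the fitted amplitude on
clean trajectories reproduces 2^(2/3), and is the package's way of
*measuring* the plateau rather than asserting it). The default objective is
least squares on log y rather than on y itself: neck measurements err
multiplicatively (segmentation error scales with object size, and the
synthetic generator's lognormal noise encodes the same assumption), and on
a 9-point schedule the choice matters — absolute-residual fitting lets the
two late, large-y points dominate and roughly doubles the τ scatter
(Monte-Carlo: ~10% SD vs ~4% at 5% neck noise). Absolute-residual fitting
is available via `weighting="none"`. Points with y = 0 carry no
information on the log scale and are dropped; missing frames are dropped,
never interpolated (9-point series cannot support imputation). Goodness of
fit is always reported as adjusted R² on the y scale,
1 − (1−R²)(n−1)/(n−p−1) with p the number of free parameters, so values are
comparable with conventional reports for these curves.

The initial guess for τ is the time at which y first exceeds half its
final observed value (median time as fallback), with restarts from 0.2×
and 5× on failure. A trajectory that never saturates (e.g. y ≡ 0) drives
τ̂ to the 10⁶-h bound and is returned flagged (`converged=False`); flagged
pairs are excluded from group statistics.

**Fit windows.** Spheroids younger than ~3 days compact (shrink) while
fusing, violating the constant-radius assumption; for them only the first
6 h of kinetics are fitted. Older pairs use the full 48-h record. R₀ is
always frozen at its first-frame value, because the model normalizes by
the *initial* radius. Both choices can be overridden per run.

**Group summaries.** Per-pair Γ/η values are averaged (mean ± SD over
pairs); the association of Γ/η with R₀ is tested with a two-sided Pearson
correlation. Under the model Γ/η is size-independent, so a significant
correlation flags a model violation.

## Doublet imaging

The imaging stage replaces manual measurement of the doublet silhouette.
Each frame is thresholded with Otsu's global method (the stereoscopic
images this emulates show dark spheroids on a light field; the minority
intensity class is taken as foreground), holes are filled, and the largest
one or two components are kept. A contrast guard (foreground/background
mean separation ≥ 4× the within-class spread) rejects object-free frames.

Geometry extraction proceeds in two stages:

1. **Width profile.** The doublet axis is the principal axis of the
   foreground pixels. The perpendicular extent per 1-px bin along the axis
   gives a width profile; two prominence-filtered maxima (the lobes) with
   a minimum between them establish that a neck exists and roughly where.
   A unimodal profile means the pair has fully fused — the frame is flagged
   (`NeckUndefinedError`) and excluded from fitting rather than assigned
   the theoretical final radius, so the plateau is inferred, not imposed.
2. **Two-circle refinement.** Away from the neck, the union boundary of
   two overlapping disks *is* the respective lobe's circle. Outer-boundary
   pixels on each side of the neck plane (±2 px exclusion) are fit with a
   circle (algebraic Kasa fit + Gauss–Newton refinement, +0.5 px outward
   correction for the half-pixel bias of boundary centers), and the neck
   radius is the analytic half-chord of the two fitted circles. This is
   an order of magnitude more precise than profile extents (worst-case
   ≤0.5 px vs ~2 px over random geometries) because boundary fits average
   hundreds of pixels and the chord is computed exactly. If the refinement
   is degenerate the profile minimum and cap-corrected split areas are
   used directly (the equivalent-circle radius of a split mask is corrected
   for the circular cap hidden beyond the neck plane — without that
   correction lobe radii are biased low by ~2–3%).

The measurement is rotation-equivariant by construction (PCA axis, no
image resampling). Separated pairs (two components) get r₀ = 0 and plain
equivalent-circle radii. Per-frame failures become missing points in the
assembled series, not aborts.

Limitations: the stage assumes the two-sphere geometry of the coalescence
model itself — real late-stage doublets that deviate from circular lobes
are measured as their best two-circle approximation, and frames where one
lobe has engulfed the other are not resolvable.

## Nanoindentation

The indentation protocol this package targets: spherical tip of radius
R = 9 µm driven 3.5 µm into the sample, held 1 s, retracted; Poisson ratio
ν = 0.5 (incompressible); forces in the nN range.

**Hertz analysis.** The loading segment from the contact point to a depth
of 0.1·R (900 nm for the 9-µm tip) is fit with

    F = (4/3) · E/(1−ν²) · δ^(3/2) · √R.

E enters linearly, so the fit is exact linear least squares through the
origin with an analytic standard error. The shallow window keeps the
half-space approximation honest for ~50-µm spheroids and limits substrate
influence for monolayers.

**Viscoelastic analysis (Ting / power-law rheology).** The material is
described by the relaxation modulus E(t) = E₁·t^(−α) — E₁ the modulus at
1 s, α the fluidity exponent (0 solid-like, →1 fluid-like). While the
contact area grows (load and dwell),

    F(t) = [4√R / 3(1−ν²)] ∫₀ᵗ E(t−ξ) · d(δ^{3/2})/dξ dξ,

and during retraction the upper limit is replaced by the auxiliary time
t₁(t) < t_peak defined by ∫_{t₁}^{t} E(t−ξ) δ'(ξ) dξ = 0; t₁(t) is
non-increasing and once it reaches 0 the tip has lost contact (F = 0).

Numerics, chosen for the weak singularity of the kernel (t−ξ)^(−α):

* the kernel is integrated **analytically per interval** against a
  piecewise-linear d(δ^{3/2})/dξ, so the singular point ξ = t is never
  evaluated and α = 0 reduces to the instantaneous Hertz force exactly;
* the contact-onset interval is special: δ^{3/2} has singular curvature at
  touchdown (locally ∝ (ξ−t_c)^{3/2} for any smooth drive), so there the
  kernel is integrated against that local power law exactly (incomplete
  Beta function), and the next 12 intervals are internally subdivided
  16-fold (depth linearly interpolated — exact for piecewise-linear
  drives). Against the closed-form Beta-function solution for ramp
  loading, F(t) = [4√R/3(1−ν²)]·E₁·v^{3/2}·(3/2)·B(3/2,1−α)·t^{3/2−α},
  the forward model is accurate to <10⁻³ relative for α ≤ 0.3 at ≥200
  samples, and halving the step changes forces by <10⁻⁴;
* t₁(t) is bracketed by a vectorized sign scan of the truncated integral
  at the grid nodes and then solved exactly within the bracketing interval
  (the discretized condition is closed-form in t₁ there); monotonicity of
  t₁ is enforced.

**Inversion.** `fit_plr` minimizes force residuals of the forward model
over (E₁, α) on the complete post-contact record, multi-started at
α ∈ {0.05, 0.2, 0.4} with E₁ initialized by linear projection at each
start, bounds E₁ > 0, α ∈ [0, 0.95]. Residuals are normalized by the peak
force so optimizer tolerances are meaningful at nano-newton magnitudes.
On noiseless synthetic cycles both parameters are recovered to <10⁻³
relative; with 1% force noise E₁ is recovered to ~0.1% and α to ~0.001
(the full calibration is run by the acceptance script). For α = 0 truth
the estimate sits at the boundary with E₁ equal to the Hertz modulus.

**Contact point.** A two-segment piecewise model over candidate split
samples: flat baseline before, power-law rise after, total squared error
minimized over the split and over a small grid of rise exponents
(1.2–1.5). The exponent grid matters: a ramp on a PLR material rises as
(t−t_c)^{3/2−α}, and pinning the exponent at the elastic 3/2 biases the
detected contact several samples early. The search stops at the first
peak-depth sample (dwell relaxation would otherwise corrupt the rise
model). A rise below 3× the baseline noise SD is "no contact"; a record
with no flat region is rejected as lacking a baseline.

**Cantilever compliance.** Recordings made in piezo coordinates are
converted to indentation via δ = z_piezo − F/k given the cantilever
stiffness k (0.041–0.05 N/m is typical for the instruments this emulates).
The correction is optional and off for synthetic curves, which are already
in indentation coordinates. The dwell is treated as depth-controlled; for
piezo-held dwells the small creep under cantilever compliance is
second-order at these stiffnesses.

**Sample summaries.** Replicate indentations (typically 3–4 per spheroid)
are first averaged within each spheroid when replicate structure is given;
means ± SD are then taken across spheroids. Flagged (non-converged) fits
are dropped. Moduli are reported in kPa.

## Derived tissue quantities

The effective surface tension is estimated by the scaling law Γ ~ E·R₀
(surface-layer stiffness times spheroid radius). It is an
order-of-magnitude estimator and every number derived from it is tagged as
"apparent" in the output provenance. The apparent viscosity is
η = Γ / (Γ/η), with the µm/h → m/h conversion made explicit; in SI the
chain collapses to the identity η = E·τ/2^(2/3), which the tests verify
exactly. Group-level η uses group-mean E, R₀ and Γ/η (one η per group);
heterotypic pairs, for which a single tension estimate is not defined, get
none. Stiffness and tension ratios are reported to one decimal; the
package reports unit-consistent viscosities with provenance rather than
attempting to reproduce any externally rounded values.

**Statistics.** Group comparisons run a normality screen per group
(Shapiro–Wilk plus the D'Agostino–Pearson omnibus test when n ≥ 8), then
one-way ANOVA and all pairwise two-sided t-tests with Bonferroni
correction (raw p × number of comparisons, clipped at 1), highlighting
p < 0.001. Calibration checks in the acceptance suite confirm the nominal
type-I error at α = 0.05 within binomial error over 1000 null simulations
and essentially full power at the soft-spheroid effect size (means
1.63 vs ~3.9 kPa, SDs 0.34–0.82, n = 20).

## Synthetic data: what it emulates and what it does not

The generators produce the statistical structure the analysis assumes:

* **Fusion trajectories** follow the coalescence law with per-pair radii,
  sampled at the experimental schedule 0.5, 1, 2, 3, 4, 6, 7, 24, 48 h,
  with mean-preserving lognormal multiplicative noise on r₀. The default
  noise CV of 0.05 is an assumption (no measurement-error estimate exists
  for the manual protocol this replaces); it corresponds to a few-pixel
  uncertainty on a ~100-µm neck and is the single most influential
  generator parameter for the fusion recovery rates. Compaction of young
  spheroids is modelled as linear fractional shrinkage (rate 1/h, floored
  at 10% of the initial radius) — the real process is only known
  qualitatively, and the linear form is the minimal one that reproduces
  "early window good, late window biased".
* **Cohorts** share one ground-truth Γ/η; per-pair R₀ ~ N(mean, sd)
  truncated positive (defaults 75 ± 20 µm, spanning the ~30–120 µm range
  such pairs occupy) and τ follows the droplet relation per pair. Pair
  count defaults to 12. Seeds derive from the master seed via spawned
  `SeedSequence` children, so cohorts are reproducible element-wise.
* **Doublet frames** are rigid intersecting disks (dark on light, 8-bit)
  whose center distance reproduces the commanded neck through the chord
  relation. No volume conservation, no intensity texture, no optics — the
  rendered frames test the *measurement* chain, not photorealism, so the
  imaging round trip bounds algorithmic error only, not real segmentation
  error on textured images.
* **Indentation cycles** drive depth as a ramp–hold–ramp (3.5 µm/s, i.e.
  a 1-s loading ramp, 200 Hz sampling — instrument-typical choices, the
  protocol source states depth and dwell but not speed), compute force
  with the same Ting forward model used in inversion, and add white
  Gaussian force noise. An optional pre-contact approach segment provides
  the baseline for contact detection. Because generation and inversion
  share the forward model, noiseless recovery tests are self-consistency
  checks; the independent evidence for the forward model itself is the
  Beta-function ramp oracle and the Hertz elastic limit.

## Problem sizes in the shipped checks

The test suite and acceptance script run: 200 fusion replicates per group
condition (three conditions) plus 16 cohorts of 12 pairs; 100 indentation
curves across the (E₁, α) ranges of the two spheroid types; 50 random
doublet geometries at 2 µm/px; 1000 null ANOVA simulations and 300 power
simulations. These sizes put Monte-Carlo standard errors comfortably below
the tolerances being checked while keeping a full run in minutes on one
core.

## Known limitations

* The coalescence model itself is descriptive: when fusion is governed by
  ECM remodeling or collective migration rather than visco-capillary flow,
  τ and Γ/η remain well-defined fit parameters but lose their literal
  material interpretation. The package reports fit diagnostics (adj. R²,
  correlation of Γ/η with R₀) precisely so such violations are visible.
* Γ ~ E·R₀ has no prefactor; only ratios and orders of magnitude of the
  derived tension/viscosity are meaningful.
* The Ting inversion assumes a single load–dwell–retract cycle, depth
  control, no adhesion (no negative force branch) and the PLR form;
  multi-term relaxation spectra and JKR/DMT adhesion are out of scope.
* Imaging handles one doublet per field, bright-field-like contrast, 2-D
  silhouettes only.
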