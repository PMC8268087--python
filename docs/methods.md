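# Methods

This note documents the models, numerical choices and known limitations of
`ivdmech`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Viscoelastic ramp–hold indentation

### Model

The tissue is modelled as a standard linear solid: a spring E₀ (kPa) in
parallel with a Maxwell arm (spring E₁, dashpot with time constant τ₁),
relaxation modulus G(t) = E₀ + E₁·e^{−t/τ₁}. For a rigid sphere of radius
R on an incompressible (ν = 0.5 by default) half-space, elastic–viscoelastic
correspondence replaces the Hertz modulus with a hereditary integral:

    P(t) = K ∫₀ᵗ G(t−u) d[h(u)^{3/2}]/du du,   K = 4√R / (3(1−ν²)).

For the trapezoidal command (ramp h = vt to h_max, then hold) the integral
reduces to I(t) = ∫₀ᵗ e^{u/τ}√u du. Substituting s = u/τ gives the closed
form e^{−t/τ}·I(t) = τ^{3/2}(√x − dawsn(√x)) with x = t/τ, where `dawsn`
is the Dawson function. This damped form is evaluated directly and is
numerically stable for all x ≥ 0 (the naive e^{t/τ}-scaled form overflows
for t ≫ τ). Ramp phase:

    P = K [E₀ (vt)^{3/2} + (3/2) E₁ v^{3/2} τ^{3/2} (√x − dawsn √x)]

Hold phase: the ramp integral is frozen at t_R and decays as
e^{−(t−t_R)/τ}. An adaptive-quadrature evaluation (`method="quad"`) is kept
as an independent numerical route; tests require agreement with the closed
form to 1e-8 relative over τ₁/t_R ∈ {0.1, 1, 10}, and both are checked
against a brute-force trapezoid convolution written inside the test suite.

The unload segment is *not* modelled (adhesion and loss of contact make it
unreliable for soft hydrated tissue); fitting uses loading + holding only.
The synthetic generator still produces an unload branch — via a
trapezoid-rule hereditary integral over the full depth history — so that
realistic whole records exercise segment selection.

### Units

User-facing quantities are the instrument's units (s, μm, μN, kPa);
conversion to SI happens once inside the numerical kernels. In mixed
μm–kPa units the Hertz force comes out in nN, a classic factor-of-1000
trap; the single conversion boundary avoids it.

### Contact detection

Contact is a sustained force rise above the pre-contact baseline: the
smoothed force (moving average, default 5 samples) must exceed the baseline
by δ = max(0.003 μN, 0.005 × rise) and stay above for 5 samples. The
baseline (mean + linear drift) is estimated twice: first from the leading
samples, then refit on everything safely before the first crossing. Error
modes: no crossing → `NoContactError`; a "baseline" that itself climbs by
more than five thresholds (the record opens in contact) →
`AmbiguousContactError` (callers may force index 0 for pre-zeroed curves).

The bare threshold crossing is systematically *late*: the force needs time
to build up to δ, so zeroing there clips the first tens of nanometres of
indentation and biases the fitted moduli by several percent. By default the
detector therefore back-extrapolates: over the early rise (between δ and
25 % of the full rise, with some pre-crossing baseline included) it fits
the quasi-elastic Hertzian power law P − P₀ = A·max(t − t₀, 0)^{3/2} by
least squares and takes t₀ as the contact time. This refinement is a flag
(`refine=False` restores the raw crossing). Fitting the raw residuals
rather than a linearised (P−P₀)^{2/3} transform keeps the estimate
unbiased under additive noise.

### Parameter estimation

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective) on (E₀, E₁, τ₁) with E₀, E₁ ≥ 0 and
τ₁ ∈ [sample interval, 10·t_hold]. The ramp end is identified from the
displacement command (first sample at 99 % of h_max), but the ramp *speed*
comes from a mid-ramp (10–90 %) regression — the 99 % crossing alone
under-estimates the ramp duration by up to one threshold width, which
propagates into a ~1 % modulus bias. Initialisation: E₀ from the hold
plateau force, E₀+E₁ from an early-ramp secant, τ₁ from a log-linear fit of
the hold decay; a coarse multi-start grid over τ₁ and the modulus split is
tried on non-convergence. Fits with τ₁ pinned at a bound are flagged
(`at_bounds`) but retained; exclusion is the caller's choice. The
containment bounds guarantee f ∈ [0, 1] for every converged fit.

### Validity criteria

Representative contact strain uses Tabor's convention 0.2·a/R with
a = √(R·h_max); at R = 42 μm, h_max = 2 μm this gives 4.4 %, consistent
with the < 5 % design criterion (a h/R-type definition would not be).
Substrate effects are flagged when h_max exceeds 10 % of the section
thickness (2 μm on 25 μm sections → 8 %, acceptable).

## Fibre orientation

### Structure tensor

Gradients are the exact derivatives of a separable cubic B-spline
interpolant of the image: the 2-D spline prefilter
(`scipy.ndimage.spline_filter`, mirror boundaries) followed by the
derivative kernel [−½, 0, ½] along the derivative axis and the B-spline
weights [⅙, ⅔, ⅙] along the other. A central-difference fallback is
selectable and must agree with the spline route within 2° on phantoms
(cross-validated in the tests). Tensor components ⟨gx²⟩, ⟨gx·gy⟩, ⟨gy²⟩
are Gaussian-windowed with σ = 10 px (truncated at 3σ, reflective
boundaries) — σ is interpreted as the standard deviation of the averaging
kernel. With y measured upwards, the orientation **along** structures is
θ = ½·atan2(−2Jxy, Jyy−Jxx), folded to [0°, 180°), and coherency is
(λmax−λmin)/(λmax+λmin), defined as 0 where the tensor trace vanishes
(constant image: zero coherency, masked θ, no exception).

Angle convention: 0° is the image x-axis (the dorsoventral axis under the
default axis convention), increasing counter-clockwise. The synthetic fibre
renderer uses the same convention, so round trips close without sign
gymnastics; the grating and rotation-equivariance tests pin the convention
down to ±1°.

### Masks, quadrants, statistics

Pixels enter statistics iff intensity > 5 % of the image maximum AND
coherency > 0.05, both strict inequalities (raw image intensity, not tensor
energy). The ROI is split at the midpoints into cranial/caudal ×
dorsal/ventral quadrants; odd dimensions give the extra pixel to the
caudal/ventral half. Flipping an axis polarity in the `AxisConvention`
swaps labels only.

Orientations are axial (θ ≡ θ+180°): summaries double the angles, average
the resultant vector, and halve back. Dispersion is the axial circular SD
½·√(−2 ln R̄) in degrees (this equals `scipy.stats.circstd(…, high=180)`,
cross-checked in tests). A region with mean resultant length R̄ < 0.1 is
flagged as having no predominant orientation. Histograms use 36 bins of 5°
over [0°, 180°); the binning is a display choice and does not enter the
statistics. The across-sample table reports the axial circular mean of the
per-sample means and the root-mean-square axial deviation from it (for
three tightly clustered samples this coincides with the arithmetic mean
± SD to well under a degree; both interpretations of a "± SD across n = 3
samples" are thereby served).

## Group statistics

The design is nested: ≥ 6 indents per structure within each specimen,
3 specimens per group. The group effect is tested with specimen as a random
factor. For this one-way layout the F-test with containment denominator
degrees of freedom (n_specimens − n_groups, hence F(1, 4) for 3 + 3) is
*identical* to a one-way ANOVA on specimen means; that equivalence is taken
as the normative definition and enforced against `scipy.stats.f_oneway` to
1e-10 in the tests. Unbalanced indent counts are handled by weighting
specimen means equally. df₂ never depends on indent counts. Significance is
fixed at α = 0.05 with no multiple-testing correction (a deliberate mirror
of the small-sample design; a limitation, not an oversight).

Outlier exclusion: within each structure × level × stage × group cell
(pooled over specimens; per-specimen cells available via the `cell`
argument), values deviating from the cell mean by more than 3 sample SDs
are removed in a single pass — the rule is not iterated. Note a structural
property of k-sigma rules: in a cell of n observations the largest
attainable standardised deviation is (n−1)/√n, so with n ≈ 11 a single
gross outlier can never exceed 3 SD of the contaminated cell; the rule only
has power in larger cells.

## Synthetic data: what it emulates, what it does not

The indentation generator reproduces the study conditions: trapezoidal
displacement control at 2 μm/s to 2 μm with a 10 s hold (ramp time 1 s),
R = 42 μm, ν = 0.5, 100 Hz sampling, a pre-contact approach baseline, and
additive i.i.d. Gaussian force noise plus optional linear drift. Cohorts
follow the nested design (3 specimens per group, ≥ 6 indents per
structure), with specimen-level parameters drawn from a between-specimen
normal and indent-level values from a within-specimen normal; the default
TS24 cell means/SDs follow the group summary statistics of the study, with
two thirds of the printed variance assigned between specimens and one third
within (a typical split for technical replicates nested in biological
ones — the published tables do not resolve it). Since no relaxation time is
published, cohorts default to τ₁ = 2 s, which is ≪ the 10 s hold so the
equilibrium modulus is identifiable.

Deliberately not emulated: cantilever compliance (commanded displacement is
treated as indentation depth; the 0.48 N/m spring constant is carried as
metadata only), adhesion, poroelastic drainage, thermal drift nonlinearity,
and any substrate stiffening. Passing round-trip tests therefore shows the
*estimator* is correct and noise-robust, not that real curves are free of
these effects.

The phantom generator renders straight anti-aliased fibres with Gaussian
cross-section (σ = width/2) at axial wrapped-normal angles, uniform
centres, optional per-quadrant distributions, plus Gaussian background
noise. It does not simulate confocal optics (PSF, depth attenuation),
fibre curvature, crossings statistics or bundling; a trivial stack option
exists only to exercise maximum-intensity projection. Orientation recovery
within 1–3° on phantoms validates the tensor pipeline and conventions, not
segmentation of real histology.

## Problem sizes and determinism

Default analyses are sized for interactive use: 100 Hz curves (~1100–1400
samples), 512×512 phantoms with 200 fibres, 500-replicate null simulations
for the type-I-error check, 50-seed noise sweeps for recovery statistics.
All stochastic paths take explicit seeds (`numpy.random.default_rng`);
identical spec + seed reproduces outputs bit for bit, and the pipeline
manifest records the config hash and seed so every output is regenerable
from config + seed alone.

## Known limitations

- The SLS has a single relaxation time; tissues with broad spectra will
  show systematic hold-phase residuals that the `rmse`/`r_squared`
  diagnostics surface but the model cannot absorb.
- Contact back-extrapolation assumes the early response is Hertzian-like
  (power 3/2); strong adhesion or an initial jump-to-contact would bias it.
- The orientation pipeline assumes roughly uniform illumination; the 5 %
  intensity mask is global, so strong vignetting shifts region statistics.
- The specimen-mean ANOVA equivalence holds exactly for the balanced
  specimen design it is defined on; with unequal specimen counts per group
  it remains a valid equal-weights test but is no longer the REML mixed
  model.
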