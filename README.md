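# ivdmech

Quantitative analysis tools for the mechanics and micro-structure of the
prenatal intervertebral disc (IVD): viscoelastic characterisation of soft
embryonic tissue by spherical nanoindentation, and quantification of
collagen fibre organisation in the annulus fibrosus (AF) from fluorescence
images. The package targets the comparison of normal embryos against
muscle-less (*mdg*, muscular dysgenesis) mutants, in which fetal muscle
contractions are absent, but the machinery is generic: any ramp–hold
indentation campaign on thin soft sections and any fibrous-texture
orientation analysis with a nested group design can use it.

Because raw instrument exports and confocal stacks for such studies are
rarely deposited, the package ships first-class synthetic generators that
emulate the experimental design (trapezoidal displacement control, nested
specimens-within-groups cohorts, fibrous phantom images with known
per-quadrant orientation). Every analysis stage is validated against the
ground truth those generators carry.

## The models

**Viscoelastic indentation.** A rigid sphere of radius R indenting an
incompressible half-space elastically gives the Hertz force
P = 4√R·E·h^{3/2} / (3(1−ν²)). Time dependence is introduced by
elastic–viscoelastic correspondence: the modulus is replaced by a Boltzmann
hereditary integral over the relaxation function of a standard linear solid
(SLS) — a spring E₀ in parallel with a Maxwell arm (spring E₁ + dashpot,
time constant τ₁), G(t) = E₀ + E₁·e^{−t/τ₁}:

    P(t) = 4√R / (3(1−ν²)) · ∫₀ᵗ G(t−u) · d[h(u)^{3/2}]/du du

solved in closed form (via the Dawson function) separately for the loading
ramp h = vt and the hold h = h_max. Fitting P(t) over ramp + hold yields
the instantaneous modulus E_ins = E₀+E₁, the equilibrium modulus
E_eq = E₀, and the elastic fraction f = E_eq/E_ins ∈ [0, 1] (1 = purely
elastic, 0 = purely viscous).

**Fibre orientation.** Per-pixel orientation θ ∈ [0°, 180°) and coherency
C ∈ [0, 1] come from the eigenstructure of the Gaussian-windowed structure
tensor (cubic-spline image gradients, window σ = 10 px). Pixels with
intensity > 5 % of the maximum and coherency > 0.05 enter region
statistics; regions are the four quadrants (cranial/caudal ×
dorsal/ventral) of the ROI. Orientations are axial, so means and
dispersions use circular statistics on doubled angles.

**Group comparison.** Properties are compared between groups with group as
a fixed factor and specimen as a random factor; with 3 specimens per group
the group F-test has the containment degrees of freedom (1, 4). Per-cell
observations deviating more than 3 SD from the cell mean are excluded in a
single pass.

## Worked example

Simulate one noisy indentation curve at typical annulus fibrosus
parameters, detect contact, and fit the SLS model:

```python
from ivdmech import SLSParams, detect_contact, fit_sls
from ivdmech.synthetic import SyntheticIndentSpec, generate_indent_curve

params = SLSParams.from_moduli(E_ins=24.0, f=0.74, tau1=2.0)   # kPa, -, s
record = generate_indent_curve(
    SyntheticIndentSpec(params=params, baseline_duration=1.0,
                        noise_sd=0.002, seed=1)
)
contact = detect_contact(record)          # 0.003 uN force-rise criterion
fit = fit_sls(record, contact)            # ramp + hold least squares
print(f"E_ins = {fit.E_ins:.2f} kPa, f = {fit.f:.3f}")
```

prints

```
E_ins = 23.83 kPa, f = 0.741
```

i.e. the generating instantaneous modulus (24 kPa) and elastic fraction
(0.74) are recovered within ~1 % despite 2 nN of force noise and an unknown
contact point. The same round trip on a fibrous phantom:

```python
from ivdmech.orientation import apply_masks, circular_summary, orientation_field
from ivdmech.synthetic import FiberImageSpec, generate_fiber_image

phantom = generate_fiber_image(
    FiberImageSpec(n_fibers=200, angle_mean=87.0, angle_sd=5.0,
                   noise_sd=0.02, seed=1)
)
field = apply_masks(phantom.image, orientation_field(phantom.image))
s = circular_summary(field.theta[field.valid_mask])
print(f"recovered {s.circular_mean:.2f} deg over {s.n_pixels} pixels")
```

```
recovered 86.46 deg over 152843 pixels
```

recovers the 87° ground-truth mean orientation within half a degree.

A full synthetic cohort (2 groups × 3 structures × 3 specimens × 6 indents,
plus phantom images per group) runs from the command line:

```sh
ivdmech run --seed 0 --out demo-output
```

which writes per-indent fit tables, the group-comparison table
(F, df, p per structure and metric), per-region orientation summaries and a
run manifest under `demo-output/`.

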