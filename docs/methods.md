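# Methods

## Model

`boneplug` models the load transfer between a cemented, skeletally
attached amputation prosthesis and the residual femur as a small-strain
linear-elastic problem on a parametric, axisymmetric-geometry (but fully
3-D) assembly:

* **stem** — solid frustum, 12 mm diameter distally tapering to 9 mm at
  the tip, 120 mm long; isotropic, E = 115 GPa (Ti6Al4V), ν = 0.30;
* **cement** — PMMA mantle, 1 mm thick distally, thickening linearly to a
  configurable 2 mm proximally; isotropic, E = 2 GPa, ν = 0.40;
* **bone layer** — 2 mm of periprosthetic cortical bone around the mantle;
* **outer bone** — a parametric cortical wall (default 5 mm) standing in
  for the residual femur, continuing past the stem tip as a tube to the
  201 mm residual length.

Cortical bone (both bone parts) is orthotropic with E_X = 12.00,
E_Y = 20.00, E_Z = 13.40 GPa, ν_XY = 0.22, ν_YZ = 0.35, ν_XZ = 0.38,
G_XY = 5.61, G_YZ = 6.23, G_XZ = 4.53 GPa, expressed in a cylindrical
frame (X = radial, Y = axial, Z = circumferential) and rotated per element
to the global frame by the full fourth-order tensor transform. The
conjugate Poisson ratios follow compliance symmetry ν_ji = ν_ij E_j / E_i.
Cancellous bone is omitted.

The outer wall replaces CT-derived anatomical geometry deliberately: the
assembly is then fully parametric, reproducible from a dozen numbers, and
the physics of interest — stiffness-proportional load sharing between stem
and periprosthetic bone — is preserved. Consequences of this idealisation
are listed under *Limitations*.

All interfaces are fully bonded (shared nodes). This matches an
osseointegrated state and the stiffness-sweep load case of the physical
study; frictional or separating contact at the distal interfaces is the
model's main fidelity deviation and is out of scope.

### Boundary conditions

The distal face is fixed over the spigot footprint: all nodes at y = 0
with r ≤ 9 mm (stem + cement + bone-layer faces). The 18 mm spigot
diameter equals the bone-plug outer diameter, and in the stiffness-sweep
configuration the distal bone faces are bonded to the (rigidly potted)
collar, so fixing the whole plug face is the faithful idealisation;
fixing the stem face alone would create a free-edge unloading boundary
layer in the distal bone exactly where the slice band sits.

Loads are applied on the proximal face as the minimum-norm nodal
distribution whose resultant force equals the load-case components and
whose resultant moment equals `lever_arm × force`. The default lever arm
(−40 mm, medial) stands in for the femoral-head offset and produces the
distally increasing mediolateral bending moment characteristic of stance
loading. Two load cases are built in: the validation case (842.8 N =
86 kg × 9.8 m s⁻² decomposed by direction cosines for 6.9° adduction and
2.0° flexion; anteversion spins the bone about its own axis and does not
enter the axial decomposition, which is also the only decomposition
consistent with all three published components) and the early-stance
hip-contact case (−804.05, −1957.53, −141.95) N taken verbatim rather than
re-derived from musculoskeletal data.

## Meshing

Cross-sections are meshed with a square central core mapped onto the disk
by the elliptical map (u, v) → (u√(1 − v²/2), v√(1 − u²/2)) — which sends
the square boundary exactly onto a circle — surrounded by concentric rings
of quadrilaterals; sections are extruded axially into 8-node hexahedra.
Pure ring meshing cannot hex-mesh the solid stem without degenerate
elements at the axis, hence the core. The sector count keeps the worst
circumferential arc within 3× the element edge length.

All radii carry a single area-preserving scale factor
κ = √(2π / Σ sin Δθ_j) so every polygonal ring has exactly the area of the
annulus it discretises; with radii linear in y this makes every meshed
part volume equal the analytic frustum/shell volume to roundoff at any
resolution — the volume checks are therefore exact conformity checks, not
resolution-dependent approximations.

`refine` scales the structured counts (sectors, radial divisions, axial
divisions) directly instead of re-deriving them from the edge length, so
successive refinements are exactly self-similar — the premise of
Richardson extrapolation. Within the slice band the axial stations align
with the slice planes (one element layer per 1.09 mm slice by default).

Elements are trilinear hexahedra with full 2×2×2 Gauss integration (no
reduced integration or hourglass control, keeping the element free of
stabilisation parameters and easy to check against closed forms).
Quadratic 20-node elements are not implemented; discretisation error is
controlled by the Richardson criterion instead of element order.

## Fields and instrumentation

Strains are evaluated at Gauss points (volume-averaged per element) and at
element corners for nodal recovery; nodal strain is the average over
elements sharing the node. Corner evaluation matters: averaging element
*centroid* strains onto surface nodes under-reads bending strain by a
systematic radial offset and spoils convergence.

SED is U = ½ σ : ε per Gauss point, volume-averaged per element. With
engineering shear in Voigt storage, Σ U·V equals the external work
½ fᵀu identically; the energy-balance check in the tests is therefore a
consistency identity, verified to 1e-8.

A virtual uniaxial gauge reads the mean nodal axial strain over a square
footprint (side = gauge length) on the outer surface. The physical gauge
length is 1 mm; the pipeline's default sites use a 4 mm footprint so the
patch contains surface nodes at desk-scale resolution. The DIC-like
comparison uses the central 95% inter-percentile span of a displacement
component over a surface region (robust to outlying nodes); the visible
region is a configurable node mask rather than a camera model.

## Remodelling classification

The mechanostat band 0.0036 ≤ U/ρ ≤ 0.0044 J g⁻¹ is converted to
volumetric bounds with an apparent density of ρ = 1.8 g cm⁻³ (typical
cortical bone; the density behind the published conversion is not stated,
so it is configurable). Defaults give 6480–7920 J m⁻³. Slice fractions are
computed by exact element-area weighting (element volume / axial extent)
rather than image-based area measurement, removing rasterisation error;
fractions sum to 1 per slice by construction. The distal-to-proximal trend
statistic is the mean of per-step relative changes of a fraction across
slices; steps with a zero baseline are skipped and logged, since the
relative change is undefined there.

The slice band is 11 × 1.09 mm element layers starting at the osteotomy
plane — the distal end of the bone layer, where load transfer and stress
shielding are strongest. A band of that pitch cannot tile the whole 120 mm
layer, so it is anchored distally, with slice 1 adjacent to the osteotomy
face.

## Validation statistics

* **Lin's CCC** uses population (1/n) moments; this convention reproduces
  the published span concordance of 0.997 from the printed spans, while
  the sample (n − 1) convention gives 0.998.
* **Richardson extrapolation** takes solutions at normalised edge lengths
  (2, 1, 0.5), computes the observed order
  p = ln(Δ₁/Δ₂)/ln 2 and the extrapolated value, and reports the relative
  error at the finest level; oscillatory sequences are rejected with a
  request to refine. Convergence is declared below 1% relative error.
* **OAT sensitivity** uses the sample SD (n − 1) over model variants,
  reported as a percentage of the mean per gauge; the published variant
  roster is not reproduced — the module provides the machinery over a
  user-supplied variant grid.
* The published strain concordance of 0.934 is *not* recoverable from the
  four printed mean strain pairs under either moment convention (it likely
  involves the untabulated per-increment data), so it is documented here
  and not asserted anywhere.

## Synthetic measurements

Virtual gauge readings are the linearly scaled unit-load truth plus
independent Gaussian noise with the published per-gauge SDs
(5.2, 8.5, 2.9, 12.7 µε); DIC samples add isotropic Gaussian noise of
1 µm. A seed fixes every draw. The stepped 0.33–3.5 BW protocol is
represented as independent readings per step — the elastic model has no
hysteresis, so the loading/unloading branches are identical. Not emulated:
gauge misalignment, adhesive/coupon mechanics, speckle imaging, dwell-time
drift. Passing the recovery tests therefore shows the statistics pipeline
is unbiased under the assumed noise law, not that a physical experiment
would achieve those errors.

## Problem sizes and tolerances

Desk-scale discretisations are used throughout: 3–5 mm element edge
lengths (10³–10⁴ elements) for the solved cases, against the 0.625 mm
production resolution of the element-count budget the assembly was
originally studied at. This is a deliberate choice: the analytic oracles
(transformed-section axial strain, Euler–Bernoulli bending strain) agree
with the FE solution within 0.2–0.6% at these sizes, comfortably inside
the 2%/3% acceptance tolerances, and the Richardson study shows < 1%
discretisation error at the 5 mm base level for the gauge functional.
Direct sparse factorisation (SuperLU) with a 1e-8 relative-residual
contract; solves failing the residual, equilibrium or positivity checks
raise rather than warn.

Numerical edge cases: inadmissible elastic constants are rejected by
naming the offending stiffness eigenvalue; degenerate load faces
(collinear nodes) are rejected before solving; empty gauge footprints,
empty DIC regions, empty slices and zero-reference percentage errors all
raise; a zero-mean gauge in the sensitivity summary is flagged NaN rather
than fatal.

## Limitations

* Parametric cylinders, not anatomical geometry: absolute SED magnitudes
  and slice fractions are specific to this idealised assembly; only the
  directions and orderings (flexible stem → more apposition, less
  resorption; apposition falling proximally) are claimed, and those are
  what the acceptance tests assert.
* Fully bonded interfaces: no frictional slip, no debonding, hence no
  contact-driven sensitivity at the distal gauges.
* Linear elasticity: no viscoelasticity, fatigue, or time-stepping
  remodelling (density-update laws are out of scope; the classification is
  a single-time-point likelihood map).
* The homeostatic band and density conversion are treated as fixed
  thresholds, not calibrated quantities.
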