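# Methods

This note documents the models implemented in `pulmoflow`, the
defaults and their rationale, the numerical schemes, and what the
synthetic phantoms do and do not establish about real data.

## Synthetic 4D-flow phantom

**Geometry.**  A rigid Y-vessel: a straight main pulmonary artery
(MPA) of radius 17.5 mm and length 30 mm bifurcating into left and
right branches (LPA 11.5 mm, RPA 12 mm radius, 40 mm long) at ±55°
from the MPA axis.  These are typical dimensions of a dilated PAH
pulmonary trunk; they were chosen so that the largest cohort stroke
volume (184 mL at a 0.92 s cycle) keeps analytic peak velocities below
the default 1.5 m/s velocity-encoding limit with margin, and so that
the branch lumens separate well inside the volume.  The two branch
cylinders emanating from one point overlap for some distance; the
**carina** — the most distal cross-section whose lumen is still
singly connected — is located by scanning analytic cross-sections at
0.5 mm resolution, and the ground-truth region labels place the
MPA/branch boundary there.  This matches both anatomy (an observer
splits the vessel where the lumen splits) and the automatic
bifurcation detector in `segmentation.label_regions`, which marches
voxel slices from the inlet and splits at the first slice with two
8-connected lumen components.

**Velocity field.**  Inside each cylindrical segment the field is the
exact axisymmetric Womersley solution for the prescribed volumetric
flow waveform, written as one-sided Fourier coefficients c_n of
Q(t) = Re Σ c_n e^{inωt}: the n = 0 term is the Poiseuille parabola,
higher modes use J₀ Bessel functions of complex argument
Λ = i^{3/2}α_n with α_n = R√(nω/ν).  The branch waveforms are the
inlet waveform scaled by the flow split (RPA fraction f, LPA 1 − f),
so cross-section quadrature recovers Q(t) exactly in every segment
and wall shear rate has a closed form — the oracle for every
downstream estimator.  The default waveform is a half-sine systolic
ejection over T/3 with zero diastolic flow, scaled to the stroke
volume (A = 3πSV/2T) and truncated to 10 harmonics; because the
truncated series is band-limited, the uniform 25-frame sampling
integrates it exactly (periodic trapezoid), which is why stroke-volume
recovery errors are dominated by spatial, not temporal, quadrature.
The kinematic viscosity of the analytic field is ν = 3.3×10⁻⁶ m²/s
(the high-shear blood value at ρ = 1060 kg/m³).

**Voxel sampling.**  Voxels are sampled at their centres; voxels whose
26-neighbourhood crosses the lumen boundary average 27 sub-samples
(3 per axis) with velocity zero outside — the partial-volume dilution
that real phase-contrast data shows at the wall.  The magnitude image
is the lumen partial-volume fraction.  Optional zero-mean Gaussian
noise (seeded; `numpy` Generator) is added to each phase component,
then clipped at the venc.  Default acquisition: 25 frames at
(2, 2.5, 2.5) mm spacing, matching clinical 4D-flow resolution; venc
1.5 m/s.  Aliasing is deliberately *not* modelled: a spec with
analytic peak velocity above the venc raises instead.

**What the phantom does not emulate:** k-space physics, eddy-current
or background-phase offsets, phase wrapping, wall motion, intra-voxel
dephasing, or anatomically irregular lumens.  Passing tests establish
correctness of the estimators under known smooth fields — not their
robustness to those artefacts.

## Segmentation

The lumen is the voxel-wise Boolean union of three velocity-phase
masks and a magnitude mask (each direction "sees" the segments where
its component dominates), cleaned to the largest 26-connected
component (ties broken toward the lexicographically smallest voxel).
Regional labels: MPA proximal to the auto-detected carina, distal
in-slice components assigned LPA/RPA by centroid side; a user plane
overrides detection.  Outlet analysis planes are **branch-axis
normal** (principal axis of each branch's voxels by PCA, oriented
distally): with steep branch angles, an axial-slice plane cuts the
branch obliquely and is truncated by the branch end, which was found
to undercut flux by ~8%.

## Flow quantification

Plane sampling is trilinear on a regular in-plane grid at half the
smallest voxel spacing.  Two weighting modes are used deliberately:
flux integrals (Q(t), stroke volume, branch split) sum the
interpolated field with *unit* weights over the one-voxel-dilated
lumen support, because partial-volume averaging already conserves the
velocity integral — weighting again by lumen fraction would
double-count the dilution; lumen *averages* (plane-mean velocity) use
the interpolated indicator weights instead.  Branch fluxes are
measured on the axis-normal outlet discs restricted to the whole
lumen mask (each disc geometrically cuts one branch only), and split
fractions are normalised over the two branches so they sum to one.
Peak systole is defined as the frame of maximum inlet volumetric
flow; the plane-mean peak-systolic velocity uses velocity magnitude
by default with a through-plane-component option, since which of the
two the reference workflow used is not determinable.

## Pressure estimation

Simplified Bernoulli peak PAP = 4v² + RAP (mmHg; v in m/s), Chemla
mean PAP = 0.61·peak + 2, and the strict mPAP > 20 mmHg PH
classification.  The single pressure-unit constant 133.322 Pa/mmHg is
used package-wide.

## Windkessel tuning and 0D simulation

Each branch outlet is a 3-element Windkessel: C·dP_c/dt = Q −
(P_c − P_d)/R₂ with P = R₁Q + P_c.  Tuning uses only non-invasive
inputs: R_total = (target mean PAP − P_d)/Q̄ per branch, split
R₁ = f·R_total, R₂ = (1 − f)·R_total, C = τ/R₂.  Back-deriving f and
τ from the shipped cohort parameters gives f ≈ 0.04–0.21 and
τ = R₂C ≈ 0.60–0.72 s, so the defaults f = 0.1, τ = 0.7 s sit
mid-range; distal pressure defaults to zero, consistent with
back-computing R_total from the printed values.  Note the printed
per-branch parameters imply *different* per-patient mean pressures
for LPA and RPA (e.g. ≈38 vs ≈28 mmHg for the first patient), so the
exact original tuning inputs are not recoverable; the tuner therefore
targets a single per-patient pressure.  Integration is fixed-step
classical RK4 at dt = 0.005 s (the ODE is mildly stiff at worst:
τ ≫ dt); cycle indices carry a half-step guard so boundary samples
stay in the cycle they close.  The periodicity metric is
100·max|a − b|/max|b| between consecutive cycles; from a discharged
bed it decays geometrically at e^{−T/τ}, crossing 1% after ~5 cycles
for τ ≈ T.

## Tube solver

Full-scale 3D patient CFD is out of scope; the solver's role is
to exercise the same methodology — prescribed inlet profile,
shear-thinning rheology, coupled Windkessel outlet, run-to-periodicity
— in a geometry with exact oracles: a straight axisymmetric rigid
tube.

Staggered (r, z) grid: axial velocity at radial centres / axial
faces, radial velocity at radial faces / axial centres, pressure at
cell centres; default 64 × 32 cells.  Incremental pressure projection:
a predictor with the lagged pressure gradient and θ-implicit viscous
terms (θ = 1, backward Euler, by default), then a pressure-increment
Poisson solve (direct sparse factorisation, computed once) enforcing
discrete incompressibility to machine precision — instantaneous
inlet/outlet mass balance is exact up to solver roundoff.  Convection
is explicit (upwind axially, central radially) and CFL-checked; a
violation raises with the step number, and runs choose dt accordingly
(dt = 0.005 s suits velocities up to ~0.3 m/s at default resolution;
pulsatile validation cases use 0.0025 s).  Viscosity is evaluated from
the previous step's generalized shear rate √(2D:D); the viscous
matrices are refactorised only when the viscosity field drifts beyond
0.5%, which bounds the induced error well below the WSS tolerance.

Two wall closures matter for wall shear accuracy: the viscous wall
flux uses a ghost-extrapolated quadratic (second-order) Dirichlet
closure, and wall shear rate is extracted with a three-point one-sided
cubic fit through the no-slip wall value.  With the naive half-cell
flux the Womersley wall-shear L2 error at default resolution was
5–7%; with these closures it is ≈0.4% (velocity ≈0.05%), and the
steady Poiseuille state is reproduced to machine precision.

The Windkessel couples explicitly: the outlet flow of step n advances
P_c, and the resulting pressure is the Dirichlet outlet value of the
projection.  The compliance pressure initialises to R₂·Q̄ (a
pre-charged bed) unless a discharged start is requested.  Runs
continue until the outlet-pressure periodicity metric drops below the
configured tolerance (1% default, minimum three cycles), and
`converged_final_cycle` fails loudly with the achieved metric
otherwise.

**Laminar regime.**  The transition criterion Re_peak < 150·α is
evaluated with the dimensionally consistent Womersley number
α = (D/2)√(ωρ/μ), ω = 2π/T, taking the high-shear viscosity as
reference.  (Describing α itself as "2π/period" conflates α with ω;
the package treats that phrase as defining ω.)  Under this standard
definition some cohort-scale conditions land *above* 150·α, so the
solver reports both numbers and warns rather than asserting
laminarity; simulations remain laminar by construction
(axisymmetric, no turbulence model).

## Rheology

Quemada law μ = μ_p(1 − k(γ̇)φ/2)⁻² with
k = (k₀ + k_∞√(γ̇/γ_c))/(1 + √(γ̇/γ_c)).  Defaults are the standard
literature constants for normal blood — μ_p = 1.32 mPa·s, φ = 0.45,
k₀ = 4.33, k_∞ = 2.07, γ_c = 1.88 s⁻¹ — giving a high-shear plateau
of ≈3.4 mPa·s; all are configurable since the exact constants behind
any given study are rarely printed.  Shear rates are floored at
10⁻³ s⁻¹ to avoid the zero-shear blow-up (0.5·k₀·φ ≈ 0.97 is close to
the singular value 1).  The high-shear limit μ_∞ is the reference
viscosity for Reynolds/Womersley numbers and for voxel-grade WSS.

## Wall shear stress and the resolution bias

Fine-grid WSS is μ(γ̇_w)·γ̇_w from the solver's wall trace; TAWSS is
the trapezoidal cycle average of |WSS| per wall location, and regional
averages are area-weighted over MPA or MPA+LPA+RPA wall elements.

The voxel-grade estimator mimics 4D-flow post-processing: per wall
patch (region × axial station × angle), the tangential velocities of
the nearest `fit_depth` (default 2) lumen voxels along the inward
normal are regressed against wall distance with the intercept pinned
at the analytically known wall position, and WSS = μ_ref × slope with
the Newtonian high-shear μ_ref (coarse data cannot support
shear-dependent viscosity).  Because the first voxel centre sits a
millimetre or more into a boundary layer that is itself ~1 mm thick,
the fitted slope underestimates the true gradient — for steady
Poiseuille flow a one-voxel fit at depth d recovers exactly
γ̇_w(1 − d/2R).  On the default phantom the coarse/fine TAWSS ratio
falls from ≈0.48 at 1 mm voxels to ≈0.18 at 2.5 mm and ≈0.11 at 5 mm:
the same direction and order of magnitude as the published gap
between plane-based 4D-flow TAWSS and model-based values, whose
absolute patient numbers are out of scope here.  Wall distances are
measured from the exact analytic wall, so the bias isolated is purely
resolution, not registration; a residual curvature effect (off-ray
voxel centres sit slightly closer to a curved wall than their ray
projection) contributes a few percent on the smaller-radius branches.

## Cohort statistics

Ordinary least squares (scipy) with R² as the squared Pearson
correlation, reported at 2 d.p. when compared against printed values
and at full precision in JSON.  The shipped cohort reproduces
R² = 0.84 (slope −11.6 mmHg/Pa) for whole-geometry TAWSS vs mPAP.
Recomputing the MPA-only regression from the printed two-decimal
TAWSS values gives R² = 0.7645 — rounding to 0.76, one hundredth
below the originally reported 0.77, which evidently used unrounded
inputs; similarly the stroke-volume regression recomputes to 0.71
rather than the reported 0.69.  Both recomputed values are asserted
as such in the unit tests.  The diameter regression is implemented
but can only run on synthetic cohorts (no diameters are printed).
Parameter-recovery uses a synthetic cohort (n = 200 by default) with
a negative linear TAWSS→mPAP rule (−12 mmHg/Pa, intercept 60 mmHg,
5 mmHg Gaussian noise — the printed cohort's scale) and checks the
fitted slope against truth in standard-error units.  With n = 7 no
inferential machinery is attached, deliberately.

## Problem sizes

Default test and acceptance runs use: phantom volumes of roughly
40 × 40 × 20 voxels × 25 frames (≈1 mm sweeps up to 110 × 100 × 50);
solver grids of 32–64 radial × 32 axial cells at dt = 2.5–5 ms for
3–12 cycles.  These sizes keep every oracle comparison well inside
its tolerance while the full suite runs in about a minute.

## Known limitations

* Straight-tube solver: no secondary flows, curvature or bifurcation
  hemodynamics; branch effects live only in the phantom/voxel path.
* Rigid walls everywhere (as in the reference workflow); no
  fluid–structure interaction.
* The voxel-WSS estimator requires the phantom's analytic wall
  position; a mask-interpolated wall for arbitrary segmentations is
  future work.
* Explicit convection caps dt by CFL; the stated 5 ms step applies to
  low-velocity regimes at default resolution.
* The 0D/1D/2D chain is not a substitute for patient-specific 3D CFD;
  it verifies methodology, not patient values.
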