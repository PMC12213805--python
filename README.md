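# pulmoflow

Non-invasive pulmonary-artery hemodynamics for pulmonary arterial
hypertension (PAH) research: a fully testable, desk-scale
implementation of a patient-specific 4D-flow-MRI-driven workflow that
quantifies inlet flow, tunes Windkessel outlet boundary conditions
from echocardiographic pressure estimates, simulates pulsatile
non-Newtonian flow, computes time-averaged wall shear stress (TAWSS),
and correlates it with catheter-measured mean pulmonary arterial
pressure (mPAP) across a cohort.

## The problem

PAH (mPAP > 20 mmHg) is diagnosed by invasive right heart
catheterization, often years after first symptoms.  Image-based
hemodynamic modelling offers a non-invasive alternative: velocity
fields from 4D-flow MRI drive patient-specific flow models whose
derived quantities — above all TAWSS — track disease severity.  Across
a seven-patient cohort, whole-geometry TAWSS regresses against
catheter mPAP with R² = 0.84 and a negative slope: **low wall shear
accompanies high pressure**.

The package implements every stage with exact synthetic ground truth:

| stage | module | core quantity |
| --- | --- | --- |
| synthetic 4D-flow phantom | `pulmoflow.phantom` | Womersley velocity field u(r,t) in a bifurcating vessel |
| vessel reconstruction | `pulmoflow.segmentation` | Boolean union of phase/magnitude masks, MPA/LPA/RPA labels |
| flow quantification | `pulmoflow.flowquant` | Q(t), stroke volume SV = ∫Q dt, LPA/RPA flow split |
| pressure estimation | `pulmoflow.pressure` | peak PAP = 4v² + RAP; mean PAP = 0.61·peak + 2 |
| outlet boundary tuning | `pulmoflow.windkessel` | 3-element Windkessel: R_total = P̄/Q̄, τ = R₂C |
| blood rheology | `pulmoflow.rheology` | Quemada law μ = μ_p(1 − k(γ̇)φ/2)⁻² |
| pulsatile flow | `pulmoflow.solver` | axisymmetric Navier–Stokes, projection scheme, 150·α laminar check |
| wall shear stress | `pulmoflow.wss` | TAWSS = (1/T)∫\|τ_w\| dt; voxel-grade 4D-flow-style estimator |
| cohort statistics | `pulmoflow.cohortstats` | OLS of TAWSS vs mPAP, validation metrics |

The printed seven-patient cohort (periods, stroke volumes, flow
splits, Windkessel parameters, validation velocities, regional TAWSS)
ships as a CSV fixture, so every cohort-level analysis runs without
any data download.

## Worked example

Echo-based pressure screening:

```text
$ pulmoflow estimate-pressure --tricuspid-velocity 3.0 --rap 8
peak PAP = 44.00 mmHg, mean PAP = 28.84 mmHg, PH = True
```

A tricuspid jet of 3 m/s over an estimated right atrial pressure of
8 mmHg gives a peak PAP of 4·3² + 8 = 44 mmHg by the simplified
Bernoulli equation; the Chemla relation maps this to a mean PAP of
28.84 mmHg, above the 20 mmHg threshold, so the patient classifies as
pulmonary-hypertensive.

Cohort regressions on the printed tables:

```text
$ pulmoflow correlate
TAWSS (MPA+LPA+RPA) [Pa]: R^2 = 0.8432 (slope -11.64)
TAWSS (MPA) [Pa]: R^2 = 0.7645 (slope -16.27)
Stroke volume [mL]: R^2 = 0.7138 (slope -0.21)
```

Each pascal of whole-geometry TAWSS corresponds to roughly 11.6 mmHg
*lower* mean PAP across the cohort; restricting TAWSS to the main
pulmonary artery alone, or replacing it with stroke volume, weakens
the correlation.

End-to-end phantom run (generate study → segment → quantify → tune →
simulate → TAWSS):

```text
$ pulmoflow run-all --mode phantom --seed 0
{
 "stroke_volume_ml": 80.28,
 "rpa_fraction": 0.5499,
 "mean_pap_echo_mmhg": 31.87,
 "zero_d": {"RPA": {"mean_pressure_mmhg": 31.86}, ...},
 "tawss_voxel_pa": {"MPA": 0.146, ...},
 "tawss_fine_mpa_pa": 0.832,
 "resolution_bias_ratio": 0.175,
 "segmentation_dice": 0.96,
 ...
}
```

The phantom was generated with SV = 80 mL and an RPA fraction of 0.55;
the pipeline recovers 80.28 mL and 0.5499.  The tuned Windkessel
reproduces the echo-derived 31.87 mmHg target to 0.01 mmHg.  The
voxel-grade TAWSS estimate (0.146 Pa at 2.5 mm voxels) sits far below
the analytic fine-grid value (0.832 Pa) — the resolution bias that
makes direct 4D-flow WSS magnitudes unreliable and motivates the
model-based route.

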