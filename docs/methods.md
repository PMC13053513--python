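# Methods

This note documents the models behind `cvikit`, the choices made where the
design was genuinely open, and what the synthetic studies do and do not
demonstrate.

## Lesion geometry and plaque composition

A lesion is an axisymmetric lumen profile a(z) on a uniform centerline grid
(default Δz = 0.1 mm for single-lesion analysis, 0.25 mm inside the cohort
generator, where grid-convergence tests show <1% feature drift between Δz
and Δz/2). The stenosis is a symmetric cosine bump (Gaussian optional)
reaching a_ref·(1 − severity) at the lesion midpoint, with straight
inlet/outlet segments; for this family the diameter stenosis DS equals the
severity parameter exactly. The outer wall b(z) follows the lumen at a
constant wall thickness, thickened by the displaced plaque and by outward
bulging proportional to (remodeling index − 1). Asymmetric lesions and
image-derived geometry are out of scope.

Plaque stiffness is a surrogate of CT attenuation: a monotone
piecewise-linear map from Hounsfield units to elastic modulus with default
anchors (−30 HU → 5 kPa, 30 HU → 25 kPa, 150 HU → 1000 kPa,
400 HU → 10 000 kPa), fully configurable. No published calibration exists
for this map; it is an explicit configuration artifact, and the package's
conclusions are about orderings (soft vs stiff), not absolute moduli. Two
adverse-plaque flags are derived from the profiles (low-attenuation plaque:
min HU ≤ 30; positive remodeling: index ≥ 1.1); spotty calcification and
the napkin-ring sign are inherently 3-D patterns that a 1-D profile cannot
encode, so the generator carries them as labels with class-conditional
prevalences.

## Reduced-order hemodynamics

Steady flow at one hyperemic operating point. Pressure losses combine
(i) Poiseuille resistance integrated along the profile,
dP_v(z) = ∫ 8μQ/(πa⁴) dζ, and (ii) an expansion (Borda–Carnot/Young–Tsai)
loss dP_e = Kt·(ρ/2)·Q²·(1/A_s − 1/A_0)² with Kt = 1.52, deposited linearly
from the throat to the lesion exit so p(z) stays continuous (the index
takes a pointwise maximum and needs a well-defined local pressure). Wall
shear stress is the local Poiseuille value 4μQ/(πa³).

`FlowConditions.Q` (default 2.693 mL/s, the flow giving 15 dyn/cm² WSS in a
straight 2 mm-radius vessel) is interpreted as the hyperemic flow of the
*unobstructed* vessel: it fixes a distal microvascular resistance
R_m = Pa/Q − R_ref, and the operating flow solves
Pa = (R_m + R_v)·Q + c₂Q². This closure keeps the distal pressure — hence
FFR — positive for arbitrarily tight stenoses, which a fixed-flow model
cannot do. `autoregulate=False` imposes Q directly (used by the analytic
Poiseuille and WSS-scaling tests). Pulsatile flow, turbulence and
autoregulation dynamics are not modelled.

FFR is the most-distal pressure over aortic pressure; ΔFFR its drop across
the lesion endpoints. The WSS lesion summary is the area-weighted mean over
the lesion surface in dyn/cm². Axial plaque stress is the axial component
of the wall traction, t_ax = p·n_z + τ·ℓ_z with n_z = −a′/√(1+a′²);
its summary is the area-weighted mean of |t_ax| (upslope/downslope
decompositions are not reproduced), reported in dyn/cm² — the literature
does not state a unit for this quantity and the choice is recorded here.

## Cap mechanics

Each grid station is an independent plane-strain two-layer cylinder: the
cap [a, a+h] (Ec = 200 kPa, νc = 0.25, h = 20 µm — literature values for a
thin fibrous cap) inside the plaque/wall annulus [a+h, b] (modulus from the
HU map, νp = 0.45, near-incompressible soft tissue). Displacements take the
Lamé form u = Ar + B/r per layer; the four coefficients follow from the
inner pressure, displacement and radial-traction continuity at the
interface, and the outer condition — traction-free at b by default, with a
clamped option mimicking embedding in stiff surrounding tissue (clamping
never increases the cap stress; results for both appear in the test suite).
Axial coupling, residual stress, anisotropy and large deformation are
omitted.

The cap stress σc is the **thickness-averaged** hoop stress in the cap — a
membrane stress (the inner-surface peak is available as a secondary
output). Two structural facts anchor the kernel:

- For an unsupported layer, radial force balance makes the
  thickness-averaged hoop stress exactly p·a/h, so σc/σ* → 1 in the
  soft-plaque limit for *any* h/a — the Laplace limit is recovered
  identically, not asymptotically.
- Behind a very stiff annulus the plane-strain solution puts the cap in net
  hoop *compression* (Poisson coupling to radial compression). A compressed
  cap has no tensile rupture drive, so the utilization ratio σc/σ* floors
  at zero while σc itself keeps its sign.

The closed form is verified against an independent ~10⁴-node radial
finite-difference discretization of the elasticity ODE to better than 10⁻⁴
relative error over randomized parameter sweeps (free and clamped).

## The index

CVI = max over the cap extent (the whole lesion by default) of
(σc/σ*)·(τ/p). Ties resolve to the smallest z. Two unit conventions are
first-class and recorded in every result: `"consistent"` (τ and p in the
same unit; strictly dimensionless, invariant under common rescaling of all
loads) and the default `"paper"` (τ in dyn/cm² over p in mmHg, =
consistent × 1333.22), which places typical lesions in the 0.1–1 range
customary for this index. The shear factor uses the local instantaneous
magnitude.

## Synthetic cohorts

The generator emulates a retrospective lesion-level case cohort:

- A latent risk stratum (prevalence = culprit fraction, default 63/209)
  selects class-conditional truncated-normal marginals for severity (= DS;
  0.432 ± 0.151 vs 0.552 ± 0.147), length (15.31 ± 8.06 vs 17.86 ± 7.73 mm),
  minimum attenuation (normals placed so that P(HU ≤ 30) ≈ 7% vs 30%) and
  remodeling index (P(RI ≥ 1.1) ≈ 10% vs 34%), plus spotty-calcification
  (19%/41%) and napkin-ring (8%/33%) prevalences. Reference radius and
  nominal flow are class-independent. Truncation to physical ranges shifts
  means slightly (≈ +0.3 mm for length, < 0.005 for DS); the
  law-of-large-numbers tests account for this.
- Every lesion is pushed through the full geometry → flow → cap-stress →
  index pipeline, so all 11 features are physically coherent (severity
  raises ΔFFR and WSS; soft plaque raises the index).
- Culprit labels are drawn from a logistic model on the **latent
  mechanistic risk** — the standardized log of the computed index (the
  natural scale for a positive, right-skewed biomarker) — with slope
  `effect_size`. The intercept is solved numerically so the expected
  prevalence equals the configured culprit fraction (chosen over rejection
  resampling, which would distort the feature marginals). The default
  slope 1.0 puts the index's own population discrimination near AUC 0.75,
  the regime reported for lesion-level culprit prediction;
  `effect_size = 0` severs labels from all features (the null used for
  calibration tests). `label_mode="stratum"` instead uses the stratum as
  the label, reproducing the class-conditional marginals exactly.
- Culprit lesions receive event times uniform on the 1–24-month
  scan-to-event window; nonculprits are administratively censored at 24
  months (a Weibull option exists for power studies). Lesions are grouped
  into synthetic patients of 2–4, but the evaluation is per-lesion.

All randomness flows from one seed through named substreams; identical
configs give byte-identical CSVs. What passing tests show: the evaluation
machinery is calibrated and recovers a mechanistic signal when one exists
by construction. What they do not show: performance on real CCTA cohorts —
the generator matches published *marginals*, not the unpublished joint
feature structure, imaging noise, or inter-patient correlation.

## Evaluation statistics

- **Logistic models.** Maximum-likelihood with intercept on z-scored
  features, stabilized by a tiny ridge (10⁻⁸, all coefficients of the
  standardized model) that keeps separation finite without materially
  changing rankings. Fitting is Newton with a trust region; z-scoring uses
  cohort-level moments (ML scores are affine-equivariant, so this fixes
  only the scale on which the ridge acts). Cross-checked against an
  independent scipy trust-region optimizer of the penalized likelihood.
- **LPOCV AUC.** Every culprit×nonculprit pair is held out, the model refit
  on the remaining n−2 lesions (batched, warm-started Newton — thousands of
  refits per second) and the pair scored 1 / 0.5 / 0. Pairs are pooled
  across patients; pairs whose training set degenerates to one class are
  skipped and counted. Verified to agree *exactly* with an explicit
  per-pair brute-force loop on toy cohorts.
- **Shapley ΔAUC.** Coalition value v(S) = AUC of the model on feature
  subset S, v(∅) = 0.5; exact enumeration of all 2^k subsets for k ≤ 12,
  permutation Monte Carlo (explicit seed) beyond. The value function
  defaults to apparent AUC — refitting 2^11 subsets under LPOCV is
  combinatorially prohibitive — with LPOCV available. Efficiency
  (Σφ = v(full) − 0.5) and symmetry hold to 10⁻¹⁰ in exact mode.
- **Bootstrap.** Lesions resampled with replacement, the same resample
  indexing every model (paired replicates); single-class resamples redrawn
  with a capped retry count; percentile 95% CIs.
- **Youden cutoff.** All midpoints between sorted unique scores; ties to
  the smallest threshold; constant scores return J = 0 flagged undefined.
- **Survival.** Kaplan–Meier per group (lifelines) and the two-group
  log-rank test, verified against a hand risk-set enumeration.
- **Group comparisons.** Welch's t (unequal variances) for continuous
  features; chi-squared with Yates continuity correction on 2×2 tables for
  flags — the corrected test reproduces the worked example's p = 0.002
  (uncorrected gives 0.001). No multiple-testing adjustment is applied.

## Fixed study sizes and seeds

Test and acceptance runs use: 200 effect-free cohorts of n = 200 for null
calibration (mean single-feature LPOCV AUC within [0.48, 0.52]; Welch
type-I error within [0.03, 0.07] over 2000 simulations), and a single
n = 500 recovery cohort at the canonical seed 20260001 for the qualitative
ranking study. Across eight arbitrary seeds the index ranks first in
single-feature AUC in 8/8 cohorts and first in Shapley attribution in 7/8
(once edged out by the low-attenuation flag) — the ranking claim is a
fixed-seed study condition, not a universal guarantee at n = 500.

## Known limitations

Axisymmetric single-vessel lesions only; no bifurcations, tandem-lesion
interaction, or patient-level risk; linear elasticity with assumed cap
properties (cap thickness and modulus are not measurable from CT); the
HU→modulus map is uncalibrated; the `"paper"` unit convention for the index
is a reporting choice, not a physical statement; and synthetic-cohort
results quantify the pipeline, not clinical performance.
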