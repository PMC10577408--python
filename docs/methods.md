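# Methods

This note documents the models behind `coroflow`, the parameters that
matter, how the synthetic data are calibrated, and the numerical choices —
in enough detail that every result the tests and `scripts/acceptance.py`
compute can be traced to a stated assumption.

## Vessel geometry

A vessel tree is a set of segments, each a polyline centerline with a
linearly tapering reference radius and optional focal stenoses. A stenosis
is parameterized by its throat position, lesion length `L`, and diameter
reduction `DS ∈ [0, 1)`; the lumen radius is

```
r(s) = taper(s) · (1 − DS · w(s))
```

with a shape window `w` supported exactly on `[center − L/2, center + L/2]`
and peaking at 1 at the throat. The default window is the C¹-smooth raised
cosine; a truncated Gaussian (σ = L/6) is available. Reference diameter at
any lesion must be ≥ 2 mm, mirroring the usual inclusion criterion for
FFR interrogation.

Rasterization marks a voxel as lumen iff its center lies within `r(s*)` of
the centerline, `s*` being the nearest centerline sample. The domain is
padded laterally (default 1 mm) but cut flush at the inlet/outlet end
planes, so the mask touches the box boundary only at its open ends — this
is what lets both the centerline extractor and the flow solver identify
inlets and outlets from the mask alone. Default spacing is 0.35 mm,
the order of CCTA in-plane resolution; rasterizing requires
`spacing ≤ r_min/2`. Masks round-trip through NIfTI-1 with
`affine = diag(spacing)` plus the origin translation (world mm, 0-based
voxel indices, voxel-center sampling).

## Centerline and stenosis quantification

The centerline is the ridge of the Euclidean distance transform (EDT).
Each foreground patch on the domain boundary is an open end; the end with
the largest inscribed radius is taken as proximal. Minimum-cost geometric
paths (cost `(edt_max/edt)²`, 26-connected) from the proximal end to every
distal end hug the EDT ridge; shared path prefixes become parent branches,
so a bifurcated mask yields three branches meeting at a degree-3 junction.
Per-point radius is the EDT value (inscribed sphere); points and radii get
a 3-point moving-average smoothing. We use EDT-ridge paths rather than
topological thinning because the thinning implementation available to us
erases tubes whose cross-section is symmetric with an even voxel width;
the ridge-path formulation has no such failure mode and directly yields
ordered, rooted branches.

DS% follows QCA practice: within a user-supplied lesion window,
`d_min` is the minimum diameter, `d_ref` interpolates the shoulder
diameters linearly to the location of `d_min`, and
`DS% = 100·(1 − d_min/d_ref)`; `DS ≥ 50%` flags an anatomically
significant stenosis. The window is a required input because the package
has no notion of where a "target lesion" is on real data.

Expected accuracy (tested): mean radius within ±0.19 mm of truth and axis
RMS under one voxel on straight tubes at 0.375 mm spacing; recovered DS
within ±5 points of the specified value at spacing ≤ r_throat/3, and
strictly increasing in the true DS across 30/50/70/90%.

## Boundary conditions and fluid model

Blood is Newtonian with μ = 3.5 mPa·s, ρ = 1056 kg/m³; mean aortic
pressure Pa = 90 mmHg; hyperemic mean inlet velocity 0.35 m/s. None of
these is identifiable from the validation data the package emulates, so
all are config-overridable; they are standard textbook values for
adenosine hyperemia. Total inlet flow is `v_hyp · A_inlet`; outlets are
flow-prescribed with a Murray cube-law split (`Q_i ∝ r_i³` on the
reference outlet radius). Flow-prescribed outlets with one pressure datum
make the steady problem well posed without inventing a microvascular
resistance model. The venous reference is 0 mmHg. Flow is steady
throughout; no pulsatility, no fluid–structure interaction, no turbulence
model.

## 1D reduced-order solver

Along each root-to-leaf path the pressure drop is the element-wise
Poiseuille integral `∫ 8μQ/(πr(s)⁴) ds` over the sampled radius profile,
plus one separation (post-stenotic expansion) loss per lesion applied at
the throat:

```
ΔP_sep = K_t · ρ/2 · (A0/As − 1)² · (Q/A0)²,   K_t = 1.52
```

with `A0` the reference area and `As` the throat area. This is the
classic two-term stenosis loss model; the viscous term uses the actual
lesion shape (so a cosine lesion loses less than a uniform throat of the
same length would). Pressure is continuous at junctions; children tap the
parent at their attachment point. Negative distal pressures are flagged
as warnings, not errors. The solver is closed-form (no iteration) and
serves as the oracle for the 3D scheme.

## 3D immersed-boundary projection solver

MAC staggered grid: pressure at cell centers, velocities on faces; the
lumen mask supplies the fluid cells. Wall condition is stair-step direct
forcing — faces touching solid are pinned to zero — with mirror ghost
values in the viscous stencil so the no-slip plane sits on the stair
surface itself (zero ghosts would place it half a cell outside and bias
the Poiseuille drop by ≈ −20% at 12 voxels/diameter; with mirroring the
bias is ≈ +3%). Inlet and outlet velocities are prescribed parabolic
profiles scaled to the requested flows; the profiles make entrance
development nearly free for tube geometries.

Each pseudo-time step:

1. explicit momentum predictor — first-order upwind advection, central
   diffusion, `dt = 0.5·min(h²/6ν, h/u_max)`;
2. pressure Poisson solve `∇²φ = (ρ/dt)∇·u*` by BiCGStab, warm-started
   from the previous step; the pure-Neumann operator is grounded by a
   weak diagonal anchor at one outlet cell (the mass-balanced right-hand
   side keeps the anchor leak negligible). The preconditioner is a
   complete sparse LU of the fixed operator, built once — at desk scale
   (≤ ~10⁵ fluid cells) the factorization costs a fraction of a second
   and makes each BiCGStab solve essentially one iteration;
3. velocity correction `u ← u* − (dt/ρ)∇φ`.

Convergence: relative L2 norm of the velocity update ≤ 1e−5 (default).
A final projection solved to rtol 1e−13 leaves the divergence metric —
worst cell net flux normalized by the inlet flux — at round-off
(~1e−18 in the tests; the acceptance bound is 1e−8). FFR extraction
samples the pressure field on the centerline, averaging over the
cross-section disc of radius r(s)/2, anchors the inlet-plane mean to Pa,
and reads the per-lesion value at the distal shoulder plus a 20 mm offset
(capped at the vessel end). The measurement location is exposed because
published CT-FFR reports do not define theirs.

Scope: the solver handles one inlet face and one outlet face on opposite
ends of a grid axis — straight and axisymmetric stenosed tubes, which is
where a closed-form or 1D oracle exists. Branched trees use the 1D
solver. Verified behavior (all in the test suite): Poiseuille pressure
drop within 15% of the closed form at ≥ 12 voxels/diameter and Re ≈ 50;
error magnitude monotonically decreasing over three grid levels
(6/8/12 voxels per diameter); per-plane mass flux within 2% everywhere;
1D↔3D lesion-FFR agreement within 0.05 for DS ≤ 0.7; FFR strictly
decreasing in DS and in flow in both solvers. The severity sweep runs at
300 mm³/s — below the hyperemic default — which keeps the throat jet of
the DS = 0.7 case comfortably laminar on a grid the suite can afford; the
monotonicity and agreement properties under test do not depend on the
absolute flow.

## Virtual cohort generator

The generator reproduces the statistical structure of a paired
FFR / CT-FFR validation study with 303 patients and 324 vessels, using
only published marginal summaries as calibration anchors. It is the
package's study-conditions definition, not a tuning surface; the
constants below were fit once, numerically, and frozen.

* **Invasive FFR**: two-component normal mixture, clipped to [0.2, 1]:
  `0.5469·N(0.8729, 0.05) + 0.4531·N(0.6884, 0.09)`. Component spreads
  are design values; weight and means were fit so the clipped mixture
  reproduces the published median 0.82 and IQR (0.70, 0.88). The implied
  ischemia prevalence (FFR ≤ 0.80) is ~44–45%, matching the published
  45.1% without being a parameter.
* **CT-FFR**: `clip(FFR + b + ε, 0.2, 1)` with `ε ~ N(0, 0.0709)`; the
  noise SD derives from the published 95% limits of agreement
  (−0.146, +0.132) as `(0.132 + 0.146)/(2·1.96)`. The raw shift `b` is
  solved per cohort (closed-form censored-normal mean, Brent root) so the
  *post-clipping* mean difference equals the target bias −0.007; clipping
  at the physiological ceiling would otherwise drag the realized bias to
  −0.008.
* **CCTA stenosis grade**: cumulative-logit link
  `P(grade ≥ g | FFR) = expit(k(θ_g − FFR))` with k = 11.5056,
  θ₅₀ = 0.83164, θ₇₀ = 0.67665 — fit to the CCTA operating point
  (Se 82% / Sp 62% against FFR ≤ 0.80) and a 27.2% share of 70–90%
  grades. The published grade marginals and the published Se/Sp are
  mutually inconsistent (they imply different DS ≥ 50% rates), so the
  link honors the operating point, which is what the comparative ROC
  analyses rest on; the 30–49 / 50–69 split is consequently not matched.
* **Everything else**: lesion locations multinomial 73.6/9.2/17.2%
  (LAD/LCX/RCA); plaque labels independent Bernoulli 48.8/37.3/40.9%
  (fibrous/calcified/lipid — overlapping, as published); lesion length
  lognormal matching median 10.85 mm and IQR 6.92–15.15; Agatston score
  lognormal with median 188.5 and P(≥ 400) = 0.327 (a two-parameter
  family cannot also match the printed IQR; the tail probability drives
  the ≥ 400 subgrouping, so it wins). Per-patient FFR/CT-FFR is the
  minimum over the patient's vessels (the published per-patient rule is
  unstated); the 21 extra vessels go to distinct, uniformly chosen
  patients.

**What is emergent rather than calibrated.** The Spearman rank
correlation between CT-FFR and FFR is not an input; under the pinned
calibration it concentrates near 0.84 (published: 0.88). Likewise the
Youden-optimal threshold: its population value under this generator is
0.78, and the median over 50 cohorts of n = 324, snapped to the nearest
0.05, is 0.80. Plaque labels are independent of FFR (the joint
distribution is unpublished), so discordance-regression reproductions
are structural, not numeric.

**What the generator does not emulate**: image appearance, per-lesion
geometry–FFR coupling (CT-FFR noise is exchangeable across vessels),
within-patient correlation beyond the shared Agatston score, and any
case-mix drift. Passing tests therefore demonstrate that the statistics
machinery recovers known generative truth at study scale — not that the
physiologic model generalizes to real CCTA data.

## Validation statistics

Truth is invasive FFR ≤ 0.80 throughout (the inclusive cut point; values
in 0.75–0.80 are additionally flagged as the gray zone, and reporting
strata are [0, 0.6], (0.6, 0.7), [0.7, 0.8), [0.8, 0.9), [0.9, ∞), with
≤ 0.60 inclusive). Choices where the emulated analyses are silent:

* Confidence intervals: exact Clopper–Pearson (conservative,
  reproducible); zero-denominator metrics are reported as unavailable,
  never as zero.
* AUC is the Mann–Whitney statistic with ties counted ½; the threshold
  sweep runs over unique scores with the FFR orientation
  (lower = positive). DeLong structural components give the AUC variance
  and the paired-comparison z test.
* Youden threshold: argmax of Se + Sp − 1 over the sweep; exact ties
  break toward the threshold nearest 0.80 and are flagged, as is perfect
  separation (where any threshold in the gap is optimal).
* McNemar: the continuity-corrected statistic `(|b−c|−1)²/(b+c)` is
  always reported; the p-value is exact binomial when b + c < 25.
* Bland–Altman: differences CT-FFR − FFR; LoA = bias ± 1.96·SD (n−1).
* Discordance regression: one-predictor logistic fits (IRLS via
  statsmodels); complete separation and degenerate strata are flagged
  fits, never silent divergence. No multiple-testing correction is
  applied (two-tailed α = 0.05), matching the emulated analysis plan.

## Pipeline and provenance

`run_pipeline` executes geometry → centerline → FFR (1D or 3D) → cohort →
evaluation and writes a versioned JSON report embedding the full config
and all seeds; a rerun from the same config is byte-identical. The global
seed fans out to per-stage child seeds via a CRC-keyed SeedSequence, all
below 2³¹.

## Problem sizes

The test suite solves 3D flow on grids between roughly 60×16×16 and
150×26×26 (up to ~2×10⁴ fluid cells) and simulates cohorts of n = 324
(50 replicates) plus one n = 10⁵ draw for marginal checks; the whole
suite runs in a few minutes on one CPU. The acceptance script uses 50
cohorts for the threshold estimate and 200 for the agreement statistics.

## Known limitations

* The stair-step wall is first-order: expect a few percent bias in
  pressure drops at 12 voxels/diameter, worse below 8.
* The 3D solver is restricted to single-inlet/single-outlet axis-aligned
  topologies; branched hemodynamics are 1D only.
* The separation-loss constant K_t = 1.52 is an empirical lumped value;
  per-lesion CT-FFR values from any specific clinical implementation are
  not reproducible here (their geometry, hyperemia model and constants
  are unpublished), and no attempt is made to match them.
* The cohort generator's CT-FFR error model is exchangeable noise; it
  cannot reproduce lesion-level error structure (e.g. calcium-dependent
  bias) except as independently drawn labels.
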