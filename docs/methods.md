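# Methods

This note records the modelling choices behind `plaquefatigue`: the
mechanical model and its numerical treatment, the statistical machinery,
what the synthetic cohort does and does not emulate, and the defaults that
matter.  It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Thin-slice mechanics

**Kinematics.**  A single cross-section is treated as a generalized
plane-strain body: the in-plane deformation gradient is free, the axial
stretch is prescribed at λ_z = 1/(1 − 0.05) to represent 5% axial
shrinkage of a stiff atherosclerotic vessel.  A 0.5 mm extruded slice with
uniform axial stretch and plane-parallel faces has exactly this in-plane
response; the slice thickness scales energies only, never stresses, so no
3D extrusion is solved.

**Constitutive model.**  Modified Mooney–Rivlin energy in the invariants of
C = XᵀX, with an exponential stiffening term; the wall ("other tissue")
additionally carries an exponential fiber term in I4 along the local
circumferential direction.  Parameters (kPa where dimensional):

| tissue    | c1     | c2    | D1    | D2  | K1   | K2   |
|-----------|--------|-------|-------|-----|------|------|
| lipid     | 0.5    | 0     | 0.5   | 1.5 | —    | —    |
| calcium   | 92     | 0     | 36    | 2   | —    | —    |
| wall      | −278.7 | 24.35 | 133.7 | 2   | 7.19 | 23.5 |

Near-incompressibility is not part of the printed law; it is imposed here
by a volumetric penalty κ(J − 1)² with κ = 10⁴ kPa (two to three orders
above the wall shear scale; doubling κ changes luminal stresses on the
cylinder benchmark well below the oracle tolerances).  The isochoric part
is evaluated on the modified invariants Ī1 = J^(−2/3) I1, Ī2 = J^(−4/3) I2
— the standard decoupled realization.  On volume-preserving states this
coincides exactly with the plain form, and it is what makes the reference
configuration stress-free; with the plain invariants plus a penalty the
reference would carry a spurious hydrostatic stress.  The anisotropic
bracket is read as (K1/K2)[exp(K2(I4−1)²) − 1], which vanishes at the
reference; the alternative reading differs only by an additive constant
and yields identical stresses.

The wall's negative c1 makes the ground-state energy weakly non-convex in
some directions (the I2 and exponential terms keep the ground-state shear
modulus positive, ≈ 26 kPa).  Consequences for the solver are handled
below; the analytic stresses themselves are validated against
finite-difference energy gradients to 1e-5 relative over hundreds of
random states per tissue.

**Strain measure.**  "Maximum principal strain" is the maximum principal
Green–Lagrange strain E = (C − I)/2, the standard choice in image-based
plaque modelling.  Principal values are taken over the full block-diagonal
3D tensors (in-plane block plus axial component).

**Reference configuration.**  VH-IVUS frames are R-wave gated, i.e. imaged
at minimum arterial pressure — never at zero pressure.  The stress-free
reference is obtained by (a) the fixed axial stretch above and (b) a
uniform in-plane circumferential shrinkage s about the lumen centroid,
found by the fixed point s ← s·√(A_target/A_computed), where A_computed is
the lumen area after inflating the s-scaled geometry to the minimum
pressure.  The map s ↦ A(s) is close to quadratic, so the iteration
converges in a handful of steps; 20 iterations is a hard cap carrying the
trace on failure.  The scale is capped at 1 (shrinkage only): a
configuration that would need expansion — e.g. a near-rigid wall whose
axial pre-stretch contracts the plane more than inflation recovers — is an
error rather than a silent extrapolation.  Default tolerance: 1% relative
lumen-area mismatch, below IVUS segmentation precision.  The shrink
parameterization (one uniform scale) is a deliberate one-parameter design
with a monotone response; nothing finer is identifiable from a single area
target.

**Discretization.**  Structured mesh of 6-node (quadratic) triangles in
polar parameter space about the lumen centroid; quadratic elements avoid
volumetric locking under the penalty.  Contours are star-shaped by
construction of the generator, so the polar structured mesh is well-posed,
and midside boundary nodes are sampled on the true contour.  Element
tissue labels come from centroid-in-polygon tests against the component
polygons.  Default target edge length 0.08 mm (≈ 2–4k elements);
benchmarks in the test suite use 0.1–0.3 mm, where the cylinder oracle
(luminal stress within 10% of Laplace P·r/t at small load) and the mesh
convergence check (< 5% change under edge halving) already hold.

**Solver.**  Total-Lagrangian displacement formulation, 3-point quadrature,
incremental loading (default 10 increments) with Newton iterations.  The
luminal pressure is a follower load; in 2D a uniform pressure on a closed
cavity boundary is conservative with potential −p·λ_z·A_cavity, so the
consistent load vector is the (exact, bilinear) gradient of the cavity
area over the deformed quadratic boundary edges and the load stiffness is
its constant Hessian.  The element tangent is a finite difference of the
analytic internal force (perturbation ~1e-6 of the element scale), which
preserves Newton's practical convergence while keeping the stress code the
single source of truth.  Because of the weak non-convexity noted above the
assembled tangent can be indefinite near the solution path; the solver
therefore uses adaptive Levenberg damping with a backtracking line search
on the total potential, reverting to the undamped (quadratically
convergent) iteration whenever a full step is accepted.  Convergence is
declared at a relative residual of 1e-8 against the larger of the external
load and the pre-assembly element force scale; a stagnation floor accepts
roundoff-limited plateaus (relevant only for artificially stiffened
materials, e.g. the ×10⁶ rigid-limit check).  Rigid-body modes of the
free-floating ring are removed by three Lagrange constraints on net
translation and rotation.  Nodal stress/strain fields are recovered by
area-weighted averaging of element quadrature values.  The
systolic solve warm-starts from the diastolic state.

## Factors, outcome, and statistics

Nineteen baseline factors per slice: 12 biomechanical (max/average luminal
principal stress and strain at each of the two pressures, plus the four
amplitudes) and 7 morphological (plaque burden at minimum pressure,
lumen/wall areas at both pressures, and the two area amplitudes).
Amplitudes are definitions — systolic minus diastolic — and are tested as
exact identities.  The luminal "average" is the unweighted mean over lumen
boundary nodes (an arc-length weighting changes axisymmetric benchmarks by
less than their discretization tolerance).  DLA uses the imaged
(minimum-pressure-matched) lumen areas of the two timepoints, since lumen
area is an image-derived quantity; DLA = 0 counts as non-narrowing.

The per-factor screen fits y_ij = β0 + β1 x_ij + b_j + ε_ij by maximum
likelihood (not REML, so the Wald test on β1 is the standard one; the
choice of Wald over likelihood-ratio is a documented decision) and reports
r = β̂1·√(var x/var y) with plain sample variances computed ignoring
grouping.  That ratio is not a bounded correlation: when a covariate is
confounded with the grouping, the within-patient slope times the total
variance ratio can exceed 1, in which case r is clipped to ±1 with a
warning.  With fewer than two groups the model degenerates to OLS and r
is exactly the Pearson correlation.  No multiplicity correction is applied
across the 19 screens (a marginal screen; the family-wise error is
correspondingly larger) — the CLI output restates this caveat.

## Random forest

scikit-learn's `RandomForestClassifier` supplies the forest; everything
decision-like sits in this package.  OOB error (each sample scored only by
trees whose bootstrap excluded it) is the sole validation surface; a
holdout is deliberately absent.  Mtry is grid-searched (default 1..19) at
a fixed 500-tree count, ties to the smaller value; Ntree is the smallest
entry of (250, 500, 1000, 1500, 2000, 3000) from which every subsequent
OOB change stays below 0.5 percentage points, falling back to the last
entry with a warning flag.  Importance is mean-decrease-Gini in the
established weighted form (impurity decrease at a factor's split nodes,
weighted by node sample fraction; scikit-learn normalizes across factors,
which is immaterial for ranking).  Backward elimination drops the lowest
20% of factors by importance per round and keeps the smallest set within
one binomial standard error of the best OOB error (the 1-SE rule, the
varSelRF defaults).  Classification metrics treat the positive class as an
explicit parameter; for the published-matrix reproduction the
non-narrowing (label 0) ground-truth row is positive — the only convention
under which the printed percentage set (83.61 / 86.25 / 80.69 / 83.13 /
84.17) is mutually consistent.  Undefined ratios (zero denominators) are
reported as NaN, never as 0.

## Synthetic cohort

The generator emulates the *structure* of a two-timepoint IVUS study, not
its images: 7 patients, 305 paired slices (per-patient counts drawn in
40–50 and adjusted deterministically to the exact total), lumen radius
~N(1.5, 0.3) mm, wall thickness ~N(0.75, 0.15) mm, eccentric lumens
(r(θ) = base(1 + e·cos θ) plus low-order Fourier perturbation, 64
vertices), angularly varying wall thickness, lipid modelled as a sector
annulus (40–120° span) and calcium as a thin outer arc, and per-patient
pressures ~80/120 mmHg (10.67/16.0 kPa) — the pulsating-pressure defaults,
since no per-patient values are published.  Follow-up changes only the
lumen (uniform rescale to the new area; inclusions are clipped to the
follow-up wall ring); the EEM is fixed.  One global seed; per-patient
sub-streams are derived deterministically, so cohorts are bit-for-bit
reproducible.

The outcome link is
DLA = γ0 + γ_f·A_surr + γ_pb·PB + b_patient + ε, with A_surr the Laplace
thin-wall hoop-stress amplitude ΔP·r_eq/t_mean, b ~ N(0, 0.15²) mm²,
ε ~ N(0, 0.25²) mm², γ_f = +0.15 mm²/kPa, γ_pb = −0.05 mm²/%.  The slopes
and noise were sized (before any mechanics run) so that the Bayes accuracy
of sign prediction sits in the mid-80% range — the regime the method is
meant to operate in — and the intercept γ0 = 1.25 mm² was calibrated once
so the narrowing fraction averages ≈ 145/305.  Geometry draws that would
produce a non-positive follow-up lumen or push a grown lumen outside the
EEM are resampled with a cap; a configuration rejecting more than 1% of
draws is an error.

What the generator does **not** emulate: image noise and segmentation
error, longitudinal registration error, plaque-component change between
timepoints, vessel curvature and bifurcations, and any within-patient
spatial correlation along the pullback beyond the shared random intercept.
Passing tests therefore demonstrate that the pipeline recovers a known
generative structure of realistic scale — not that the biological effect
sizes are as simulated.

A closed-form surrogate feature path (thin-wall stresses at both
pressures, strains via an effective modulus of 400 kPa stiffening with
plaque burden, linearized pressure–area compliance) mirrors the FE feature
table for fast exploration and CI; the FE path is the reference
implementation and both share every downstream contract.

## Problem sizes in the shipped checks

The test suite and acceptance script run the FE solver on coarse meshes
(0.1–0.3 mm edges) and scaled-down cohorts (tens of FE slices; the full
305-pair cohort through the surrogate path), chosen so the whole suite
completes in minutes while every oracle tolerance above is already met at
those resolutions.  Statistical calibrations use 500 replications at the
study's own size (7 × 44).

## Known limitations

* Generalized plane strain cannot represent axial bending or out-of-plane
  shear; the axial boundary conditions of a true extruded slice are
  approximated by one uniform stretch.
* The penalty formulation caps the achievable incompressibility; σ is
  accurate to O(σ/κ).
* The circumferential shrink is a single scale; real pre-stretch fields
  are inhomogeneous.
* The mixed-model screen assumes Gaussian errors and a random intercept
  only (no random slopes).
* The surrogate feature path is linearized thin-wall mechanics; it is for
  ordering and speed, not absolute stress values.
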