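# Methods

## Scope and assumptions

`arterywall` models one resistance-artery segment with constant,
externally imposed pressure P, flow Q and vasoactive stimulation (CON,
DIL, expressed as equipotent wall stress and shear stress in Pa). There
is no tissue feedback and no network: the segment cannot change its own
pressure or flow. SMC are assumed to wrap the vessel perpendicular to
its axis (zero pitch), the wall is a circular annulus, and the three
stress-bearing elements (matrix, active filaments, cytoskeleton) keep
fixed area fractions (⅓ each) during growth. Axial mechanics, separate
elastin/collagen pools, and concentration-based pharmacology of named
agonists are out of scope.

## Constitutive laws

The source equations for the element stresses are not available in
closed form in the extracted text, so the package uses reconstructions
that are anchored at the published parameter values and validated
against the published steady-state results (see "Validation" below):

* **matrix** (slack for ε ≤ 0, Pa):
  σ_p(ε) = c_p1 (e^{c_p3 ε} − 1) + c_p2 (e^{c_p4 ε} − 1), a
  bi-exponential law with a soft toe (c_p1 = 55 kPa, c_p3 = 1.5) and a
  very steep collagen-like limb (c_p2 = 0.0186 Pa, c_p4 = 24);
* **active capacity** (Pa):
  σ̂_a(l) = σ_amax · exp(−((l − l_opt)/l_w)²), a Gaussian bell peaking
  at 250 kPa for l_opt = 106.18 µm with width l_w = 45.868 µm; actual
  active stress is A·σ̂_a(l);
* **cytoskeletal brake** (Pa):
  σ_c(l) = c_c1 (l / c_c3)^{c_c2}, a power law equal to 250 kPa at
  c_c3 = 118.92 µm with exponent c_c2 = 30. The printed unit of c_c2
  (m⁻¹) is dimensionally inconsistent with any steep brake at these
  scales, so the exponent is treated as dimensionless. At the reference
  length (80 µm) the brake contributes ~1.7 Pa — negligible, as
  required.

Geometry convention: r_m is the mid-surface radius, wcsa = 2π r_m h
exactly, and r_i = r_m − h/2. This is exact for a circular annulus
(π(r_o² − r_i²) = 2π r_m h) and keeps the Laplace relation in its
thin-wall form σ_eq = P r_i / h.

## Rate laws

Mechanics and tone are linear first-order relaxations. For the three
structural laws the fixed points, signs and rate-constant units are
fixed by the published parameter table; the detailed kinetic factors are
the package's choice and do not affect any steady state:

* plasticity: d(sp)/dt = k_span (l_ref − l) l/l_ref. The l/l_ref factor
  makes the relative rate of length change carry the ratio of actual to
  reference cell length; the fixed point l = l_ref and its local
  stability are what the analyses rely on.
* remodeling: d(r_m,slack)/dt = k_slack r_m,slack (β ε − α A) — a linear
  balance of strain-driven outward and tone-driven inward reorganization,
  proportional to the slack radius itself (geometric similarity).
* growth: d(wCSA)/dt = k_growth wCSA (σ − σ_ref).

Equipotent-stress convention: CON adds to wall stress inside the
myogenic Hill curve; DIL adds to shear inside the dilation Hill curve.
Endothelial function ecf scales the dilatory pathway; values above 1
(supra-normal function) are allowed because the sensitivity analysis
perturbs ecf around its default of 1.

## Numerical choices

* **Integration.** BDF (stiff) with rtol 1e-5 and absolute tolerances
  1e-5 (ε), 1e-3 (A, sp), 0.01 µm (r_m,slack), 1 µm² (wCSA). The five
  relaxation times at the default state are ≈ 25 s (mechanics), 200 s
  (tone), 530 s (plasticity), 5·10⁴ s (remodeling) and 3.3·10⁵ s
  (growth); this spread is what makes the system stiff. Evaluation
  grids are log-spaced. Integration restarts at protocol breakpoints.
* **Strain floor.** ε is floored at −0.5 as a hard numerical constraint:
  stresses are evaluated at the floored strain and the strain rate is
  projected to zero at the floor, so constricting transients cannot push
  the state into unrepresentable geometry.
* **Steady states: integrate-then-polish.** A long integration (horizon
  chosen by the slowest active process: 10⁸ s for the full model, down
  to 10⁴ s for pure mechanics) approaches the attractor; damped Newton
  root-finding on the masked derivative then reduces the residual to
  ~1e-12 in scaled units (component scales = the absolute tolerances).
  A state is "stable" when the scaled residual is below 1e-10.
  Pure root-finding alone would be unreliable here because the system
  has saddle points (e.g. the tone knockout).
* **Stability is trajectory-based.** The integration start is displaced
  by a deterministic 0.1% relative kick so that a start placed exactly
  on an unstable equilibrium leaves its saddle; guard bounds on r_i
  (1% / 20× the initial value) classify collapse and runaway; an
  RHS-evaluation budget (3·10⁵) bounds trajectories that never settle
  — e.g. the mechanics+tone variant at 160 mmHg sustains a
  vasomotion-like limit cycle and is reported `nonconvergent`.
* **Full-model fixed point, semi-analytic.** At a full-model equilibrium
  l = l_ref, σ = σ_ref and βε = αA reduce the system to a scalar root
  for tone in the wall-composition closure; the tone set-point then
  yields the required shear, Poiseuille the radius and Laplace the wall
  thickness. `solve_growth_fixed_point` implements this reduction; it
  provides the canonical initial vessel and serves as an independent
  cross-check of the integrate-then-polish route in the tests (they
  agree to better than 1e-6 relative).
* **Quasi-static curves.** Pressure–radius relations at frozen
  structure/tone are computed by scanning and bracketing the mechanical
  load-balance in ε per pressure point, keeping the mechanically stable
  root continued from the previous point. Points without any equilibrium
  (e.g. full activation at the default structure, where active stress
  exceeds the load down to the strain floor — myogenic closure) are
  flagged NaN.
* **Sensitivity.** Central differences at ±5% (configurable; ±50%
  mirrors the published parameter-variation range). Entries whose
  perturbed run does not converge are NaN and recorded.

## What the defaults represent

The default parameter set describes a vessel that settles, at 80 mmHg
and 0.25 µL/s, at r_i ≈ 68 µm, tone ≈ 0.37, wall stress 30 kPa and wall
shear 3.56 Pa (35.6 dyn/cm²). Because the wall-side equilibrium fixes
the total dilatory shear stimulus, steady-state radius is independent of
pressure, shear is independent of flow, and chronic dilators trade 1:1
against shear until the total (≈ 35.6 dyn/cm²) is exhausted — beyond
that the radius grows without bound (aneurysm-like runaway).

## Known limitations

* The constitutive forms are reconstructions; quantities that depend on
  the local slope of σ_p or σ̂_a (the non-structural sensitivity
  entries) carry a few-percent transcription uncertainty, which is why
  they are validated at ±0.05 absolute / ±10% relative rather than to
  printed precision.
* Some extreme parameter variations (reference SMC length halved or
  ×1.5, reference growth stress halved) have no equilibrium in this
  reconstruction: the required tone exceeds the Hill ceiling and the
  vessel diverges. This matches the qualitative "contractile
  dysfunction / forced dilation" regime described for low reference
  lengths, but the original parameter-variation maps show converged
  states there.
* Initial states whose wall area can close the lumen within the
  admissible strain range (r_m² ≤ wcsa/4π at the strain floor) are
  outside the representable basin: the fast mechanical constriction
  seals the vessel before slower processes react. Basin-robustness
  claims therefore apply to geometrically admissible starts
  (`engine.lumen_open_at_strain_floor`).
* Verdicts are trajectory-based; no eigenvalue/bifurcation analysis is
  performed, so a `nonconvergent` verdict does not distinguish a limit
  cycle from very slow convergence.
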