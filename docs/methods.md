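# Methods

This note documents the model equations, the numerical choices, the
study conditions baked into the defaults, and the known limitations —
including one important dynamical property of the published parameter
set that anyone using this package should understand.

## Model

### Cross-bridge kinetics

Each smooth-muscle fiber direction carries a four-state Hai–Murphy
population `n = (nA, nB, nC, nD)` (detached/attached ×
dephosphorylated/phosphorylated, with D the latch state) evolving as
`dn/dt = K n`. The rate matrix couples the states through
phosphorylation `k1 = k6 = k16` (MLCK), dephosphorylation
`k2 = k5 = k25` (MLCP), attachment `k3` and detachment `k4`, `k7`
(constants). Column sums of `K` are zero, so `sum(n) = 1` is an exact
invariant of both the ODEs and the backward-Euler discretization, and
`K` is a Metzler matrix, so the implicit update also preserves
`n >= 0` for any step size.

### Stretch sensing

The total fiber stretch `lam = sqrt(a·C·a)` (not its elastic part)
drives two regulation loops:

* **Calcium / MLCK (fast).** `[Ca] = gamma1 <lam - lam_c>^2` (µM,
  Macaulay bracket), `k16 = eta [Ca]^2/([Ca]^2 + Ca50^2)`. The
  reference stretch `lam_c` obeys a four-parameter sigmoid rate in
  `delta = [Ca]_target - [Ca]`, bounded by ±0.0443 1/s, with target
  `[Ca]_tar = gamma3 lam^2/(lam^2 + lam50c^2)`. The sigmoid offset
  tau is constructed so the rate is exactly zero at `delta = 0`. An
  unstretched artery therefore develops a basal calcium tone of
  `[Ca]_tar(1) = 0.369 µM` within seconds — intended behavior, not a
  bug.
* **MLCP (slow).** `k25` falls while the wall is stretched beyond a
  second reference `lam_p` (rate bounded by [−1.07e-3, 0.97e-3] 1/s²,
  with a `1 - exp(-zeta1 k25)` factor that makes `k25 = 0` an exact
  lower barrier) and `lam_p` adapts at rates bounded by
  [−2.3e-4, 0.7e-4] 1/s depending on `k25_target(lam) - k25`, with an
  exponential barrier keeping `lam - lam_p` above `-1e-5`.

### Active and passive mechanics

Multiplicative split `lam = lam_a lam_e`; active energy
`Psi_a = mu_a/2 (nC + nD)(lam_e - 1)^2` per fiber; driving stress
`P_c = kappa nC`; Hill-type evolution
`d(lam_a)/dt = beta1 (P_a - P_c)/(P_a + beta2)`. Here `P_a` is the
total-stretch conjugate stress `dPsi_a/d lam = mu_a (nC + nD)
(lam_e - 1)/lam_a` — note the `1/lam_a` chain-rule factor, without
which the isometric balance `P_a = P_c` is unreachable at realistic
attached-head fractions and the contraction runs away (the λ_e-
conjugate form `mu_a (nC+nD)(lam_e-1)` is exposed separately as
`active_stress`). The active second Piola–Kirchhoff contribution is
`2 dPsi_a/dC` at frozen internal variables, i.e.
`P/(lam_a lam) a⊗a`.

The passive wall is polyconvex:
`alpha1 (I1 I3^{-1/3} - 3) + alpha2 (I3^alpha3 + I3^{-alpha3} - 2)`
plus `alpha4 <K3 - 2>^alpha5` per collagen/SMC family,
`K3 = I1 I4 - I5` (zero stiffness in fiber compression; `alpha5 > 2`
makes the cutoff C¹). Linearized at identity this gives shear modulus
`mu = 2 alpha1` and bulk modulus `K = 8 alpha2 alpha3^2` — the basis of
the small-pressure Lamé check in the test suite.

## Numerics

* **Local integration.** Backward Euler everywhere. `lam_c` is a
  scalar bracketed Newton (the bounded rate confines the root to
  `old + dt·[rate_min, rate_max]`, so the iteration is globally
  convergent even when the sigmoid saturates). `(k25, lam_p)` is a
  damped 2×2 Newton with analytic Jacobian; after a sudden stretch
  drop the iteration starts at the `zeta2` barrier wall rather than on
  its exponential cliff. The fractions are one 4×4 linear solve.
  `lam_a` is a damped scalar Newton. Tolerances 1e-10 (chemistry) and
  1e-12 (active stretch), 50 iterations, previous step as the guess;
  each solver finishes with one pure Newton polish step so that
  complex-step perturbations propagate exactly through the iteration.
* **Tangents by complex step.** All constitutive code is written to
  accept complex scalars (branches decided on real parts, capped
  exponentials, overflow-safe logistic). The 6×6 material tangent is
  `Im S(C + i h E_k)/h` with `h = 1e-20`, with the internal variables
  re-solved for every perturbed `C` — fully coupled, matched against
  central finite differences in the tests.
* **Ring solver.** The pressurized ring is θ-independent and axially
  constrained (plane strain, `lam_z = 1`), so equilibrium is solved in
  the radius only: quadratic 3-node elements in the reference radius,
  2-point (reduced) Gauss quadrature — reduced integration is needed
  because the strong volumetric penalty otherwise produces
  checkerboard `sigma_rr` modes — with one material-point history per
  quadrature point and a follower pressure load. Defaults: 4 elements
  (9 nodes, 8 quadrature points), mirroring a 4-element radial
  resolution; doubling the resolution moves the 120 mmHg outer
  diameter by < 1e-4 µm. Newton with backtracking line search uses the
  complex-step consistent tangent (quadratic local convergence,
  asserted in the tests); when the penalty creates a narrow curved
  valley far from the solution, a Powell-dogleg trust-region fallback
  (scipy `root(method="hybr")` on the same residual/Jacobian) bridges
  the global phase.
* **Residual stress.** Opening-angle closing with
  `k_phi = pi/(pi - phi)`, `lam_theta = k_phi r(R)/R` (phi interpreted
  as the half opening angle; conventions differ across the literature
  and the alternative `2pi/(2pi - phi)` changes details but not the
  qualitative behavior). The closing solve precedes the 600 s
  preconditioning hold.
* **Protocols.** Pressure steps are ramped linearly over 1 s (5
  sub-steps) — a numerical regularization standing in for the
  not-actually-instantaneous experimental pressurization. Holds are
  stepped at dt = 1 s, waves at dt = 0.02 s by default. Failed steps
  retry with recursive dt halving (≤ 5 levels).

## Study conditions and defaults

All parameter defaults are the optimized values for a rat middle
cerebral artery segment: passive `alpha1..alpha5` and opening angle
38.923°, chemical constants (`k3 = 0.134`, `k4 = 0.00166`,
`k7 = 6.6e-5` 1/s, `Ca50 = 0.4` µM, ...), active constants
(`mu_a = 11.857`, `kappa = 148.262`, `beta2 = 26.68` kPa,
`beta1 = 1.006e-3` 1/s), start values (`nA = 1`, `k25 = 1.82758` 1/s,
`lam_c = lam_p = lam_a = 1`), ring radii 92/112 µm, fiber angle
10°→40°. The staircase protocol is 600 s at 10 mmHg followed by
300 s holds at 20–120 mmHg in 20 mmHg increments (the intermediate
levels are this package's choice; only the preconditioning, the hold
time and the final level are fixed by the experimental description).
The wave protocol holds 80 mmHg for 2000 s, then applies 1 Hz
raised-cosine waves at 120/80, 180/120 (at 3000–3400 s) and back;
the acceptance tests run a time-scaled variant (600 s hold, 600 s of
120/80 waves, a 500 s 180/120 episode, 100 s of 120/80, dt = 0.2 s,
2 radial elements) so the full suite fits a routine CI budget; at that
scale the fully active wall is still mid-cascade rather than in the
fully developed repetitive regime, but the regulation signature
(diastolic re-contraction during the high episode, maxima returning
toward the low-regime value) is preserved and both model reductions
demonstrably lack it.

The synthetic-trace generator produces forward-model diameter traces
with multiplicative Gaussian noise (seeded); it emulates the sampling
noise of diameter tracking in a pressure myograph but none of the
systematic effects of real experiments (drift, wall-detection bias,
temperature/solution changes), so passing recovery tests demonstrate
identifiability under the model, not robustness to model error.
Passive-stage fits exploit that the passive response is elastic:
each sample is a static equilibrium, cached per pressure level.
Fitting uses seeded differential evolution (population mirroring the
~40 concurrent candidates used when the reference parameters were
produced; optional polish); tolerances and budgets are exposed on
`FitSpec`.

## Dynamics of the published parameter set: a caution

The `(k25, lam_p)` subsystem is a positive-feedback pair: once `k25`
falls below its stretch target, `lam_p` *decreases* (at up to
2.3e-4 1/s), which re-opens the stretch difference and inhibits MLCP
further. Consequences, verified numerically:

* The interior fixed point returned by `chem_steady_state` is a
  saddle. Held at constant stretch, the virgin state does not converge
  to it: for `lam ≳ 1.1` `k25` crashes to its zero barrier (and `nC`
  approaches 1); for smaller stretches `k25` drifts slowly upward with
  `lam_p` parked at the barrier. The fixed point is still exactly
  preserved by the implicit integrator when started on it, which is
  what the tests assert.
* On the staircase boundary-value problem the terminal state is
  decided by a razor-edge race between the contraction speed (bounded
  by `beta1`) and the bounded `lam_p` rates. In this solver the race
  robustly ends in the strong-contraction basin: `k25 → 0`,
  `nC → 0.99`, peak `lam_e ≈ 3.6`, peak circumferential stress
  ≈ 74 kPa, end diameter ≈ 132 µm — rather than the
  moderate-contraction end state (`nC ≈ 0.25`, `lam_e ≈ 2.25`,
  ≈ 30 kPa) reported for the reference 3D computation. The outcome is
  unchanged under dt ∈ {0.5, 1, 10} s, ramp 0.1 vs 1 s, 4 vs 8 radial
  elements, and both opening-angle conventions; mid-protocol states
  (e.g. `nC = 0.28`, `lam_e = 1.87` at t = 1800 s) and the
  passive-vs-Y27632 diameter gap (≈ 21 µm) do match the reference
  behavior quantitatively. Swapping the orientation of the `lam_p`
  sigmoid (the "stabilizing" variant) was tested and makes the crash
  happen earlier; it is not the resolution.

Anyone fitting this model to their own data should be aware that
terminal states at high sustained stretch sit on this knife edge.

## Limitations

* Reduced 1D radial ring: exact for the symmetric plane-strain problem
  posed here, but no axial stretch scenarios, no 3D geometry, no
  fluid–structure interaction.
* No fiber dispersion, no filament-overlap modulation, no
  vasoconstrictor pharmacology, no electrophysiology.
* The experimental pressure–diameter traces behind the parameter set
  exist only as published figures; the fitting layer is therefore
  validated by synthetic-data recovery, and a CSV import path is
  provided for users with digitized data.
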