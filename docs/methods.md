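# Methods

This note documents the modelling choices, numerical treatments and known
limitations of the package. Stresses and moduli are in kPa, times in
seconds; stretches and the exponents are dimensionless.

## Constitutive formulations

All four models are hyperelastic and transversely isotropic with respect to
a unit reference fiber direction m (structural tensor M = m ⊗ m). The
homogeneous load cases fix the fiber along the third coordinate axis and
are isochoric by construction, which the incompressible analytic responses
require; the uniaxial gradients are therefore written with the square-root
lateral contractions diag(λ^{-1/2}, λ^{-1/2}, λ) (and its permutation for
transverse loading).

**Active-stress model (ASE).** The isochoric energy separates along-fiber
shear (G₁B₁²), transverse shear (G₂B₂²), and a fiber term defined through
the total Cauchy fiber stress, ∂Ψ_f/∂λ̄ = σ_f/λ̄. The shear invariants are
B₁ = √(Ī₅/Ī₄² − 1) and B₂ = acosh θ with θ = (Ī₁Ī₄ − Ī₅)/(2√Ī₄).
Activation scales a parabola-blend force-length factor f_a (continuously
differentiable; both one-sided values at the branch junctions 0.6·λ_opt and
1.4·λ_opt equal 0.36) while the passive factor f_p is tension-only:
exponential on (1, λ*), linear beyond, with the linear coefficients derived
for C¹ continuity. The model is paired with an isochoric neo-Hookean term
(μ = 10 kPa) because without it a purely compressive fiber state carries no
stress at all. The volumetric part is (K/2)(ln J)² with an isochoric/
volumetric split of the invariants.

**Generalized active-strain family (GASA / ASA / GASAM).** The shared
energy is the exponential two-invariant form
Ψ = γ/4[(e^{α(Ĩ−1)}−1)/α + (e^{β(J̃−1)}−1)/β + (det C^{−κ}−1)/κ] with
L̃ = (ω₀/3)I + (1−ω₀)M. The volumetric penalty is coupled (no isochoric
split). Activation enters the first generalized invariant only,
Ĩ = C : L̃ + ω_a·(C : M); this is the unique reading consistent with the
explicit activation level of the modified model (re-deriving it from the
uniaxial energy balance reproduces that expression term by term).

All three variants calibrate ω_a against incompressible uniaxial loading
along the fiber, demanding that the model's fiber-direction nominal stress
equal the passive response plus the active nominal stress
P_a = P_opt·f_t·f_ξ(λ):

* GASA holds ω_a fixed in the stress. Solving the matching condition in
  closed form yields ω_a = W₀(χ*)/(αλ²) − Ĩ_p′/(2λ) with
  χ* = (2αλP_a/γ)·e^{α(2−2Ĩ_p+λĨ_p′)/2} + (αλĨ_p′/2)·e^{αλĨ_p′/2},
  where W₀ is the principal Lambert-W branch and Ĩ_p(λ), Ĩ_p′(λ) are the
  closed-form uniaxial passive invariants (verified in the tests against
  direct tensor contraction to 1e-12).
* ASA solves the implicit uniaxial energy balance for ω_a by Newton
  iteration seeded with the explicit GASAM level (brentq bisection
  fallback), to an absolute tolerance of 1e-10. Its stress includes
  S₂ = 2(∂Ψ_e/∂ω_a)(∂ω_a/∂C) with ∂ω_a/∂λ by central differences at
  relative step 1e-6 (the spectral norm of the resulting stress error is
  well below the 1e-6 energy-consistency tolerance).
* GASAM adds S_{ω_a} = (γ/4)e^{α(Ĩ−1)}λ(∂ω_a/∂λ)M to the frozen-level
  stress, which renders ω_a explicit: ω_a = ln φ/(αλ²) with
  φ = 1 + (4α/γ)e^{α(1−Ĩ_p)}P_opt·f_t·∫f_ξ; the stretch derivative is
  analytic.

A direct consequence, asserted in the tests: the three variants produce
identical passive responses everywhere and identical active uniaxial
along-fiber responses; they differ in active transverse and shear loading
through the differing treatment of the activation level's deformation
dependence.

## Activation in time and space

The tanh ramp f_t = tanh(c(t − t₀)) is clamped to zero before the start
time (the raw tanh would be negative). Its rate c = 34.4017 1/s is shipped
as the fitted default. The twitch train superposes, per motor-unit type i,
single twitches of the classical normalized shape (Δt/T_i)e^{1−Δt/T_i}
fired every interstimulus interval I_i, weighted by ρ_i·F_i and scaled by
Na; the sum is normalized by its analytic long-time plateau mean
Na·Σρ_iF_i·e·T_i/I_i so the fused tetanus is 1. The precise superposition
formula of the micro-mechanical source model is not reproduced in the
literature available to the package, so this classical shape is a
documented stand-in: it preserves the semantics of T_i (time to single-
twitch peak) and produces a fused tetanus, but its absolute (un-normalized)
plateau differs from the source's. For that reason the shipped fitted
parameter set carries the peak active nominal stress P_opt = 64.6809 kPa
directly for all three generalized-family members (the family shares one
fitted uniaxial active response), with Na and the twitch micro-parameters
retained for the time dependence only.

Spatiotemporal activation reduces, at a material point, to a scaling factor
s ∈ [0, 1] multiplying the time function (`Activation.scaled`); activation
schedules are read from two-column (time, s) tables with step
interpolation. The 5%-scaled tetanic peak stress of the rotator-cuff
scenario, 0.05 × 64.6809 ≈ 3.234 kPa, is computed through this mechanism.

## Load-case responses

The fully incompressible responses evaluate the models without their
volumetric terms and eliminate the constraint pressure through one
traction-free face per load case (UTCAF: P₃₃ reported with P₁₁ = 0; UTCTF:
P₁₁ with P₂₂ = 0; PSAF: P₃₃ with P₁₁ = 0; PSTF: P₁₁ with P₃₃ = 0; PSTIF:
P₁₁ with P₂₂ = 0; simple shear reports the pressure-independent P₃₂).
These assignments follow standard uniaxial/planar-tension testing
conventions; they are the only ones consistent with a single reported
stress per curve.

The nearly incompressible responses mimic a displacement-driven unit-cube
experiment: the stretch in the traction-free direction is released and
solved for vanishing nominal stress (bracketed brentq, expanding from the
isochoric guess), all other directions held at their tabulated values. For
transverse uniaxial loading this means the fiber direction is guided at
λ^{-1/2} and only the free transverse face equilibrates — the same boundary
conditions as the incompressible computation, so the two converge as the
penalty grows. With the shipped penalties (κ = 1000, K = 10000 kPa) the
curve-level deviation max|ΔP|/max|P| is below 1% for every load case, and
it decreases monotonically over κ ∈ {10, 100, 1000} (for the bulk modulus
the ladder {100, 1000, 10000} kPa is used; a bulk modulus of 10 kPa would
sit at the shear-modulus scale and is not a near-incompressible regime).
The curve-level normalization is used because every passive curve crosses
zero at the reference state, where a pointwise relative error is
undefined.

The free-contraction analogue roots the tetanic uniaxial response on
(max(λ_min + 10⁻³, 0.45), 1) by brentq at 1e-8; a passive activation input
returns the reference stretch 1 directly.

## Numerical treatments

* The transverse-shear invariant derivative carries the factor
  A(θ) = acosh θ/√(θ²−1), singular as θ → 1 (vanishing transverse
  asymmetry). For θ − 1 < 1e-9 the series limit A ≈ 1 − (θ−1)/3 is used —
  an exact limit rather than an ε-perturbation, so axisymmetric stretch
  states evaluate cleanly; the resulting term is then a pure pressure and
  cancels from the reported incompressible responses. θ ≥ 1 holds for all
  isochoric states (by the arithmetic–geometric mean inequality applied to
  the transverse stretches); θ < 1 − 1e-8 raises a domain error signalling
  inconsistent input.
* Note that B₂ measures transverse *asymmetry*, not merely shear: it is
  nonzero for uniaxial loading transverse to the fiber (unequal in-plane
  stretches), and zero exactly on transversely symmetric diagonal states.
* The fiber energy of the active-stress model is obtained by adaptive
  quadrature of σ_f/λ̄ from 1 to λ̄ (tolerance 1e-10); the stress uses σ_f
  directly, so the quadrature only backs energy-consistency checks. The
  force-length integral ∫f_ξ starts at λ_min, honoring the kink there.
* The elasticity tensor is computed by symmetric central differences of S
  with respect to C (relative step 1e-6), minor symmetries enforced by
  symmetrization and the major-symmetry residual reported; closed forms are
  intentionally out of scope. With the stiff shipped penalty (κ = 1000) the
  higher C-derivatives of the volumetric term dominate the finite-
  difference truncation error, so the directional-derivative verification
  uses a moderate penalty (κ = 10).

## Parameter identification

Fitting is staged — passive parameters first (ASE: G₁, G₂, D₁, D₂, λ*;
family: α, β, γ, ω₀) against the passive curves of all six load cases,
then active parameters (ASE: a, λ_opt; family: P_opt, λ_opt, λ_min)
against the active uniaxial along-fiber curve at tetanus (time functions
set to 1), with the passive set fixed. Staging is possible because the
active and passive contributions decouple in every model. The optimizer is
scipy's Trust Region Reflective with physiological box bounds
(ω₀ ∈ (0.01, 0.99), λ_opt ∈ (1.0, 1.6), λ_min ∈ (0.3, 0.9),
λ* ∈ (1.05, 2.0), positive lower bounds 1e-4 elsewhere). Design choices:

* σ_max is held fixed rather than fitted: it multiplies both the passive
  (σ_max·D₁) and active (σ_max·a) fiber terms, so only those products are
  identifiable; D₁ and a carry the freedom.
* The incompressibility parameters κ and K are fixed, not fitted.
* The family's active uniaxial residuals use the shared analytic response
  P_pas(λ) + P_a(λ) rather than the constitutive activation solve: the two
  coincide wherever the solve is feasible, but the analytic form remains
  defined where a trial parameter set would demand ω_a ≥ 1, keeping the
  optimizer's landscape free of penalty cliffs.
* If a parameter's Jacobian column is numerically zero at the first
  solution (typically a kink location such as λ* lying beyond the sampled
  stretch range), it is re-centered into the lower part of its bounds and
  the solve repeated (at most twice); genuinely unidentifiable parameters
  (e.g. the shear moduli from uniaxial along-fiber data alone) are
  reported in the fit result instead.
* Constitutive failures during residual evaluation are mapped to a large
  finite penalty so the optimizer stays in-domain; optimizer failures
  return a non-converged result with diagnostics rather than raising.

Goodness of fit is reported per curve as RMSE (kPa), range-normalized RMSE
and maximum absolute deviation — a reasonable superset of the error
measures customarily reported for such fits.

## Synthetic data

The generator emulates the structure of the characterization dataset: six
passive load-case curves plus an active tetanic uniaxial along-fiber
curve, computed from a chosen model/parameter set and perturbed by
multiplicative Gaussian noise (relative noise keeps all modes informative,
as the stress magnitudes span orders of magnitude across modes). Default
grids: passive along-fiber λ ∈ [0.7, 1.5] with 20 points (extending beyond
λ* = 1.4 so the linear passive branch is exercised and λ* is
identifiable), transverse λ ∈ [0.7, 1.3], shear amount ∈ [0.02, 0.4],
pure-shear modes λ ∈ [1.0, 1.3] with 16 points, active λ ∈ [0.6, 1.3] with
25 points (bracketing the force-length optimum); default relative noise
0.02. The noiseless recovery experiments in the tests use these defaults;
the noisy (2%) experiment uses 40-point grids for conditioning. What
passing recovery tests show is that the identification pipeline is
self-consistent — they do not certify the models against real tissue,
whose inter-study heterogeneity, strain-rate effects and measurement bias
the generator deliberately does not emulate.

## Limitations

* Purely hyperelastic: no viscoelasticity, no history-dependent force
  enhancement/depression, no metabolic energetics.
* The force–velocity dependency is the constant 1 throughout.
* ω_a is calibrated from uniaxial fiber loading by construction; the
  package does not generalize the calibration to other deformation modes.
* No finite-element machinery: all results are material-point quantities
  (homogeneous deformations of a unit cube); three-dimensional geometry,
  contact and fiber-field effects are out of scope.
* The GASA activation solve is infeasible (ω_a ≥ 1) for short fiber
  stretches combined with large active stress demands; the package raises
  a dedicated error there rather than clamping.
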