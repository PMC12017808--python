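# myomech

Hyperelastic constitutive models for **active skeletal muscle** at the
material-point level: four transversely isotropic formulations, their
activation-level computations, homogeneous load-case stress responses, and
multi-load-case parameter identification. The package targets the
constitutive layer of continuum-mechanical musculoskeletal models (e.g. of
the human shoulder), where muscles act both as force generators and as
active joint stabilizers.

## The models

All four models describe nearly incompressible, transversely isotropic
tissue with reference fiber direction **m**, structural tensor
M = m ⊗ m, right Cauchy–Green tensor C = FᵀF, and fiber stretch
λ = √(C : M). Stresses follow from a strain-energy density Ψ via
S = 2 ∂Ψ/∂C and P = F S (units: kPa).

* **ASE** (active stress): Ψ = G₁B₁² + G₂B₂² + Ψ_f(λ̄) + (K/2)(ln J)² plus an
  isochoric neo-Hookean companion term (shear modulus μ) for matrix
  compression stiffness. B₁, B₂ are along/transverse-fiber shear strain
  invariants; the fiber energy is defined through the total Cauchy fiber
  stress, ∂Ψ_f/∂λ̄ = σ_f/λ̄, with σ_f = σ_max(λ̄/λ_opt)·a·f_t·f_a(λ̄) +
  σ_max·λ̄·f_p(λ̄). Activation adds stress in parallel.
* **GASA** (generalized active strain): Ψ = γ/4·[(e^{α(Ĩ−1)}−1)/α +
  (e^{β(J̃−1)}−1)/β + (det C^{−κ}−1)/κ] with generalized invariants
  Ĩ = C : L̃ + ω_a·C : M and J̃ = cof C : L̃, where
  L̃ = (ω₀/3)I + (1−ω₀)M mixes matrix and fibers. The activation parameter
  ω_a enters the first invariant and is given **explicitly** through the
  principal branch of the Lambert W function, calibrated so the uniaxial
  fiber-direction nominal stress equals passive + active nominal stress.
* **ASA** (active strain): the same energy expressed in the elastic part of
  the multiplicative split F = F_e F_a with
  F_a = (1−ω_a)M + (1−ω_a)^{−1/2}(I−M), det F_a = 1. ω_a is the root of an
  implicit energy balance (Newton with bisection fallback), and the stress
  includes the term 2(∂Ψ_e/∂ω_a)(∂ω_a/∂C).
* **GASAM** (modified generalized active strain): GASA plus the stress term
  S_{ω_a} = 2(∂Ψ/∂ω_a)(∂ω_a/∂C), which makes ω_a fully explicit,
  ω_a = ln φ/(α λ²), with an analytic stretch derivative. Time dependence
  uses a smooth tanh ramp instead of the motor-unit twitch train.

The active nominal stress is P_a = P_opt · f_t(t) · f_ξ(λ), with a
force-length relation f_ξ that vanishes below λ_min and peaks (=1) at
λ_opt, and a time function f_t that is either a tanh ramp or a normalized
superposition of motor-unit twitch trains. Spatiotemporally varying
activation enters as a per-evaluation scaling factor s ∈ [0, 1].

Because the three generalized active-strain variants calibrate ω_a against
the same uniaxial decomposition, they share the identical active uniaxial
along-fiber response and the identical passive response for all load cases;
they differ in active transverse and shear loading.

## Worked example

The fitted parameter set ships as the named fixture `table5`. The
material-point analogue of a tetanic **free contraction** is the stretch at
which the incompressible uniaxial along-fiber nominal stress vanishes:

```bash
$ myomech stressfree
{
  "stress_free_stretch": {
    "ASE": 0.68398,
    "GASA": 0.709295,
    "ASA": 0.709295,
    "GASAM": 0.709295
  },
  "scale": 1.0
}
```

The active-stress model shortens to ≈ 0.68 of its reference length, the
generalized active-strain family to ≈ 0.71 — the family generates no active
stress below λ_min = 0.568, and resists compression more strongly. The
**isometric** counterpart (held reference length) gives the tetanic
fiber-direction stress in kPa:

```bash
$ myomech isometric
{
  "isometric_stress_kPa": {
    "ASE": 56.0798667604539,
    "GASA": 58.64675101910413,
    "ASA": 58.646751037917284,
    "GASAM": 58.646751019104094
  },
  "scale": 1.0
}
```

GASA and ASA agree to solver precision, as their activation-level
constructions guarantee. From Python, the same quantities and full stress
tensors are available directly:

```python
import myomech as mm

model = mm.get_model("GASAM")
res = mm.pk2_stress(model, [[1, 0, 0], [0, 1, 0], [0, 0.2, 1]],
                    act=mm.Activation.tetanic())
print(res.omega_a_used)   # 0.7564516043907942 — activation level used
print(res.P[2, 1])        # 5.138424014024266 kPa nominal shear stress
```

Synthetic stress–stretch datasets (six passive load cases + active uniaxial
tension/compression along the fiber), and the two-stage passive → active
parameter identification:

```bash
myomech generate --model GASAM --noise 0.02 --seed 1 --out curves.tsv
myomech fit --model GASAM --curves curves.tsv
```

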