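"""Activation-parameter computation for the generalized active-strain family.

The internal activation parameter ``omega_a`` quantifies the contraction
level. All three variants calibrate it against incompressible uniaxial
loading along the fiber (C = diag(1/lam, 1/lam, lam^2)) such that the model's
fiber-direction nominal stress decomposes into the passive response plus the
active nominal stress ``Pa``:

* GASA — stress matching with ``omega_a`` held fixed in the stress yields an
  explicit expression in terms of the principal branch of the Lambert W
  function.
* ASA — the multiplicative active-strain split makes the matching condition
  an implicit energy balance; it is solved by a damped Newton iteration
  seeded with the explicit GASAM level, falling back to bracketing bisection.
* GASAM — including the d(omega_a)/dC stress term turns the balance into an
  explicit logarithm, with an analytic stretch derivative.

A direct consequence of the three calibrations is that GASA, ASA and GASAM
share the identical uniaxial fiber-direction nominal stress Ppas + Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .activation import f_xi, f_xi_integral
from .params import GenActiveStrainParams

__all__ = [
    "UniaxialPassiveInvariants",
    "uniaxial_passive_invariants",
    "uniaxial_elastic_invariants",
    "omega_gasa",
    "omega_asa",
    "omega_gasam",
    "ActivationInfeasibleError",
    "ActivationConvergenceError",
]

OMEGA_MAX = 1.0 - 1e-9


class ActivationInfeasibleError(ValueError):
    """The requested active stress cannot be realized by any omega_a in [0, 1)."""


class ActivationConvergenceError(RuntimeError):
    """The implicit activation solve found no root in [0, 1)."""


@dataclass(frozen=True)
class UniaxialPassiveInvariants:
    """Passive generalized invariants on the incompressible uniaxial path."""

    Itilde_p: float
    Jtilde_p: float
    Itilde_p_prime: float
    Jtilde_p_prime: float


def uniaxial_passive_invariants(lam: float, omega0: float) -> UniaxialPassiveInvariants:
    """Closed forms of the passive generalized invariants for
    C = diag(1/lam, 1/lam, lam^2) and their stretch derivatives."""
    if lam <= 0.0:
        raise ValueError("stretch must be positive")
    w3 = omega0 / 3.0
    wp = 1.0 - omega0
    Ip = w3 * (2.0 / lam + lam**2) + wp * lam**2
    Ip_p = w3 * (-2.0 / lam**2 + 2.0 * lam) + 2.0 * wp * lam
    Jp = w3 * (2.0 * lam + 1.0 / lam**2) + wp / lam**2
    Jp_p = w3 * (2.0 - 2.0 / lam**3) - 2.0 * wp / lam**3
    return UniaxialPassiveInvariants(Ip, Jp, Ip_p, Jp_p)


def uniaxial_elastic_invariants(lam: float, omega_a: float, omega0: float):
    """Elastic generalized invariants (Itilde_e, Jtilde_e) on the uniaxial
    path after the active split: Ce = diag((1-wa)/lam, (1-wa)/lam,
    lam^2/(1-wa)^2)."""
    one = 1.0 - omega_a
    w3 = omega0 / 3.0
    wp = 1.0 - omega0
    lam_e2 = lam**2 / one**2
    Ie = w3 * (2.0 * one / lam + lam_e2) + wp * lam_e2
    Je = w3 * (2.0 * lam / one + 1.0 / lam_e2) + wp / lam_e2
    return Ie, Je


def omega_gasa(lam: float, Pa: float, p: GenActiveStrainParams) -> float:
    """Explicit Lambert-W activation level of the GASA model.

    ``Pa`` is the active nominal stress in kPa; ``omega_a = 0`` when it
    vanishes.
    """
    if lam <= 0.0:
        raise ValueError("stretch must be positive")
    if Pa < 0.0:
        raise ValueError("active nominal stress must be nonnegative")
    if Pa == 0.0:
        return 0.0
    a, g = p.alpha, p.gamma
    ui = uniaxial_passive_invariants(lam, p.omega0)
    Ip, Ipp = ui.Itilde_p, ui.Itilde_p_prime
    chi = (2.0 * a * lam * Pa / g) * np.exp(0.5 * a * (2.0 - 2.0 * Ip + lam * Ipp)) \
        + 0.5 * a * lam * Ipp * np.exp(0.5 * a * lam * Ipp)
    if chi < -np.exp(-1.0):
        raise ActivationInfeasibleError(
            f"Lambert-W argument {chi} below -1/e for lam={lam}, Pa={Pa}")
    w = float(np.real(lambertw(chi, k=0)))
    omega = w / (a * lam**2) - Ipp / (2.0 * lam)
    if not 0.0 <= omega < 1.0:
        raise ActivationInfeasibleError(
            f"omega_a = {omega} outside [0, 1) for lam={lam}, Pa={Pa}")
    return omega


def _energy_lhs(omega: float, lam: float, p: GenActiveStrainParams) -> float:
    Ie, Je = uniaxial_elastic_invariants(lam, omega, p.omega0)
    with np.errstate(over="ignore"):
        return (np.expm1(p.alpha * (Ie - 1.0)) / p.alpha
                + np.expm1(p.beta * (Je - 1.0)) / p.beta)


def _energy_lhs_prime(omega: float, lam: float, p: GenActiveStrainParams) -> float:
    one = 1.0 - omega
    w3 = p.omega0 / 3.0
    wp = p.omega_p
    dIe = w3 * (-2.0 / lam + 2.0 * lam**2 / one**3) + 2.0 * wp * lam**2 / one**3
    dJe = w3 * (2.0 * lam / one**2 - 2.0 * one / lam**2) - 2.0 * wp * one / lam**2
    Ie, Je = uniaxial_elastic_invariants(lam, omega, p.omega0)
    return (np.exp(p.alpha * (Ie - 1.0)) * dIe + np.exp(p.beta * (Je - 1.0)) * dJe)


def omega_asa(lam: float, f_time: float, p: GenActiveStrainParams,
              tol: float = 1e-10, max_iter: int = 60) -> float:
    """Implicit activation level of the active-strain model.

    Solves the uniaxial energy balance (elastic energy at activation equals
    passive energy plus 4/gamma times the integrated active nominal stress)
    by Newton iteration seeded with the explicit GASAM level, with a
    bracketing fallback.
    """
    if lam <= 0.0:
        raise ValueError("stretch must be positive")
    amp = p.P_opt * f_time
    if amp == 0.0 or lam <= p.lam_min:
        return 0.0
    integral = f_xi_integral(lam, p.stretch_dependency())
    rhs = _energy_lhs(0.0, lam, p) + 4.0 / p.gamma * amp * integral
    g = lambda w: _energy_lhs(w, lam, p) - rhs

    omega = omega_gasam(lam, f_time, p)[0]
    omega = min(max(omega, 0.0), 0.9 * OMEGA_MAX)
    for _ in range(max_iter):
        val = g(omega)
        if abs(val) < tol:
            return omega
        step = -val / _energy_lhs_prime(omega, lam, p)
        new = omega + step
        if not 0.0 <= new < OMEGA_MAX:
            break
        if abs(new - omega) < 1e-15:
            return new
        omega = new
    else:
        if abs(g(omega)) < 1e-8:
            return omega

    # bisection fallback on [0, 0.999...]
    from scipy.optimize import brentq

    lo, hi = 0.0, 0.999
    glo = g(lo)
    while g(hi) * glo > 0.0:
        hi = 0.5 * (hi + 1.0)
        if hi > OMEGA_MAX:
            raise ActivationConvergenceError(
                f"no activation root in [0, 1) for lam={lam}, f_time={f_time}; "
                f"g(0)={glo:.3e}, g({OMEGA_MAX})={g(OMEGA_MAX):.3e}")
    return float(brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16))


def omega_gasam(lam: float, f_time: float, p: GenActiveStrainParams):
    """Explicit activation level of the modified model and its stretch
    derivative ``d(omega_a)/d(lam)``."""
    if lam <= 0.0:
        raise ValueError("stretch must be positive")
    amp = p.P_opt * f_time
    sd = p.stretch_dependency()
    integral = f_xi_integral(lam, sd) if lam > p.lam_min else 0.0
    if amp == 0.0 or integral == 0.0:
        return 0.0, 0.0
    a, g = p.alpha, p.gamma
    ui = uniaxial_passive_invariants(lam, p.omega0)
    scale = (4.0 * a / g) * np.exp(a * (1.0 - ui.Itilde_p)) * amp
    phi = 1.0 + scale * integral
    if phi <= 0.0:
        raise ActivationInfeasibleError(f"phi = {phi} <= 0 for lam={lam}")
    omega = np.log(phi) / (a * lam**2)
    phi_prime = scale * (f_xi(lam, sd) - a * ui.Itilde_p_prime * integral)
    d_omega = (phi_prime / phi - 2.0 / lam * np.log(phi)) / (a * lam**2)
    return float(omega), float(d_omega)
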