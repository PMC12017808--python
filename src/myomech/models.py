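"""The four hyperelastic constitutive models for active skeletal muscle.

``ASE``
    Active-stress model: isochoric along/transverse fiber shear terms built
    on the Criscione-type invariants B1, B2, a fiber term whose energy is
    defined through the total Cauchy fiber stress (d psi_f / d lam_bar =
    sigma_ftot / lam_bar), an isochoric neo-Hookean companion for matrix
    compression stiffness, and a (K/2) (ln J)^2 volumetric part. Activation
    adds a stress contribution scaled by the amplitude ``a``.

``GASA`` / ``ASA`` / ``GASAM``
    Generalized active-strain family sharing the exponential two-invariant
    energy psi = gamma/4 [ (e^{alpha(Itilde-1)}-1)/alpha +
    (e^{beta(Jtilde-1)}-1)/beta + (det(C)^{-kappa}-1)/kappa ] (coupled
    volumetric term, no isochoric split). GASA activates through the first
    generalized invariant with the activation level held fixed in the stress;
    ASA uses the multiplicative elastic/active split of F; GASAM is GASA plus
    the deformation-dependence stress term S_omega_a with an explicit
    activation level.

All stresses are second Piola-Kirchhoff in kPa; ``incompressible=True``
evaluates the fully incompressible formulation (volumetric term dropped, the
constraint pressure to be supplied by the caller, e.g. through a
traction-free face in :mod:`myomech.response`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from . import kinematics as kin
from .activation import Activation, f_xi, f_xi_a, f_xi_p
from .activation_level import omega_asa, omega_gasa, omega_gasam
from .kinematics import FiberFrame, fiber_frame_e3
from .params import ASEParams, GenActiveStrainParams, fitted_params

__all__ = [
    "StressResult",
    "ASEModel",
    "GASAModel",
    "ASAModel",
    "GASAMModel",
    "get_model",
    "psi",
    "pk2_stress",
    "push_forward",
    "elasticity_tensor",
]

_I3 = np.eye(3)


@dataclass(frozen=True)
class StressResult:
    """Energy and stress measures of one constitutive evaluation.

    ``omega_a_used`` is the activation level entering the stress (the
    activation parameter for the generalized family; amplitude times time
    function for the active-stress model).
    """

    psi: float
    S: np.ndarray
    P: np.ndarray
    sigma: np.ndarray
    omega_a_used: float


def push_forward(S, F):
    """First Piola-Kirchhoff and Cauchy stress from S: P = F S,
    sigma = J^-1 P F^T."""
    F = np.asarray(F, dtype=float)
    P = F @ S
    J = float(np.linalg.det(F))
    sigma = (P @ F.T) / J
    return P, sigma


def _result(psi_val, S, F, omega_a):
    P, sigma = push_forward(S, F)
    return StressResult(psi=float(psi_val), S=S, P=P, sigma=sigma,
                        omega_a_used=float(omega_a))


class ASEModel:
    """Active-stress constitutive model."""

    name = "ASE"

    def __init__(self, params: ASEParams | None = None):
        self.params = params or fitted_params("ASE")

    @property
    def min_active_stretch(self) -> float:
        # below 0.4 * lam_opt the active parabola blend returns to zero
        return 0.4 * self.params.lam_opt

    def sigma_fiber_total(self, lam_bar: float, f_time: float) -> float:
        """Total Cauchy fiber stress: activation-scaled active part plus the
        tension-only passive part."""
        p = self.params
        sd = p.stretch_dependency()
        active = p.sigma_max * (lam_bar / p.lam_opt) * p.a * f_time * f_xi_a(lam_bar, p.lam_opt)
        passive = p.sigma_max * lam_bar * f_xi_p(lam_bar, sd)
        return active + passive

    def psi_fiber(self, lam_bar: float, f_time: float) -> float:
        """Fiber energy by quadrature of sigma_ftot / lam_bar from 1."""
        if lam_bar == 1.0:
            return 0.0
        val, _ = quad(lambda x: self.sigma_fiber_total(x, f_time) / x, 1.0, lam_bar,
                      epsabs=1e-10, epsrel=1e-10, limit=200)
        return float(val)

    def _iso_energy_and_stress(self, X: np.ndarray, frame: FiberFrame,
                               f_time: float, with_energy: bool):
        """Energy and 2 dPsi/dX of the isochoric energy evaluated on the
        (unit-determinant) tensor X."""
        p = self.params
        M = frame.M
        I1 = float(np.trace(X))
        I4 = float(np.tensordot(X, M))
        I5 = float(np.tensordot(X @ X, M))
        lam_bar = np.sqrt(I4)
        sqI4 = lam_bar
        theta = (I1 * I4 - I5) / (2.0 * sqI4)
        if theta < 1.0 - 1e-8:
            raise ValueError(f"acosh argument theta = {theta} < 1")
        A = kin._acosh_over_root(theta)
        sigma_f = self.sigma_fiber_total(lam_bar, f_time)

        dI1 = 0.5 * p.mu + 2.0 * p.G2 * A * (0.5 * sqI4)
        dI4 = (-2.0 * p.G1 * I5 / I4**3
               + 2.0 * p.G2 * A * (I1 / (4.0 * sqI4) + I5 / (4.0 * I4 * sqI4))
               + sigma_f / (2.0 * I4))
        dI5 = p.G1 / I4**2 + 2.0 * p.G2 * A * (-0.5 / sqI4)
        S2 = 2.0 * (dI1 * _I3 + dI4 * M + dI5 * (X @ M + M @ X))

        psi_val = 0.0
        if with_energy:
            B2 = np.arccosh(max(theta, 1.0))
            psi_val = (p.G1 * (I5 / I4**2 - 1.0) + p.G2 * B2**2
                       + self.psi_fiber(lam_bar, f_time)
                       + 0.5 * p.mu * (I1 - 3.0))
        return psi_val, S2

    def pk2(self, F, frame: FiberFrame | None = None,
            act: Activation | None = None, t: float = 0.0,
            incompressible: bool = False, with_energy: bool = True) -> StressResult:
        frame = frame or fiber_frame_e3()
        act = act or Activation.passive()
        f_time = act.level(t)
        p = self.params
        d = kin.deformation_state(F, frame)
        if incompressible:
            psi_val, S = self._iso_energy_and_stress(d.C, frame, f_time, with_energy)
        else:
            psi_val, Sbar = self._iso_energy_and_stress(d.Cbar, frame, f_time, with_energy)
            Cbar_inv = np.linalg.inv(d.Cbar)
            S_iso = d.J ** (-2.0 / 3.0) * (
                Sbar - (np.tensordot(Sbar, d.Cbar) / 3.0) * Cbar_inv)
            lnJ = np.log(d.J)
            S = S_iso + p.K * lnJ * np.linalg.inv(d.C)
            psi_val += 0.5 * p.K * lnJ**2
        return _result(psi_val, S, d.F, p.a * f_time)

    def psi(self, F, frame=None, act=None, t: float = 0.0,
            incompressible: bool = False) -> float:
        return self.pk2(F, frame, act, t, incompressible).psi


class _GenActiveStrainBase:
    """Shared machinery of the generalized active-strain family."""

    def __init__(self, params: GenActiveStrainParams | None = None):
        self.params = params or fitted_params("GASA")

    @property
    def min_active_stretch(self) -> float:
        return self.params.lam_min

    def omega_a(self, lam: float, f_time: float) -> float:
        raise NotImplementedError

    def active_stress_amplitude(self, lam: float, f_time: float) -> float:
        """Active nominal stress Pa(lam, t) entering the activation level."""
        return self.params.P_opt * f_time * f_xi(lam, self.params.stretch_dependency())

    def _invariants(self, C, frame, omega_a):
        L = kin.structural_mix(self.params.omega0, frame)
        detC = float(np.linalg.det(C))
        Cinv = np.linalg.inv(C)
        It = float(np.tensordot(C, L)) + omega_a * float(np.tensordot(C, frame.M))
        Jt = detC * float(np.tensordot(Cinv, L))
        return L, detC, Cinv, It, Jt

    def _energy(self, It, Jt, detC, incompressible):
        p = self.params
        val = (np.expm1(p.alpha * (It - 1.0)) / p.alpha
               + np.expm1(p.beta * (Jt - 1.0)) / p.beta)
        if not incompressible:
            val += (detC ** (-p.kappa) - 1.0) / p.kappa
        return 0.25 * p.gamma * val

    def _stress_frozen(self, C, frame, omega_a, incompressible):
        """2 dPsi/dC with the activation level held fixed."""
        p = self.params
        L, detC, Cinv, It, Jt = self._invariants(C, frame, omega_a)
        eI = np.exp(p.alpha * (It - 1.0))
        eJ = np.exp(p.beta * (Jt - 1.0))
        S = eI * (L + omega_a * frame.M) + eJ * (Jt * Cinv - detC * Cinv @ L @ Cinv)
        if not incompressible:
            S -= detC ** (-p.kappa) * Cinv
        return 0.5 * p.gamma * S, It, Jt, detC

    def psi(self, F, frame=None, act=None, t: float = 0.0,
            incompressible: bool = False) -> float:
        return self.pk2(F, frame, act, t, incompressible).psi


class GASAModel(_GenActiveStrainBase):
    """Generalized active-strain model with explicit (Lambert-W) activation
    level and the level held fixed in the stress derivation."""

    name = "GASA"

    def omega_a(self, lam: float, f_time: float) -> float:
        return omega_gasa(lam, self.active_stress_amplitude(lam, f_time), self.params)

    def pk2(self, F, frame=None, act=None, t: float = 0.0,
            incompressible: bool = False) -> StressResult:
        frame = frame or fiber_frame_e3()
        act = act or Activation.passive()
        d = kin.deformation_state(F, frame)
        wa = self.omega_a(d.lam, act.level(t))
        S, It, Jt, detC = self._stress_frozen(d.C, frame, wa, incompressible)
        return _result(self._energy(It, Jt, detC, incompressible), S, d.F, wa)


class GASAMModel(_GenActiveStrainBase):
    """GASA plus the S_omega_a stress term accounting for the deformation
    dependence of the activation level, which becomes fully explicit."""

    name = "GASAM"

    def omega_a(self, lam: float, f_time: float) -> float:
        return omega_gasam(lam, f_time, self.params)[0]

    def pk2(self, F, frame=None, act=None, t: float = 0.0,
            incompressible: bool = False) -> StressResult:
        frame = frame or fiber_frame_e3()
        act = act or Activation.passive()
        p = self.params
        d = kin.deformation_state(F, frame)
        wa, dwa = omega_gasam(d.lam, act.level(t), p)
        S, It, Jt, detC = self._stress_frozen(d.C, frame, wa, incompressible)
        S = S + 0.25 * p.gamma * np.exp(p.alpha * (It - 1.0)) * d.lam * dwa * frame.M
        return _result(self._energy(It, Jt, detC, incompressible), S, d.F, wa)


class ASAModel(_GenActiveStrainBase):
    """Active-strain model: multiplicative split F = Fe Fa, energy in the
    elastic invariants, implicit activation level, and the S2 term carrying
    its deformation dependence (finite-difference stretch derivative)."""

    name = "ASA"

    #: relative step of the central differences on the stretch argument
    fd_step = 1e-6

    def omega_a(self, lam: float, f_time: float) -> float:
        return omega_asa(lam, f_time, self.params)

    def _elastic_energy(self, C, frame, omega_a, incompressible,
                        with_stress: bool):
        p = self.params
        Fa_inv = np.linalg.inv(kin.active_stretch_tensor(omega_a, frame))
        Ce = Fa_inv @ C @ Fa_inv
        L, detC, Cinv, *_ = self._invariants(C, frame, 0.0)
        Ie = float(np.tensordot(Ce, L))
        FaLFa_inv = Fa_inv @ L @ Fa_inv
        Fa = kin.active_stretch_tensor(omega_a, frame)
        FaLFa = Fa @ L @ Fa
        Je = detC * float(np.tensordot(Cinv, FaLFa))
        psi_val = self._energy(Ie, Je, detC, incompressible)
        if not with_stress:
            return psi_val, None
        eI = np.exp(p.alpha * (Ie - 1.0))
        eJ = np.exp(p.beta * (Je - 1.0))
        S = eI * FaLFa_inv + eJ * (Je * Cinv - detC * Cinv @ FaLFa @ Cinv)
        if not incompressible:
            S -= detC ** (-p.kappa) * Cinv
        return psi_val, 0.5 * p.gamma * S

    def pk2(self, F, frame=None, act=None, t: float = 0.0,
            incompressible: bool = False) -> StressResult:
        frame = frame or fiber_frame_e3()
        act = act or Activation.passive()
        f_time = act.level(t)
        d = kin.deformation_state(F, frame)
        wa = self.omega_a(d.lam, f_time)
        psi_val, S1 = self._elastic_energy(d.C, frame, wa, incompressible, True)
        S = S1
        if f_time > 0.0:
            # S2 = 2 (dPsi_e/d omega_a) (d omega_a/d lam) M / (2 lam)
            h = self.fd_step * d.lam
            dwa = (self.omega_a(d.lam + h, f_time)
                   - self.omega_a(d.lam - h, f_time)) / (2.0 * h)
            hw = 1e-7
            psi_p, _ = self._elastic_energy(d.C, frame, wa + hw, incompressible, False)
            psi_m, _ = self._elastic_energy(d.C, frame, wa - hw, incompressible, False)
            dpsi_dwa = (psi_p - psi_m) / (2.0 * hw)
            S = S1 + dpsi_dwa * dwa / d.lam * frame.M
        return _result(psi_val, S, d.F, wa)


_MODEL_CLASSES = {"ASE": ASEModel, "GASA": GASAModel, "ASA": ASAModel,
                  "GASAM": GASAMModel}


def get_model(name: str, params=None):
    """Instantiate a model by name with the given (or fitted) parameters."""
    try:
        cls = _MODEL_CLASSES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected one of "
                         f"{tuple(_MODEL_CLASSES)}") from None
    return cls(params)


def psi(model, F, frame=None, act=None, t: float = 0.0,
        incompressible: bool = False) -> float:
    """Strain-energy density (kPa) of ``model`` (name or instance)."""
    if isinstance(model, str):
        model = get_model(model)
    return model.psi(F, frame, act, t, incompressible)


def pk2_stress(model, F, frame=None, act=None, t: float = 0.0,
               incompressible: bool = False) -> StressResult:
    """Second Piola-Kirchhoff stress (kPa) with push-forwards."""
    if isinstance(model, str):
        model = get_model(model)
    return model.pk2(F, frame, act, t, incompressible)


def _sqrtm_spd(C):
    w, V = np.linalg.eigh(C)
    return (V * np.sqrt(w)) @ V.T


_SYM_BASIS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def elasticity_tensor(model, F, frame=None, act=None, t: float = 0.0,
                      incompressible: bool = False, rel_step: float = 1e-6):
    """Fourth-order elasticity tensor by symmetric finite differences.

    Returns ``(CC, major_residual)`` where ``CC`` satisfies
    ``CC : dC / 2 ~= dS`` for symmetric perturbations ``dC`` and
    ``major_residual`` is the relative major-symmetry defect.
    """
    if isinstance(model, str):
        model = get_model(model)
    frame = frame or fiber_frame_e3()
    F = np.asarray(F, dtype=float)
    C = F.T @ F
    h = rel_step * float(np.linalg.norm(C))
    if h == 0.0:
        raise FloatingPointError("step size underflow in elasticity tensor")

    def stress_of_C(Cp):
        return model.pk2(_sqrtm_spd(Cp), frame, act, t, incompressible).S

    CC = np.zeros((3, 3, 3, 3))
    for (k, l) in _SYM_BASIS:
        dC = np.zeros((3, 3))
        dC[k, l] = dC[l, k] = h
        G = (stress_of_C(C + dC) - stress_of_C(C - dC)) / (2.0 * h)
        if k == l:
            CC[:, :, k, k] = 2.0 * G
        else:
            CC[:, :, k, l] = G
            CC[:, :, l, k] = G
    # enforce minor symmetry in the first pair (S is symmetric already)
    CC = 0.5 * (CC + CC.transpose(1, 0, 2, 3))
    major = CC.transpose(2, 3, 0, 1)
    denom = float(np.linalg.norm(CC))
    residual = float(np.linalg.norm(CC - major)) / denom if denom > 0 else 0.0
    CC = 0.5 * (CC + major)
    return CC, residual
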