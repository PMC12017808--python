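"""Kinematics of homogeneous deformations of transversely isotropic muscle tissue.

Conventions
-----------
All tensors are plain ``(3, 3)`` NumPy arrays in row-major order. The reference
fiber direction is a unit vector ``m``; the structural tensor ``M = m (x) m``
encodes transverse isotropy. The six homogeneous load cases used for material
characterization keep the fiber along the third coordinate axis:

======  =========================================================  ==========
mode    deformation gradient                                       magnitude
======  =========================================================  ==========
UTCAF   diag(1/sqrt(lam), 1/sqrt(lam), lam)                        stretch lam
UTCTF   diag(lam, 1/sqrt(lam), 1/sqrt(lam))                        stretch lam
SAF     identity + nu * e3 (x) e2 (simple shear along the fiber)   shear nu
PSAF    diag(1/lam, 1, lam)                                        stretch lam
PSTF    diag(lam, 1, 1/lam)                                        stretch lam
PSTIF   diag(lam, 1/lam, 1)                                        stretch lam
======  =========================================================  ==========

All six are isochoric (det F = 1), as required for the incompressible
analytic stress responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LOAD_CASES",
    "FiberFrame",
    "DeformationState",
    "LoadCaseSpec",
    "InvariantSet",
    "GeneralizedInvariants",
    "ActiveDecomposition",
    "build_fiber_frame",
    "fiber_frame_e3",
    "loadcase_deformation",
    "deformation_state",
    "basic_invariants",
    "generalized_invariants",
    "active_decomposition",
]

LOAD_CASES = ("UTCAF", "UTCTF", "SAF", "PSAF", "PSTF", "PSTIF")

_I3 = np.eye(3)

# |theta - 1| below this uses the analytic limit of acosh(theta)/sqrt(theta^2-1)
THETA_LIMIT_TOL = 1e-9


@dataclass(frozen=True)
class FiberFrame:
    """Reference fiber direction ``m`` and structural tensor ``M = m (x) m``."""

    m: np.ndarray
    M: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3,):
            raise ValueError("fiber direction must be a 3-vector")
        norm = float(np.linalg.norm(m))
        if norm == 0.0 or not np.isfinite(norm):
            raise ValueError("fiber direction must be a nonzero finite vector")
        m = m / norm
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "M", np.outer(m, m))


def build_fiber_frame(m) -> FiberFrame:
    """Normalize ``m`` and build its structural tensor."""
    return FiberFrame(np.asarray(m, dtype=float))


def fiber_frame_e3() -> FiberFrame:
    """The default frame with fibers along the third coordinate axis."""
    return FiberFrame(np.array([0.0, 0.0, 1.0]))


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient with derived strain measures.

    ``C = F^T F`` is the right Cauchy-Green tensor, ``Cbar = J^(-2/3) C`` its
    isochoric part, ``lam`` the fiber stretch sqrt(C : M) and ``lam_bar`` its
    modified counterpart.
    """

    F: np.ndarray
    J: float
    C: np.ndarray
    Cbar: np.ndarray
    lam: float
    lam_bar: float


def deformation_state(F, frame: FiberFrame) -> DeformationState:
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError("F must be a 3x3 tensor")
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise ValueError(f"det F = {J} must be positive")
    C = F.T @ F
    Cbar = J ** (-2.0 / 3.0) * C
    I4 = float(np.tensordot(C, frame.M))
    I4bar = float(np.tensordot(Cbar, frame.M))
    return DeformationState(F=F, J=J, C=C, Cbar=Cbar,
                            lam=np.sqrt(I4), lam_bar=np.sqrt(I4bar))


@dataclass(frozen=True)
class LoadCaseSpec:
    """Homogeneous load case: a mode tag plus its stretch/shear magnitude."""

    mode: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.mode not in LOAD_CASES:
            raise ValueError(f"unknown load case {self.mode!r}; expected one of {LOAD_CASES}")
        if self.mode != "SAF" and self.magnitude <= 0.0:
            raise ValueError(f"stretch magnitude must be positive, got {self.magnitude}")


def loadcase_deformation(spec: LoadCaseSpec | None = None, *,
                         mode: str | None = None,
                         magnitude: float | None = None) -> DeformationState:
    """Deformation gradient of a tabulated load case (fiber along e3, det F = 1)."""
    if spec is None:
        spec = LoadCaseSpec(mode, magnitude)
    lam = spec.magnitude
    if spec.mode == "UTCAF":
        F = np.diag([lam ** -0.5, lam ** -0.5, lam])
    elif spec.mode == "UTCTF":
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    elif spec.mode == "SAF":
        F = _I3.copy()
        F[2, 1] = lam
    elif spec.mode == "PSAF":
        F = np.diag([1.0 / lam, 1.0, lam])
    elif spec.mode == "PSTF":
        F = np.diag([lam, 1.0, 1.0 / lam])
    else:  # PSTIF
        F = np.diag([lam, 1.0 / lam, 1.0])
    return deformation_state(F, fiber_frame_e3())


@dataclass(frozen=True)
class InvariantSet:
    """Isochoric invariants and the along/transverse shear strain measures.

    ``B1 = sqrt(I5/I4^2 - 1)`` quantifies shear along the fiber and
    ``B2 = acosh(theta)`` with ``theta = (I1*I4 - I5) / (2*sqrt(I4))``
    quantifies shear/asymmetry transverse to it; both vanish in the reference
    state and for transversely symmetric stretches.
    """

    I1bar: float
    I4bar: float
    I5bar: float
    B1: float
    B2: float
    theta: float


def _acosh_over_root(theta: float) -> float:
    """acosh(theta)/sqrt(theta^2 - 1) with its analytic limit 1 at theta = 1."""
    eps = theta - 1.0
    if eps < THETA_LIMIT_TOL:
        # series about theta = 1; eps may be a small negative round-off
        return 1.0 - eps / 3.0
    return float(np.arccosh(theta) / np.sqrt(theta * theta - 1.0))


def basic_invariants(d: DeformationState, frame: FiberFrame) -> InvariantSet:
    """Isochoric invariants I1bar, I4bar, I5bar and shear measures B1, B2."""
    M = frame.M
    Cb = d.Cbar
    I1 = float(np.trace(Cb))
    I4 = float(np.tensordot(Cb, M))
    I5 = float(np.tensordot(Cb @ Cb, M))
    if I4 <= 0.0:
        raise ValueError("I4bar must be positive")
    theta = (I1 * I4 - I5) / (2.0 * np.sqrt(I4))
    if theta < 1.0 - 1e-8:
        raise ValueError(f"acosh argument theta = {theta} < 1: inconsistent deformation input")
    b1sq = I5 / I4**2 - 1.0
    B1 = float(np.sqrt(max(b1sq, 0.0)))
    B2 = float(np.arccosh(max(theta, 1.0)))
    return InvariantSet(I1bar=I1, I4bar=I4, I5bar=I5, B1=B1, B2=B2, theta=float(theta))


@dataclass(frozen=True)
class GeneralizedInvariants:
    """Generalized invariants mixing matrix and fiber contributions.

    ``Ltilde = (omega0/3) I + (1 - omega0) M`` weights the isotropic matrix
    against the fibers. The first invariant carries the activation:
    ``Itilde = C : Ltilde + omega_a * (C : M)``; the second is
    ``Jtilde = cof(C) : Ltilde``.
    """

    Ltilde: np.ndarray
    Itilde: float
    Jtilde: float
    Itilde_p: float
    Itilde_a: float


def structural_mix(omega0: float, frame: FiberFrame) -> np.ndarray:
    """The weighted structural tensor Ltilde with unit trace."""
    if not 0.0 < omega0 <= 1.0:
        raise ValueError("omega0 must lie in (0, 1]")
    return (omega0 / 3.0) * _I3 + (1.0 - omega0) * frame.M


def generalized_invariants(C, omega0: float, omega_a: float,
                           frame: FiberFrame) -> GeneralizedInvariants:
    C = np.asarray(C, dtype=float)
    if not 0.0 <= omega_a < 1.0:
        raise ValueError("omega_a must lie in [0, 1)")
    L = structural_mix(omega0, frame)
    Ip = float(np.tensordot(C, L))
    Ia = omega_a * float(np.tensordot(C, frame.M))
    cofC = float(np.linalg.det(C)) * np.linalg.inv(C).T
    Jt = float(np.tensordot(cofC, L))
    return GeneralizedInvariants(Ltilde=L, Itilde=Ip + Ia, Jtilde=Jt,
                                 Itilde_p=Ip, Itilde_a=Ia)


@dataclass(frozen=True)
class ActiveDecomposition:
    """Multiplicative split F = Fe Fa with a volume-preserving active part.

    ``Fa = (1 - omega_a) M + (1 - omega_a)^(-1/2) (I - M)`` contracts along the
    fiber and expands transversally so that det Fa = 1 exactly.
    """

    omega_a: float
    Fa: np.ndarray
    Fe: np.ndarray
    Ce: np.ndarray
    Itilde_e: float
    Jtilde_e: float


def active_stretch_tensor(omega_a: float, frame: FiberFrame) -> np.ndarray:
    if not 0.0 <= omega_a < 1.0:
        raise ValueError(f"activation parameter omega_a = {omega_a} outside [0, 1)")
    one = 1.0 - omega_a
    return one * frame.M + one ** -0.5 * (_I3 - frame.M)


def active_decomposition(d: DeformationState, omega_a: float,
                         frame: FiberFrame, omega0: float = 1.0) -> ActiveDecomposition:
    """Split ``d.F`` into elastic and active parts and evaluate the elastic
    generalized invariants (with matrix weighting ``omega0``)."""
    Fa = active_stretch_tensor(omega_a, frame)
    Fa_inv = np.linalg.inv(Fa)
    Fe = d.F @ Fa_inv
    Ce = Fe.T @ Fe
    gi = generalized_invariants(Ce, omega0, 0.0, frame)
    return ActiveDecomposition(omega_a=omega_a, Fa=Fa, Fe=Fe, Ce=Ce,
                               Itilde_e=gi.Itilde_p, Jtilde_e=gi.Jtilde)
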