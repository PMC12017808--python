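"""Homogeneous load-case stress responses.

For the fully incompressible formulations the constraint pressure is
eliminated through the traction-free face of each load case: with
``P = P_dev - p F^{-T}`` the pressure follows from the vanishing nominal
stress on the free face, and the loaded component is reported:

======  ===================  ===================
mode    reported component   traction-free face
======  ===================  ===================
UTCAF   P33                  P11 = 0
UTCTF   P11                  P22 = 0
PSAF    P33                  P11 = 0
PSTF    P11                  P33 = 0
PSTIF   P11                  P22 = 0
SAF     P32                  (pressure-free)
======  ===================  ===================

The nearly incompressible formulations are evaluated by letting the free
lateral stretches equilibrate (vanishing nominal stress on the free faces)
with the penalized compressible material, mimicking the single-element
numerical experiments used to verify the analytic responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .activation import Activation
from .kinematics import fiber_frame_e3, loadcase_deformation
from .models import get_model

__all__ = [
    "ResponseCurve",
    "nominal_response",
    "nearly_incompressible_response",
    "response_sweep",
    "stress_free_stretch",
    "isometric_tetanic_stress",
    "uniaxial_fiber_analytic",
    "NoRootError",
]

# (reported diagonal index, traction-free diagonal index) per stretch mode
_FACES = {"UTCAF": (2, 0), "UTCTF": (0, 1), "PSAF": (2, 0),
          "PSTF": (0, 2), "PSTIF": (0, 1)}


class NoRootError(RuntimeError):
    """Root search failed to bracket a sign change."""


def _as_model(model, params=None):
    return get_model(model, params) if isinstance(model, str) else model


def nominal_response(model, mode: str, x: float,
                     act: Activation | None = None, t: float = 0.0,
                     params=None) -> float:
    """Fully incompressible nominal stress (kPa) of one load case sample."""
    model = _as_model(model, params)
    act = act or Activation.passive()
    state = loadcase_deformation(mode=mode, magnitude=x)
    res = model.pk2(state.F, fiber_frame_e3(), act, t, incompressible=True)
    P_dev = state.F @ res.S
    if mode == "SAF":
        return float(P_dev[2, 1])
    j, i = _FACES[mode]
    FinvT = np.linalg.inv(state.F).T
    p = P_dev[i, i] / FinvT[i, i]
    return float(P_dev[j, j] - p * FinvT[j, j])


def _nearly_F(mode: str, x: float, free):
    if mode == "UTCAF":
        return np.diag([free[0], free[0], x])
    if mode == "UTCTF":
        # only the traction-free direction 2 relaxes; direction 3 is guided
        # at its tabulated isochoric value, matching the incompressible setup
        return np.diag([x, free[0], x ** -0.5])
    if mode == "PSAF":
        return np.diag([free[0], 1.0, x])
    if mode == "PSTF":
        return np.diag([x, 1.0, free[0]])
    if mode == "PSTIF":
        return np.diag([x, free[0], 1.0])
    raise ValueError(mode)


def _bracketed_root(f, x0: float, label: str) -> float:
    """Bracket a sign change around the initial guess and solve by brentq."""
    a, b = 0.995 * x0, 1.005 * x0
    fa, fb = f(a), f(b)
    for _ in range(200):
        if fa * fb <= 0.0:
            return float(brentq(f, a, b, xtol=1e-13, rtol=8.9e-16))
        a *= 0.98
        b *= 1.02
        fa, fb = f(a), f(b)
    raise NoRootError(f"no lateral equilibrium bracket for {label}")


def nearly_incompressible_response(model, mode: str, x: float,
                                   act: Activation | None = None, t: float = 0.0,
                                   params=None) -> float:
    """Nominal stress of the penalized compressible formulation with the
    traction-free faces equilibrated."""
    model = _as_model(model, params)
    act = act or Activation.passive()
    frame = fiber_frame_e3()

    if mode == "SAF":
        F = np.eye(3)
        F[2, 1] = x
        P = F @ model.pk2(F, frame, act, t).S
        return float(P[2, 1])

    j, i = _FACES[mode]
    iso = loadcase_deformation(mode=mode, magnitude=x).F

    def nominal(F):
        return F @ model.pk2(F, frame, act, t).S

    free = _bracketed_root(
        lambda s: nominal(_nearly_F(mode, x, (s,)))[i, i],
        iso[i, i], f"{mode} at x={x}")
    F = _nearly_F(mode, x, (free,))
    return float(nominal(F)[j, j])


@dataclass(frozen=True)
class ResponseCurve:
    """A nominal stress-stretch (or stress-shear) curve for one load case."""

    loadcase: str
    state: str          # "active" | "passive"
    model: str
    xs: np.ndarray
    Ps: np.ndarray      # kPa

    def __post_init__(self) -> None:
        if np.any(np.diff(self.xs) <= 0):
            raise ValueError("curve grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"loadcase": self.loadcase, "state": self.state,
                             "model": self.model, "x": self.xs, "P_kPa": self.Ps})


def response_sweep(model, mode: str, grid,
                   act: Activation | None = None, t: float = 0.0,
                   params=None, nearly_incompressible: bool = False) -> ResponseCurve:
    """Vectorized nominal response over a grid of stretches/shear amounts."""
    model = _as_model(model, params)
    act = act or Activation.passive()
    grid = np.asarray(grid, dtype=float)
    fn = nearly_incompressible_response if nearly_incompressible else nominal_response
    Ps = np.array([fn(model, mode, float(x), act, t) for x in grid])
    state = "passive" if act.level(t) == 0.0 else "active"
    return ResponseCurve(loadcase=mode, state=state, model=model.name,
                         xs=grid, Ps=Ps)


def uniaxial_fiber_analytic(params, lam: float, f_time: float = 1.0) -> float:
    """Closed-form incompressible uniaxial along-fiber nominal stress of the
    generalized active-strain family: passive response plus the active
    nominal stress.

    All three family members share this response by construction of their
    activation levels, so it is defined even where an activation solve would
    leave the admissible range.
    """
    from .activation import f_xi
    from .activation_level import uniaxial_passive_invariants

    ui = uniaxial_passive_invariants(lam, params.omega0)
    Ppas = 0.25 * params.gamma * (
        np.exp(params.alpha * (ui.Itilde_p - 1.0)) * ui.Itilde_p_prime
        + np.exp(params.beta * (ui.Jtilde_p - 1.0)) * ui.Jtilde_p_prime)
    Pa = params.P_opt * f_time * f_xi(lam, params.stretch_dependency())
    return float(Ppas + Pa)


def stress_free_stretch(model, act: Activation | None = None, t: float = 0.0,
                        params=None, lo: float | None = None,
                        xtol: float = 1e-8) -> float:
    """Fiber stretch at which the active uniaxial (UTCAF) nominal stress
    vanishes — the material-point analogue of a free contraction."""
    model = _as_model(model, params)
    act = act if act is not None else Activation.tetanic()
    if act.level(t) == 0.0:
        return 1.0
    if lo is None:
        lo = max(model.min_active_stretch + 1e-3, 0.45)
    hi = 1.0 - 1e-9
    f = lambda lam: nominal_response(model, "UTCAF", lam, act, t)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0.0:
        raise NoRootError(f"no sign change on [{lo}, {hi}]: f(lo)={flo:.4g}, f(hi)={fhi:.4g}")
    return float(brentq(f, lo, hi, xtol=xtol))


def isometric_tetanic_stress(model, act: Activation | None = None,
                             t: float = 0.0, params=None) -> float:
    """Fiber-direction nominal stress at held reference length (UTCAF,
    lam = 1) under the given activation (tetanic by default)."""
    model = _as_model(model, params)
    act = act if act is not None else Activation.tetanic()
    return nominal_response(model, "UTCAF", 1.0, act, t)
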