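"""Scalar activation ingredients: force-stretch dependencies, time functions,
and the active nominal stress.

Two families of force-stretch relations are implemented. The generalized
active-strain family uses a skewable bump ``f_xi`` that is exactly zero below
the minimal active stretch ``lam_min`` and peaks at 1 for ``lam = lam_opt``.
The active-stress model uses the classical three-branch parabola blend
``f_xi_a`` (continuously differentiable, symmetric about its optimum, with an
implied minimal active stretch of 0.4 * lam_opt).

Time activation is either a tanh ramp (fused tetanus without twitch ripple) or
a superposed motor-unit twitch train normalized so the fused-tetanus plateau
is 1. Spatiotemporal activation enters as a per-evaluation scaling factor
``s`` multiplying the time function.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TanhActivation",
    "TwitchTrainParams",
    "StretchDependencyParams",
    "Activation",
    "f_tanh",
    "f_twitch",
    "f_xi",
    "f_xi_integral",
    "f_xi_a",
    "f_xi_p",
    "active_nominal_stress",
    "read_schedule",
]


@dataclass(frozen=True)
class TanhActivation:
    """tanh ramp: s * tanh(c (t - t0)) for t >= t0, clamped to 0 before t0."""

    c: float = 34.4017
    t0: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.c <= 0.0:
            raise ValueError("rise rate c must be positive")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("scaling factor s must lie in [0, 1]")


def f_tanh(t, p: TanhActivation):
    """Monotone tanh activation ramp, zero before the start time."""
    t = np.asarray(t, dtype=float)
    out = p.s * np.tanh(p.c * (t - p.t0))
    out = np.where(t >= p.t0, out, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TwitchTrainParams:
    """Motor-unit twitch-train description.

    Each of the ``n_units`` motor-unit types fires a single twitch of shape
    ``(dt/Ti) exp(1 - dt/Ti)`` (peak force ``Fi`` reached at the contraction
    time ``Ti``) every interstimulus interval ``Ii``; trains are superposed
    linearly and weighted by the fractions ``rho``. ``Na`` is the number of
    activated units per unit reference cross-section area (mm^-2).
    """

    rho: tuple = (0.05, 0.29, 0.66)
    F: tuple = (2.5e-3, 4.4e-3, 76.8e-3)   # N
    T: tuple = (0.02, 0.011, 0.011)        # s
    I: tuple = (0.004, 0.004, 0.004)       # s
    Na: float = 0.4619                     # mm^-2
    duration: float = 0.15                 # s

    def __post_init__(self) -> None:
        n = len(self.rho)
        if n == 0:
            raise ValueError("at least one motor-unit type is required")
        if not (len(self.F) == len(self.T) == len(self.I) == n):
            raise ValueError("rho, F, T, I must share one length")
        if abs(sum(self.rho) - 1.0) > 1e-9:
            raise ValueError("motor-unit fractions must sum to 1")
        if min(self.F) <= 0 or min(self.T) <= 0 or min(self.I) <= 0:
            raise ValueError("F, T, I must all be positive")

    @property
    def n_units(self) -> int:
        return len(self.rho)

    def plateau_force(self) -> float:
        """Long-time mean of sum_i rho_i * F_i(t) (N).

        For twitches fired every ``Ii`` the plateau mean is the single-twitch
        integral divided by ``Ii``: rho_i * F_i * e * T_i / I_i.
        """
        return float(sum(r * f * np.e * ti / ii
                         for r, f, ti, ii in zip(self.rho, self.F, self.T, self.I)))


def f_twitch(t, p: TwitchTrainParams):
    """Normalized superposed twitch train: fused-tetanus plateau equals 1."""
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    total = np.zeros_like(t)
    for r, fi, ti, ii in zip(p.rho, p.F, p.T, p.I):
        n_fire = int(np.floor(t.max() / ii)) + 1
        fire_times = np.arange(n_fire) * ii
        dt = t[:, None] - fire_times[None, :]
        tw = np.where(dt > 0.0, (dt / ti) * np.exp(1.0 - dt / ti), 0.0)
        total += r * fi * tw.sum(axis=1)
    out = total / p.plateau_force()
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class StretchDependencyParams:
    """Parameters of the force-stretch dependencies.

    ``lam_opt``/``lam_min`` parameterize the generalized-family bump ``f_xi``;
    ``lam_opt_a`` the active-stress parabola blend; ``D1``, ``D2``,
    ``lam_star`` the exponential-then-linear passive fiber dependency, with
    ``D3``, ``D4`` derived so the linear branch is C1-continuous.
    """

    lam_opt: float = 1.1806
    lam_min: float = 0.5680
    lam_opt_a: float = 1.2264
    lam_star: float = 1.4
    D1: float = 3.6055
    D2: float = 4.4883

    def __post_init__(self) -> None:
        if not 0.0 < self.lam_min < self.lam_opt:
            raise ValueError("require 0 < lam_min < lam_opt")
        if self.lam_star <= 1.0:
            raise ValueError("lam_star must exceed 1")

    @property
    def D3(self) -> float:
        return self.D1 * self.D2 * np.exp(self.D2 * (self.lam_star - 1.0))

    @property
    def D4(self) -> float:
        return self.D1 * (np.exp(self.D2 * (self.lam_star - 1.0)) - 1.0) - self.lam_star * self.D3


def f_xi(lam, p: StretchDependencyParams):
    """Active force-stretch bump: 0 below lam_min, 1 at lam_opt."""
    lam = np.asarray(lam, dtype=float)
    lo, lopt = p.lam_min, p.lam_opt
    pref = (lam - lo) / (lopt - lo)
    expo = (2.0 * lo - lam - lopt) * (lam - lopt) / (2.0 * (lo - lopt) ** 2)
    out = np.where(lam > lo, pref * np.exp(expo), 0.0)
    return float(out) if out.ndim == 0 else out


def f_xi_integral(lam: float, p: StretchDependencyParams) -> float:
    """Integral of f_xi from lam_min to lam (0 for lam <= lam_min)."""
    from scipy.integrate import quad

    if lam <= p.lam_min:
        return 0.0
    val, _ = quad(lambda x: f_xi(x, p), p.lam_min, lam, epsabs=1e-10, epsrel=1e-10)
    return float(val)


def f_xi_a(lam_bar, lam_opt_a: float):
    """Three-branch active dependency of the active-stress model (C1, max 1)."""
    x = np.asarray(lam_bar, dtype=float) / lam_opt_a
    out = np.where(
        x <= 0.6, 9.0 * (x - 0.4) ** 2,
        np.where(x < 1.4, 1.0 - 4.0 * (1.0 - x) ** 2, 9.0 * (x - 1.6) ** 2),
    )
    return float(out) if out.ndim == 0 else out


def f_xi_p(lam_bar, p: StretchDependencyParams):
    """Passive fiber dependency: zero in compression, exponential then linear."""
    lb = np.asarray(lam_bar, dtype=float)
    expo = p.D1 * (np.exp(p.D2 * (lb - 1.0)) - 1.0)
    lin = p.D3 * lb + p.D4
    out = np.where(lb <= 1.0, 0.0, np.where(lb < p.lam_star, expo, lin))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Activation:
    """Time activation state: a time-function kind plus a scaling factor.

    ``level(t)`` returns the dimensionless activation value in [0, 1]:
    the time function evaluated at ``t`` times the spatial scaling ``s``.
    ``kind`` is one of ``"passive"``, ``"tetanic"``, ``"tanh"``, ``"twitch"``
    or ``"schedule"``.
    """

    kind: str = "tetanic"
    s: float = 1.0
    tanh_params: TanhActivation | None = None
    twitch_params: TwitchTrainParams | None = None
    schedule: tuple | None = None  # (times, values) step function

    @staticmethod
    def passive() -> "Activation":
        return Activation(kind="passive", s=0.0)

    @staticmethod
    def tetanic(s: float = 1.0) -> "Activation":
        return Activation(kind="tetanic", s=s)

    @staticmethod
    def tanh_ramp(c: float = 34.4017, t0: float = 0.0, s: float = 1.0) -> "Activation":
        return Activation(kind="tanh", s=s, tanh_params=TanhActivation(c=c, t0=t0, s=1.0))

    @staticmethod
    def twitch_train(params: TwitchTrainParams | None = None, s: float = 1.0) -> "Activation":
        return Activation(kind="twitch", s=s,
                          twitch_params=params or TwitchTrainParams())

    @staticmethod
    def from_schedule(times, values) -> "Activation":
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("schedule needs matching 1-d time and value arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("schedule times must be strictly increasing")
        return Activation(kind="schedule", s=1.0,
                          schedule=(tuple(times), tuple(values)))

    def scaled(self, s: float) -> "Activation":
        return replace(self, s=s)

    def level(self, t: float = 0.0) -> float:
        if self.kind == "passive":
            return 0.0
        if self.kind == "tetanic":
            return self.s
        if self.kind == "tanh":
            return self.s * f_tanh(t, self.tanh_params)
        if self.kind == "twitch":
            return self.s * float(np.clip(f_twitch(float(t), self.twitch_params), 0.0, 1.0))
        if self.kind == "schedule":
            times, values = self.schedule
            idx = int(np.searchsorted(times, t, side="right")) - 1
            return self.s * (0.0 if idx < 0 else float(values[idx]))
        raise ValueError(f"unknown activation kind {self.kind!r}")


def read_schedule(path) -> Activation:
    """Read a two-column (time [s], scaling factor) table; step interpolation."""
    data = np.loadtxt(Path(path), ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"schedule file {path} must have exactly two columns")
    return Activation.from_schedule(data[:, 0], data[:, 1])


def active_nominal_stress(lam: float, t: float, P_opt: float,
                          activation: Activation,
                          p: StretchDependencyParams) -> float:
    """Active nominal stress Pa = P_opt * f_time(t) * f_xi(lam) * fv (fv = 1).

    ``P_opt`` is the peak active nominal stress in kPa; the force-velocity
    dependency is the constant 1.
    """
    if P_opt < 0.0:
        raise ValueError("peak active nominal stress must be nonnegative")
    if lam <= 0.0:
        raise ValueError("stretch must be positive")
    return P_opt * activation.level(t) * f_xi(lam, p) * 1.0
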