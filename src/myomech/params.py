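"""Material parameter sets for the four constitutive models.

Units are kPa for stresses and moduli, seconds for times; stretches and the
exponents are dimensionless. The shipped ``fitted_params`` fixture carries the
parameter values identified from the multi-load-case stress-stretch fit
(available under the name ``"table5"`` in the CLI and file loaders).

Serialization uses flat key-value YAML with the field names below plus a
``model`` key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .activation import StretchDependencyParams, TwitchTrainParams

__all__ = [
    "ASEParams",
    "GenActiveStrainParams",
    "MODEL_NAMES",
    "fitted_params",
    "load_params",
    "save_params",
]

MODEL_NAMES = ("ASE", "GASA", "ASA", "GASAM")


@dataclass(frozen=True)
class ASEParams:
    """Active-stress model parameters.

    ``G1``/``G2`` are the along/transverse fiber shear moduli, ``D1``/``D2``
    shape the exponential passive fiber tension and ``lam_star`` the onset of
    its linear continuation, ``sigma_max`` is the maximal isometric fiber
    stress, ``a`` the activation amplitude, ``K`` the bulk modulus, and ``mu``
    the shear modulus of the isochoric neo-Hookean companion term that
    supplies compressive matrix stiffness.
    """

    G1: float = 0.1
    G2: float = 0.05
    D1: float = 3.6055
    D2: float = 4.4883
    K: float = 10000.0
    lam_opt: float = 1.2264
    lam_star: float = 1.4
    sigma_max: float = 1.1450
    a: float = 69.5471
    c: float = 34.4017
    t0: float = 0.0
    mu: float = 10.0

    def __post_init__(self) -> None:
        for name in ("G1", "G2", "K", "sigma_max", "mu"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")
        if self.lam_star <= 1.0:
            raise ValueError("lam_star must exceed 1")
        if self.a < 0.0:
            raise ValueError("activation amplitude a must be nonnegative")

    def stretch_dependency(self) -> StretchDependencyParams:
        return StretchDependencyParams(lam_opt_a=self.lam_opt, lam_star=self.lam_star,
                                       D1=self.D1, D2=self.D2)


@dataclass(frozen=True)
class GenActiveStrainParams:
    """Parameters shared by the generalized active-strain family (GASA, ASA,
    GASAM).

    ``alpha``/``beta`` control along/transverse fiber nonlinearity, ``gamma``
    is the stiffness scale, ``omega0`` the isotropic-matrix weighting and
    ``kappa`` the incompressibility exponent of the coupled volumetric term.
    ``P_opt`` is the peak (fused-tetanus) active nominal stress; the optional
    motor-unit twitch train provides the millisecond-scale time dependence and
    carries ``Na``, the number of activated units per reference area.
    """

    alpha: float = 2.3796
    beta: float = 0.5161
    gamma: float = 27.1072
    omega0: float = 0.6388
    kappa: float = 1000.0
    lam_opt: float = 1.1806
    lam_min: float = 0.5680
    P_opt: float = 64.6809
    c: float = 34.4017
    t0: float = 0.0
    twitch: TwitchTrainParams | None = field(default_factory=TwitchTrainParams)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "kappa"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.omega0 < 1.0:
            raise ValueError("omega0 must lie in (0, 1)")
        if not 0.0 < self.lam_min < self.lam_opt:
            raise ValueError("require 0 < lam_min < lam_opt")
        if self.P_opt < 0.0:
            raise ValueError("P_opt must be nonnegative")

    @property
    def omega_p(self) -> float:
        return 1.0 - self.omega0

    def stretch_dependency(self) -> StretchDependencyParams:
        return StretchDependencyParams(lam_opt=self.lam_opt, lam_min=self.lam_min)


def fitted_params(model: str):
    """The fitted parameter set for ``model`` (fixture name ``"table5"``)."""
    model = model.upper()
    if model == "ASE":
        return ASEParams()
    if model in ("GASA", "ASA", "GASAM"):
        return GenActiveStrainParams()
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def _to_flat_dict(params) -> dict:
    d = {}
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        if isinstance(v, TwitchTrainParams):
            d["twitch"] = {k: list(val) if isinstance(val, tuple) else val
                           for k, val in dataclasses.asdict(v).items()}
        elif v is not None:
            d[f.name] = float(v)
    return d


def save_params(params, model: str, path) -> None:
    doc = {"model": model.upper()}
    doc.update(_to_flat_dict(params))
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(path):
    """Load a (model, params) pair from a flat key-value YAML file."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "model" not in doc:
        raise ValueError(f"parameter file {path} must contain a 'model' key")
    model = str(doc.pop("model")).upper()
    if model == "ASE":
        return model, ASEParams(**doc)
    if model in ("GASA", "ASA", "GASAM"):
        tw = doc.pop("twitch", None)
        twitch = TwitchTrainParams(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in tw.items()}) if tw else None
        return model, GenActiveStrainParams(twitch=twitch, **doc)
    raise ValueError(f"unknown model {model!r} in {path}")
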