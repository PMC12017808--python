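"""Synthetic stress-stretch curve generator.

Produces pseudo-experimental curves with the structure of the
multi-load-case characterization dataset: passive curves for the six
homogeneous load cases plus an active tetanic uniaxial along-fiber curve,
computed from a chosen model and parameter set and perturbed by
multiplicative Gaussian noise (relative noise keeps all modes informative
despite stress magnitudes differing across modes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import Activation
from .curves import ExperimentalCurve, read_curves, write_curves
from .params import fitted_params
from .response import response_sweep
from .models import get_model

__all__ = ["SyntheticSpec", "DEFAULT_GRIDS", "generate_curves",
           "read_curves", "write_curves"]

#: default (lo, hi, n) grids per mode; the passive along-fiber grid extends
#: beyond the linear-branch onset so all passive parameters are informative,
#: and the active grid brackets the force-length optimum.
DEFAULT_GRIDS = {
    "UTCAF": (0.7, 1.5, 20),
    "UTCTF": (0.7, 1.3, 20),
    "SAF": (0.02, 0.4, 20),
    "PSAF": (1.0, 1.3, 16),
    "PSTF": (1.0, 1.3, 16),
    "PSTIF": (1.0, 1.3, 16),
    "UTCAF_active": (0.6, 1.3, 25),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    model: str = "GASAM"
    params: object = None
    modes: tuple = ("UTCAF", "UTCTF", "SAF", "PSAF", "PSTF", "PSTIF")
    grids: dict = field(default_factory=dict)
    noise_sd_rel: float = 0.0
    seed: int = 0
    include_active: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd_rel < 0.0:
            raise ValueError("noise_sd_rel must be nonnegative")

    def grid(self, key: str) -> np.ndarray:
        lo, hi, n = {**DEFAULT_GRIDS, **self.grids}[key]
        return np.linspace(lo, hi, int(n))


def generate_curves(spec: SyntheticSpec) -> list[ExperimentalCurve]:
    """Model responses on the grids with multiplicative noise (1 + eps),
    eps ~ Normal(0, noise_sd_rel); reproducible under a fixed seed."""
    model = get_model(spec.model, spec.params or fitted_params(spec.model))
    rng = np.random.default_rng(spec.seed)
    curves = []

    def noisy(P):
        if spec.noise_sd_rel == 0.0:
            return P
        return P * (1.0 + rng.normal(0.0, spec.noise_sd_rel, size=P.shape))

    for mode in spec.modes:
        sweep = response_sweep(model, mode, spec.grid(mode), Activation.passive())
        curves.append(ExperimentalCurve(loadcase=mode, state="passive",
                                        x=sweep.xs, P=noisy(sweep.Ps),
                                        source=f"synthetic:{spec.model}"))
    if spec.include_active:
        sweep = response_sweep(model, "UTCAF", spec.grid("UTCAF_active"),
                               Activation.tetanic())
        curves.append(ExperimentalCurve(loadcase="UTCAF", state="active",
                                        x=sweep.xs, P=noisy(sweep.Ps),
                                        source=f"synthetic:{spec.model}"))
    return curves
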