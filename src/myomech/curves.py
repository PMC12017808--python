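"""Load-case-tagged stress-stretch curves and their tabular file format.

Curves are exchanged as tab-separated text with the columns
``loadcase  state  x  P_kPa`` (plus an optional ``source`` provenance tag):
``x`` is the stretch (or the shear amount for SAF) and ``P_kPa`` the nominal
stress in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import LOAD_CASES

__all__ = ["ExperimentalCurve", "read_curves", "write_curves"]

_COLUMNS = ("loadcase", "state", "x", "P_kPa")


@dataclass(frozen=True)
class ExperimentalCurve:
    """Samples of one load case in one muscle state."""

    loadcase: str
    state: str           # "active" | "passive"
    x: np.ndarray        # strictly increasing stretch / shear amounts
    P: np.ndarray        # nominal stress, kPa
    source: str = ""

    def __post_init__(self) -> None:
        if self.loadcase not in LOAD_CASES:
            raise ValueError(f"unknown load case {self.loadcase!r}")
        if self.state not in ("active", "passive"):
            raise ValueError("state must be 'active' or 'passive'")
        x = np.asarray(self.x, dtype=float)
        P = np.asarray(self.P, dtype=float)
        if x.ndim != 1 or x.shape != P.shape:
            raise ValueError("x and P must be matching 1-d arrays")
        if x.size < 2:
            raise ValueError("a curve needs at least 2 samples")
        if np.any(np.diff(x) <= 0):
            raise ValueError(f"curve x values must be strictly increasing "
                             f"({self.loadcase}/{self.state})")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "P", P)

    def __len__(self) -> int:
        return int(self.x.size)


def write_curves(curves, path) -> None:
    frames = [pd.DataFrame({"loadcase": c.loadcase, "state": c.state,
                            "x": c.x, "P_kPa": c.P, "source": c.source})
              for c in curves]
    # shortest round-trip repr keeps the IO lossless to the last bit
    pd.concat(frames, ignore_index=True).to_csv(
        Path(path), sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_curves(path) -> list[ExperimentalCurve]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse curve file {path}: {exc}") from exc
    for col in _COLUMNS:
        if col not in df.columns:
            raise ValueError(f"curve file {path} is missing column {col!r}")
    bad = df[pd.to_numeric(df["x"], errors="coerce").isna()
             | pd.to_numeric(df["P_kPa"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"malformed numeric row(s) at line(s) "
                         f"{[int(i) + 2 for i in bad.index[:5]]} of {path}")
    curves = []
    for (lc, state), grp in df.groupby(["loadcase", "state"], sort=False):
        source = str(grp["source"].iloc[0]) if "source" in grp else ""
        curves.append(ExperimentalCurve(
            loadcase=str(lc), state=str(state),
            x=grp["x"].to_numpy(float), P=grp["P_kPa"].to_numpy(float),
            source="" if source == "nan" else source))
    return curves
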