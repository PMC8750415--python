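"""Spectral preprocessing: SNV, Savitzky–Golay filtering, Pareto scaling.

SNV (standard normal variate) removes per-spectrum multiplicative and
additive scatter by centering and unit-variance scaling each spectrum across
its channels; it uses the sample (n−1) standard deviation.  Savitzky–Golay
smoothing/derivatives wrap :func:`scipy.signal.savgol_filter` with
polynomial-fit edge handling so output length equals input length.  Pareto
scaling (column-wise centering and division by the square root of the
standard deviation) belongs to model fitting and is returned together with a
reusable scaling record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "snv",
    "savitzky_golay",
    "pareto_scale",
    "ScalingRecord",
    "PreprocessSpec",
]


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum center and scale to unit sd.

    Accepts a single spectrum (1-D) or a matrix with spectra in rows.
    Raises on constant spectra (zero standard deviation).
    """
    x = np.asarray(spectra, dtype=float)
    one_dim = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least two channels")
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for constant spectra (sd = 0)")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if one_dim else out


def savitzky_golay(spectra: np.ndarray, window: int, polyorder: int,
                   deriv: int = 0, delta: float = 1.0) -> np.ndarray:
    """Savitzky–Golay smoothing or derivative of the local polynomial fit.

    ``deriv``-th derivative of the least-squares polynomial of order
    ``polyorder`` fitted in a sliding window of ``window`` points; near the
    edges the end-window polynomial is evaluated at asymmetric positions so
    the output keeps the input length.  ``delta`` is the channel spacing used
    to scale derivatives.
    """
    x = np.asarray(spectra, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if not (window > polyorder >= deriv >= 0):
        raise ValueError("require window > polyorder >= deriv >= 0")
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(x, window_length=window, polyorder=polyorder,
                         deriv=deriv, delta=delta, mode="interp", axis=-1)


@dataclass
class ScalingRecord:
    """Column centering/scaling learned on a training matrix.

    ``scale`` holds sqrt(column sd) for Pareto scaling (1.0 for constant
    columns, which are centered only and listed in ``constant_columns``).
    """

    mean: np.ndarray
    scale: np.ndarray
    constant_columns: List[int] = field(default_factory=list)

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) / self.scale

    def invert(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X * self.scale + self.mean


def pareto_scale(X: np.ndarray) -> Tuple[np.ndarray, ScalingRecord]:
    """Mean-center columns and divide by the square root of their sample sd."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    constant = np.flatnonzero(sd == 0)
    scale = np.sqrt(sd)
    scale[constant] = 1.0
    record = ScalingRecord(mean=mean, scale=scale,
                           constant_columns=list(map(int, constant)))
    return (X - mean) / scale, record


@dataclass(frozen=True)
class PreprocessSpec:
    """Ordered filter chain applied to raw absorbance rows.

    Steps are ("snv",) or ("sg", window, polyorder, deriv).  Mean-centering
    and Pareto scaling are part of model fitting, not of this chain.
    """

    steps: Tuple[tuple, ...] = (("snv",),)

    def __post_init__(self) -> None:
        for step in self.steps:
            if step[0] == "snv":
                continue
            if step[0] == "sg":
                _, window, polyorder, deriv = step
                if window % 2 == 0 or not (window > polyorder >= deriv >= 0):
                    raise ValueError(f"invalid Savitzky-Golay step: {step}")
                continue
            raise ValueError(f"unknown preprocessing step: {step[0]!r}")

    def apply(self, spectra: np.ndarray, delta: float = 1.0) -> np.ndarray:
        out = np.asarray(spectra, dtype=float)
        for step in self.steps:
            if step[0] == "snv":
                out = snv(out)
            else:
                _, window, polyorder, deriv = step
                out = savitzky_golay(out, window, polyorder, deriv, delta=delta)
        return out

    def to_strings(self) -> List[str]:
        return ["snv" if s[0] == "snv" else f"sg({s[1]},{s[2]},{s[3]})"
                for s in self.steps]

    @classmethod
    def from_strings(cls, names: Sequence[str]) -> "PreprocessSpec":
        steps = []
        for name in names:
            name = name.strip()
            if name == "snv":
                steps.append(("snv",))
            elif name.startswith("sg(") and name.endswith(")"):
                w, p, d = (int(v) for v in name[3:-1].split(","))
                steps.append(("sg", w, p, d))
            else:
                raise ValueError(f"cannot parse preprocessing step {name!r}")
        return cls(tuple(steps))
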