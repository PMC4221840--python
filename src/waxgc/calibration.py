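"""Linear retention-time / carbon-number calibration and peak-area
quantitation.

On a short high-temperature column, retention times of long-chain esters
correlate near-linearly with their total carbon number regardless of
structural type, so a single OLS line RT = a*C + b fitted to standards lets
the ester carbon number be read off a peak apex.  Peak area vs
concentration is likewise linear over the working range (0.1-0.5 mg/mL for
C29-C44 standards), giving rough single-point quantitation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateFitError(ValueError):
    """All x values identical: no line can be fit."""


class NonInvertibleError(ValueError):
    """Model slope is not positive; the line cannot be inverted."""


@dataclass(frozen=True)
class LinearModel:
    """An OLS line y = slope*x + intercept with its fit diagnostics.

    For RT calibration x is carbon number and y retention time (slope in
    min per carbon); for quantitation x is concentration (mg/mL) and y peak
    area (counts*min).
    """

    slope: float
    intercept: float
    r_squared: float = 1.0
    n_points: int = 0

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


def fit_line(x: Sequence[float], y: Sequence[float]) -> LinearModel:
    """Ordinary least squares fit; r_squared is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need >= 2 paired points")
    if np.unique(x).size < 2:
        raise DegenerateFitError("all x values are identical")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue) ** 2
    if not math.isfinite(r2):  # constant y: correlation undefined, report 0
        r2 = 0.0
    return LinearModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=int(x.size),
    )


def default_rt_model() -> LinearModel:
    """Package default retention model RT(C) = C - 29 min.

    Places C50-C56 esters at 21-27 min and the C44 standards inside the
    19-min window of the standard mixture; override by fitting your own
    standards with :func:`fit_line`.
    """
    return LinearModel(slope=1.0, intercept=-29.0, r_squared=1.0, n_points=0)


def _round_half_up(v: float) -> int:
    return math.floor(v + 0.5)


def carbon_from_rt(model: LinearModel, rt: float, parity: str = "even") -> int:
    """Invert the RT line and round to the nearest (even) carbon number.

    ``parity='even'`` rounds to the nearest even integer (all gum-base
    ester carbon numbers are even); ``parity='any'`` rounds to the nearest
    integer.  Ties round up.
    """
    if model.slope <= 0:
        raise NonInvertibleError(f"slope must be > 0, got {model.slope}")
    c = (rt - model.intercept) / model.slope
    if parity == "even":
        return 2 * _round_half_up(c / 2.0)
    if parity == "any":
        return _round_half_up(c)
    raise ValueError(f"parity must be 'any' or 'even', got {parity!r}")


class ConcentrationEstimate(NamedTuple):
    """Predicted concentration; ``below_range`` flags negative estimates."""

    value: float
    below_range: bool


def predict_conc(model: LinearModel, area: float) -> ConcentrationEstimate:
    """Invert an area-vs-concentration calibration line.

    Negative estimates (area below the fitted intercept) are returned
    as-is with ``below_range=True`` rather than clipped.
    """
    if model.slope <= 0:
        raise NonInvertibleError(f"slope must be > 0, got {model.slope}")
    value = (area - model.intercept) / model.slope
    return ConcentrationEstimate(value=value, below_range=value < 0)


def read_points_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column calibration CSV: (carbon_number, rt_min) or
    (concentration_mg_per_mL, area).  Returns (x, y) arrays."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"calibration file {path} needs two columns")
    x = frame.iloc[:, 0].to_numpy(dtype=float)
    y = frame.iloc[:, 1].to_numpy(dtype=float)
    return x, y
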