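"""Colorimetric halide-release quantification of dehalogenation.

Halide liberated by the enzyme displaces thiocyanate from Hg(SCN)2; the
released SCN- forms a colored Fe(SCN) complex read at 460 nm.  The readout
is purely empirical: a linear standard curve over 0-3.3 mM halide maps
absorbance to concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    ExtrapolationWarning,
    InsufficientDataError,
    InvalidParameterError,
    PoorFitWarning,
)

__all__ = ["StandardCurve", "fit_standard_curve", "halide_from_absorbance", "read_standards_csv"]


@dataclass
class StandardCurve:
    """Fitted linear calibration A460 = slope * [halide] + intercept."""

    conc: np.ndarray  # mM
    a460: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    @property
    def valid_range(self) -> tuple[float, float]:
        return (0.0, float(np.max(self.conc)))

    def predict(self, conc) -> np.ndarray:
        return self.slope * np.asarray(conc, dtype=float) + self.intercept


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least squares line through (conc mM, A460) standards.

    The intercept is fitted, not forced through zero: the reagent blank has
    nonzero absorbance and batches vary.  A fit with r^2 < 0.98 warns.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("need at least 3 (conc, A460) standards")
    conc, a460 = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise DegenerateDesignError("all standard concentrations identical; cannot fit a line")
    res = stats.linregress(conc, a460)
    r2 = float(res.rvalue**2)
    if r2 < 0.98:
        warnings.warn(f"standard curve r^2 = {r2:.4f} < 0.98", PoorFitWarning, stacklevel=2)
    if res.slope <= 0:
        warnings.warn("standard curve slope is non-positive", PoorFitWarning, stacklevel=2)
    return StandardCurve(conc=conc, a460=a460, slope=float(res.slope),
                         intercept=float(res.intercept), r_squared=r2)


def halide_from_absorbance(a460: float, curve: StandardCurve) -> float:
    """Invert the standard curve; warn when extrapolating beyond the standards."""
    if curve.slope <= 0:
        raise InvalidParameterError(f"standard curve slope must be > 0, got {curve.slope}")
    conc = (a460 - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    if conc < lo or conc > hi:
        warnings.warn(
            f"halide {conc:.3f} mM outside standard range [{lo:g}, {hi:g}] (extrapolated)",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(conc)


def read_standards_csv(path) -> StandardCurve:
    """Fit a standard curve from a CSV with columns conc_mM, A460."""
    df = pd.read_csv(path)
    missing = {"conc_mM", "A460"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"standards CSV missing columns: {sorted(missing)}")
    return fit_standard_curve(df[["conc_mM", "A460"]].to_numpy())
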