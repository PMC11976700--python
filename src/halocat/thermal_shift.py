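"""Apparent melting temperatures from thermofluor (DSF) melt curves.

Tm is read off as the temperature of maximal fluorescence change: the curve
is smoothed with a centered moving average, differentiated numerically, and
the derivative peak refined by quadratic interpolation for sub-grid
resolution.  No two-state thermodynamic fit is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NoTransitionError

__all__ = ["MeltCurve", "MeltResult", "melting_temperature", "delta_tm", "read_melt_csv"]


@dataclass
class MeltCurve:
    """Fluorescence (a.u.) versus temperature (degC), strictly increasing T."""

    temperature: np.ndarray
    fluorescence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.temperature) != len(self.fluorescence):
            raise InvalidParameterError("temperature and fluorescence must have equal length")
        if len(self.temperature) < 10:
            raise InvalidParameterError("melt curve needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise InvalidParameterError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class MeltResult:
    tm: float  # degC
    transition_amplitude: float  # a.u.
    method: str = "derivative_max"


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    # reflect-pad so the smoothed trace keeps the grid length
    half = window // 2
    padded = np.concatenate([y[half:0:-1], y, y[-2 : -half - 2 : -1]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def melting_temperature(curve: MeltCurve, smoothing_window: int = 5) -> MeltResult:
    """Tm at the maximum of the smoothed |dF/dT|, quadratically refined.

    Raises :class:`NoTransitionError` when the derivative peaks at a scan
    boundary (transition truncated or absent) or when the transition
    amplitude is below five times the residual noise estimate.
    """
    if smoothing_window < 3 or smoothing_window % 2 == 0:
        raise InvalidParameterError("smoothing_window must be odd and >= 3")
    t, f = curve.temperature, curve.fluorescence
    smooth = _moving_average(f, smoothing_window)
    noise = float(np.std(f - smooth))
    amplitude = float(np.ptp(smooth))
    if amplitude == 0.0 or amplitude < 5.0 * noise:
        raise NoTransitionError(
            f"curve {curve.label!r}: amplitude {amplitude:.3g} below detection "
            f"threshold (noise estimate {noise:.3g})"
        )
    deriv = np.gradient(smooth, t)
    mag = np.abs(deriv)
    i = int(np.argmax(mag))
    # the edge region is distorted by the smoothing padding; a derivative
    # peak within one window of the boundary means the transition is
    # truncated or absent
    if i < smoothing_window or i >= len(mag) - smoothing_window:
        raise NoTransitionError(
            f"curve {curve.label!r}: derivative maximum at the scan boundary"
        )
    # quadratic through the peak and neighbors; vertex gives sub-grid Tm
    t3, y3 = t[i - 1 : i + 2], mag[i - 1 : i + 2]
    a, b, _ = np.polyfit(t3 - t3[1], y3, 2)
    tm = float(t3[1] - b / (2 * a)) if a < 0 else float(t3[1])
    return MeltResult(tm=tm, transition_amplitude=amplitude)


def delta_tm(curve: MeltCurve, reference: MeltCurve, smoothing_window: int = 5) -> float:
    """Melting-temperature shift of ``curve`` relative to ``reference`` (K)."""
    return (
        melting_temperature(curve, smoothing_window).tm
        - melting_temperature(reference, smoothing_window).tm
    )


def read_melt_csv(path) -> list[MeltCurve]:
    """Read melt CSV with columns temp_C, fluorescence and optional well."""
    df = pd.read_csv(path)
    missing = {"temp_C", "fluorescence"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"melt CSV missing columns: {sorted(missing)}")
    if "well" in df.columns:
        groups = [(str(w), g) for w, g in df.groupby("well", sort=False)]
    else:
        groups = [("", df)]
    return [
        MeltCurve(
            temperature=g.sort_values("temp_C")["temp_C"].to_numpy(),
            fluorescence=g.sort_values("temp_C")["fluorescence"].to_numpy(),
            label=w,
        )
        for w, g in groups
    ]
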