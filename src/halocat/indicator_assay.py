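"""Quantitative two-wavelength pH-indicator assay for epoxide ring opening.

The readout chain converts a pair of absorbances (reporter wavelength and
isosbestic wavelength of the bromothymol-blue deprotonation) into a product
concentration:

    (A_rep, A_iso) -> deprotonation fraction f -> pH -> consumed protons -> mM product

Azidolysis of an epoxide converts a strong acid (HN3) into a weak-acid azido
alcohol, so one proton is consumed per turnover and the pH of a weakly
buffered reaction mixture rises.  The buffer strength of the read mixture
links the pH excursion back to the proton (hence product) concentration.

All chemistry enters through calibration parameters; nothing is hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidReadError, OutOfRangeWarning

__all__ = [
    "IndicatorCalibration",
    "BufferSpec",
    "AssayScenario",
    "WellTimeSeries",
    "ProgressCurve",
    "isometric_normalize",
    "ph_from_fraction",
    "fraction_from_ph",
    "buffer_ionized_fraction",
    "protons_consumed",
    "quantify_timeseries",
    "read_plate_csv",
    "write_progress_csv",
    "read_progress_csv",
]

# clamp bound for the deprotonation fraction; keeps the pH map finite
F_EPSILON = 1e-4


@dataclass(frozen=True)
class IndicatorCalibration:
    """Empirical calibration of the indicator in the quench matrix.

    ``ratio_acid`` and ``ratio_base`` are the reporter/isosbestic absorbance
    ratios of the fully protonated and fully deprotonated indicator.  The
    50% methanol quench shifts the apparent pKa, so all three numbers are
    per-batch calibration inputs, not literature constants.
    """

    pka_apparent: float = 7.10
    ratio_acid: float = 0.10
    ratio_base: float = 2.00
    report_wavelength: float = 616.0
    iso_wavelength: float = 499.0
    indicator_conc: float = 0.032  # mM in the read mixture (20 ug/mL BTB)

    def __post_init__(self) -> None:
        if not (self.ratio_base > self.ratio_acid >= 0.0):
            raise InvalidParameterError(
                "require ratio_base > ratio_acid >= 0, got "
                f"ratio_acid={self.ratio_acid}, ratio_base={self.ratio_base}"
            )
        if self.report_wavelength == self.iso_wavelength:
            raise InvalidParameterError("report and isosbestic wavelengths must differ")


@dataclass(frozen=True)
class BufferSpec:
    """Weak-acid buffer of the read mixture (concentration in the read mixture)."""

    total_conc: float  # mM
    pka_apparent: float = 7.20
    initial_ph: float = 7.00

    def __post_init__(self) -> None:
        if self.total_conc <= 0:
            raise InvalidParameterError(f"buffer total_conc must be > 0, got {self.total_conc}")


@dataclass(frozen=True)
class AssayScenario:
    """One plate-assay configuration: buffer, calibration and sample bookkeeping.

    Quenching 100 uL sample into 100 uL methanolic indicator gives the
    default ``dilution_factor`` of 2: concentrations in the read mixture are
    half those in the reaction, and quantified product is reported back on
    the sample scale.
    """

    buffer: BufferSpec
    calibration: IndicatorCalibration = field(default_factory=IndicatorCalibration)
    substrate0: float = 10.0  # mM, in the sample
    enzyme_loading: float = 0.05  # mg/mL
    dilution_factor: float = 2.0
    temperature: float = 30.0  # degC

    def __post_init__(self) -> None:
        if self.substrate0 <= 0:
            raise InvalidParameterError("substrate0 must be > 0")
        if self.dilution_factor < 1:
            raise InvalidParameterError("dilution_factor must be >= 1")


@dataclass
class WellTimeSeries:
    """Raw two-wavelength readings for one well: (time s, A_report, A_iso)."""

    well_id: str
    times: np.ndarray  # s
    a_report: np.ndarray
    a_iso: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a_report = np.asarray(self.a_report, dtype=float)
        self.a_iso = np.asarray(self.a_iso, dtype=float)
        if not (len(self.times) == len(self.a_report) == len(self.a_iso)):
            raise InvalidParameterError("times and absorbance arrays must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise InvalidParameterError("times must be nondecreasing")
        if not np.all(np.isfinite(self.a_report)) or not np.all(np.isfinite(self.a_iso)):
            raise InvalidReadError("absorbances must be finite")
        if np.any(self.a_iso <= 0):
            raise InvalidReadError("isosbestic absorbance must be > 0")


@dataclass
class ProgressCurve:
    """Product concentration (mM, on the sample scale) versus time (s)."""

    times: np.ndarray
    product: np.ndarray
    substrate0: float
    uncertainty: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)

    @property
    def conversion(self) -> np.ndarray:
        return self.product / self.substrate0


def isometric_normalize(a_report: float, a_iso: float, cal: IndicatorCalibration) -> float:
    """Deprotonation fraction of the indicator from a two-wavelength read.

    Dividing by the isosbestic absorbance removes path length, dilution and
    total indicator concentration, so f depends only on the acid/base state:

        f = (A_rep/A_iso - r_acid) / (r_base - r_acid)

    clamped to [1e-4, 1 - 1e-4].  Ratios outside the calibrated span by more
    than 5% of the span trigger an :class:`OutOfRangeWarning` before clamping.
    """
    if a_iso <= 0:
        raise InvalidReadError(f"isosbestic absorbance must be > 0, got {a_iso}")
    span = cal.ratio_base - cal.ratio_acid
    ratio = a_report / a_iso
    tol = 0.05 * span
    if ratio < cal.ratio_acid - tol or ratio > cal.ratio_base + tol:
        warnings.warn(
            f"absorbance ratio {ratio:.4f} outside calibrated span "
            f"[{cal.ratio_acid:.4f}, {cal.ratio_base:.4f}]; clamping",
            OutOfRangeWarning,
            stacklevel=2,
        )
    f = (ratio - cal.ratio_acid) / span
    return float(min(max(f, F_EPSILON), 1.0 - F_EPSILON))


def ph_from_fraction(f: float, cal: IndicatorCalibration) -> float:
    """pH from the indicator deprotonation fraction (Henderson-Hasselbalch)."""
    if not 0.0 < f < 1.0:
        raise InvalidParameterError(f"fraction must lie in (0, 1), got {f}")
    return cal.pka_apparent + np.log10(f / (1.0 - f))


def fraction_from_ph(ph: float, cal: IndicatorCalibration) -> float:
    """Inverse of :func:`ph_from_fraction`."""
    return 1.0 / (1.0 + 10.0 ** (cal.pka_apparent - ph))


def buffer_ionized_fraction(ph: float, buffer: BufferSpec) -> float:
    """Fraction of the buffer in the deprotonated (conjugate-base) form."""
    return 1.0 / (1.0 + 10.0 ** (buffer.pka_apparent - ph))


def protons_consumed(
    ph_start: float,
    ph_end: float,
    buffer: BufferSpec,
    cal: IndicatorCalibration | None = None,
    include_minor_terms: bool = False,
) -> float:
    """Protons consumed (mM, in the read mixture) for a pH excursion.

    The dominant term is the buffer strength: raising the pH deprotonates
    buffer molecules, each releasing one proton to replace a consumed one,

        dn = B * (alpha(pH_end) - alpha(pH_start)),  alpha = 1/(1+10^(pKa-pH)).

    ``include_minor_terms`` adds the indicator's own deprotonation and the
    change in free protons; both are negligible at the default 0.03 mM
    indicator in millimolar buffer, and off by default.
    """
    for ph in (ph_start, ph_end):
        if not 3.0 <= ph <= 11.0:
            raise InvalidParameterError(f"pH {ph} outside the supported range [3, 11]")
    delta = buffer.total_conc * (
        buffer_ionized_fraction(ph_end, buffer) - buffer_ionized_fraction(ph_start, buffer)
    )
    if include_minor_terms:
        if cal is None:
            raise InvalidParameterError("include_minor_terms requires an indicator calibration")
        delta += cal.indicator_conc * (fraction_from_ph(ph_end, cal) - fraction_from_ph(ph_start, cal))
        delta += (10.0 ** (-ph_start) - 10.0 ** (-ph_end)) * 1e3  # mol/L -> mM
    return delta


def quantify_timeseries(
    ts: WellTimeSeries,
    scenario: AssayScenario,
    include_minor_terms: bool = False,
) -> ProgressCurve:
    """Product concentration versus time from a well's two-wavelength reads.

    The first reading defines the t=0 reference pH.  One proton is consumed
    per product molecule (strong acid -> weak acid), so product on the sample
    scale is ``dilution_factor`` times the in-mixture proton consumption.
    Noise passes through unaltered: monotonicity is not enforced and product
    may exceed ``substrate0`` (flagged downstream, never clamped), so that
    rate fits see unbiased errors.
    """
    if len(ts.times) < 2:
        raise InvalidParameterError(
            f"well {ts.well_id!r}: need at least 2 readings, got {len(ts.times)}"
        )
    cal = scenario.calibration
    try:
        fractions = [
            isometric_normalize(ar, ai, cal) for ar, ai in zip(ts.a_report, ts.a_iso)
        ]
    except InvalidReadError as exc:
        raise InvalidReadError(f"well {ts.well_id!r}: {exc}") from exc
    phs = [ph_from_fraction(f, cal) for f in fractions]
    ph0 = phs[0]
    product = np.array(
        [
            scenario.dilution_factor
            * protons_consumed(ph0, ph, scenario.buffer, cal, include_minor_terms)
            for ph in phs
        ]
    )
    return ProgressCurve(
        times=ts.times.copy(),
        product=product,
        substrate0=scenario.substrate0,
        label=ts.well_id,
    )


def read_plate_csv(path) -> list[WellTimeSeries]:
    """Read a plate CSV with columns well, time_s, A616, A499."""
    df = pd.read_csv(path)
    required = {"well", "time_s", "A616", "A499"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"plate CSV missing columns: {sorted(missing)}")
    out = []
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            WellTimeSeries(
                well_id=str(well),
                times=grp["time_s"].to_numpy(),
                a_report=grp["A616"].to_numpy(),
                a_iso=grp["A499"].to_numpy(),
            )
        )
    return out


def write_plate_csv(path, wells: Sequence[WellTimeSeries]) -> None:
    rows = []
    for w in wells:
        for t, ar, ai in zip(w.times, w.a_report, w.a_iso):
            rows.append({"well": w.well_id, "time_s": t, "A616": ar, "A499": ai})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_progress_csv(path, curves: Sequence[ProgressCurve]) -> None:
    rows = []
    for c in curves:
        unc = c.uncertainty if c.uncertainty is not None else np.zeros_like(c.product)
        for t, p, u in zip(c.times, c.product, unc):
            rows.append(
                {"sample": c.label, "time_s": t, "product_mM": p, "uncertainty_mM": u,
                 "substrate0_mM": c.substrate0}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_progress_csv(path) -> list[ProgressCurve]:
    df = pd.read_csv(path)
    out = []
    for label, grp in df.groupby("sample", sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            ProgressCurve(
                times=grp["time_s"].to_numpy(),
                product=grp["product_mM"].to_numpy(),
                substrate0=float(grp["substrate0_mM"].iloc[0]),
                uncertainty=grp["uncertainty_mM"].to_numpy(),
                label=str(label),
            )
        )
    return out
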