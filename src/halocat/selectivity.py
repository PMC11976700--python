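"""Enantioselectivity (E-values) and regioselectivity from conversion/ee data.

For an irreversible kinetic resolution the enantiomeric ratio E — the ratio
of the specificity constants for the fast and slow enantiomer — follows in
closed form from the conversion C and the product enantiomeric excess ee_P:

    E = ln[1 - C(1 + ee_P)] / ln[1 - C(1 - ee_P)]

Alternatively, when both substrate and product excesses are measured,
mass balance of a two-enantiomer, single-product resolution gives
C = ee_S / (ee_S + ee_P), after which the same closed form applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InfeasibleObservationError, InvalidParameterError, UndefinedResultError

__all__ = [
    "ResolutionObservation",
    "EnantioselectivityResult",
    "RegioOutcome",
    "e_from_c_eep",
    "e_from_ees_eep",
    "regio_product_fractions",
    "format_e_value",
    "read_gc_csv",
    "selectivity_table",
]

E_DISPLAY_CAP = 200.0


@dataclass(frozen=True)
class ResolutionObservation:
    """Conversion and enantiomeric excesses of one biotransformation.

    Fractions throughout (0.465, not 46.5%).  ``preferred_enantiomer`` is
    carried as metadata from the chiral analysis, never inferred.
    """

    conversion: float
    ee_p: float
    ee_s: float | None = None
    preferred_enantiomer: str = "S"
    label: str = ""

    def __post_init__(self) -> None:
        for name, val in (("conversion", self.conversion), ("ee_p", self.ee_p)):
            if not 0.0 <= val <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {val}")
        if self.ee_s is not None and not 0.0 <= self.ee_s <= 1.0:
            raise InvalidParameterError(f"ee_s must lie in [0, 1], got {self.ee_s}")
        if self.preferred_enantiomer not in ("S", "R"):
            raise InvalidParameterError("preferred_enantiomer must be 'S' or 'R'")


@dataclass(frozen=True)
class EnantioselectivityResult:
    e_value: float
    display: str
    method: str  # "from_c_eep" | "from_ees_eep"


@dataclass(frozen=True)
class RegioOutcome:
    """Response-corrected product fractions for regiodivergent ring opening."""

    fractions: dict[str, float]

    @property
    def alpha_fraction(self) -> float:
        return self.fractions.get("alpha", 0.0)

    @property
    def beta_fraction(self) -> float:
        return self.fractions.get("beta", 0.0)


def format_e_value(e: float) -> str:
    """Printed convention: two significant figures, '>200' above the cap."""
    if e > E_DISPLAY_CAP:
        return ">200"
    return f"{e:.2g}"


def e_from_c_eep(conversion: float, ee_p: float, method: str = "from_c_eep") -> EnantioselectivityResult:
    """Enantiomeric ratio from conversion and product ee (closed form)."""
    if not 0.0 <= ee_p < 1.0 + 1e-12:
        raise InvalidParameterError(f"ee_p must lie in [0, 1), got {ee_p}")
    if conversion <= 0.0:
        raise UndefinedResultError(
            "E is undefined at zero conversion; the C -> 0 limit is "
            f"(1 + ee_p)/(1 - ee_p) = {(1 + ee_p) / (1 - ee_p):.4g}"
        )
    if conversion >= 1.0:
        raise InvalidParameterError(f"conversion must lie in (0, 1), got {conversion}")
    # grouped to avoid cancellation when the fast enantiomer is nearly spent
    fast_arg = (1.0 - conversion) - conversion * ee_p
    if fast_arg <= 0.0:
        raise InfeasibleObservationError(
            f"C(1 + ee_p) = {conversion * (1.0 + ee_p):.4f} >= 1: the fast enantiomer "
            "would be over-consumed; conversion and ee_p are inconsistent"
        )
    if ee_p == 0.0:
        return EnantioselectivityResult(e_value=1.0, display=format_e_value(1.0), method=method)
    e = np.log(fast_arg) / np.log(1.0 - conversion * (1.0 - ee_p))
    return EnantioselectivityResult(e_value=float(e), display=format_e_value(float(e)), method=method)


def e_from_ees_eep(ee_s: float, ee_p: float) -> tuple[float, EnantioselectivityResult]:
    """Conversion (by mass balance) and E from substrate and product ee."""
    for name, val in (("ee_s", ee_s), ("ee_p", ee_p)):
        if not 0.0 <= val <= 1.0:
            raise InvalidParameterError(f"{name} must lie in [0, 1], got {val}")
    if ee_s + ee_p == 0.0:
        raise UndefinedResultError("ee_s = ee_p = 0 leaves conversion and E undefined")
    conversion = ee_s / (ee_s + ee_p)
    return conversion, e_from_c_eep(conversion, ee_p, method="from_ees_eep")


def regio_product_fractions(
    areas: Mapping[str, float],
    response_factors: Mapping[str, float] | None = None,
) -> RegioOutcome:
    """Normalized product fractions from GC peak areas.

    fraction_i = (area_i / rf_i) / sum_j (area_j / rf_j).  A missing response
    factor defaults to 1 with a warning.
    """
    if len(areas) < 2:
        raise InvalidParameterError("need at least 2 products")
    if any(a < 0 for a in areas.values()):
        raise InvalidParameterError("signals must be >= 0")
    if all(a == 0 for a in areas.values()):
        raise UndefinedResultError("all signals are zero; fractions undefined")
    response_factors = dict(response_factors or {})
    corrected = {}
    for product, area in areas.items():
        if product not in response_factors:
            warnings.warn(
                f"no response factor for {product!r}; assuming 1.0", UserWarning, stacklevel=2
            )
            response_factors[product] = 1.0
        corrected[product] = area / response_factors[product]
    total = sum(corrected.values())
    return RegioOutcome(fractions={p: v / total for p, v in corrected.items()})


def read_gc_csv(path) -> list[ResolutionObservation]:
    """Read a GC-derived table: sample, conversion_pct, ee_s_pct, ee_p_pct, preferred."""
    df = pd.read_csv(path)
    missing = {"sample", "conversion_pct", "ee_p_pct"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"GC CSV missing columns: {sorted(missing)}")
    obs = []
    for _, row in df.iterrows():
        ee_s = row["ee_s_pct"] / 100.0 if "ee_s_pct" in df.columns and pd.notna(row.get("ee_s_pct")) else None
        obs.append(
            ResolutionObservation(
                conversion=row["conversion_pct"] / 100.0,
                ee_p=row["ee_p_pct"] / 100.0,
                ee_s=ee_s,
                preferred_enantiomer=str(row.get("preferred", "S")),
                label=str(row["sample"]),
            )
        )
    return obs


def selectivity_table(observations) -> pd.DataFrame:
    """E-value table (one row per observation) in the printed layout."""
    rows = []
    for o in observations:
        res = e_from_c_eep(o.conversion, o.ee_p)
        rows.append(
            {
                "sample": o.label,
                "conversion_pct": 100 * o.conversion,
                "ee_p_pct": 100 * o.ee_p,
                "E": res.e_value,
                "E_display": f"{res.display} ({o.preferred_enantiomer})",
            }
        )
    return pd.DataFrame(rows)
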