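"""Initial rates, specific activities, and Michaelis-Menten / Hill fits.

Rate laws
---------
Hyperbolic (Michaelis-Menten):   v = kcat * S / (KM + S)
Cooperative (Hill):              k_obs = k_obs,max * S^n / (K50^n + S^n)

Rates may be raw (mM/s) or normalized per enzyme site (s^-1); normalization
uses the enzyme loading (mg/mL) and a user-supplied subunit molar mass —
whether the field convention is per subunit or per oligomer varies, so the
mass is explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    PoorFitWarning,
)
from .indicator_assay import ProgressCurve

__all__ = [
    "RateEstimate",
    "SpecificActivity",
    "KineticDataset",
    "MMFit",
    "HillFit",
    "initial_rate",
    "specific_activity",
    "site_concentration",
    "fit_michaelis_menten",
    "fit_hill",
    "michaelis_menten_rate",
    "hill_rate",
]


@dataclass(frozen=True)
class RateEstimate:
    """Background-subtracted initial rate from the early linear window."""

    v0: float  # mM/s
    stderr: float  # mM/s
    n_points_used: int
    window_end: float  # s


@dataclass(frozen=True)
class SpecificActivity:
    """Specific activity in U/mg (1 U = 1 umol/min)."""

    value: float
    sd: float = 0.0


@dataclass
class KineticDataset:
    """Rate-vs-concentration data for one varied species.

    ``s`` holds the varied substrate or nucleophile concentration (mM) and
    ``rate`` the observed rate — per-site k_obs (s^-1) or raw v (mM/s)
    depending on ``normalization``.  Replicates may appear either as repeated
    concentrations or aggregated with per-point ``sd``.
    """

    s: np.ndarray
    rate: np.ndarray
    sd: np.ndarray | None = None
    normalization: str = "per_site_rate"  # or "raw_rate"
    varied_species: str = "substrate"

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.s < 0):
            raise InvalidParameterError("concentrations must be >= 0")
        if len(self.s) != len(self.rate):
            raise InvalidParameterError("s and rate must have equal length")


@dataclass(frozen=True)
class MMFit:
    kcat: float
    km: float
    se_kcat: float
    se_km: float
    efficiency: float  # kcat / km
    se_efficiency: float

    def as_dict(self) -> dict[str, float]:
        return {
            "kcat": self.kcat, "km": self.km, "se_kcat": self.se_kcat,
            "se_km": self.se_km, "efficiency": self.efficiency,
            "se_efficiency": self.se_efficiency,
        }


@dataclass(frozen=True)
class HillFit:
    kobs_max: float
    k50: float
    n_h: float
    se_kobs_max: float
    se_k50: float
    se_n_h: float
    efficiency: float  # kobs_max / k50
    se_efficiency: float

    def as_dict(self) -> dict[str, float]:
        return {
            "kobs_max": self.kobs_max, "k50": self.k50, "n_h": self.n_h,
            "se_kobs_max": self.se_kobs_max, "se_k50": self.se_k50,
            "se_n_h": self.se_n_h, "efficiency": self.efficiency,
            "se_efficiency": self.se_efficiency,
        }


def michaelis_menten_rate(s, kcat, km):
    s = np.asarray(s, dtype=float)
    return kcat * s / (km + s)


def hill_rate(s, kobs_max, k50, n_h):
    s = np.asarray(s, dtype=float)
    sn = np.power(s, n_h)
    return kobs_max * sn / (np.power(k50, n_h) + sn)


def initial_rate(
    curve: ProgressCurve,
    blank: ProgressCurve | None = None,
    max_conversion: float = 0.10,
) -> RateEstimate:
    """Least-squares initial slope of a progress curve, blank-subtracted.

    Points are used while the conversion relative to the first point stays at
    or below ``max_conversion``, always keeping the three earliest points
    when available (sampling the first 30-360 s keeps most curves within the
    linear regime anyway).  A blank (no-enzyme background) curve is sloped
    identically and subtracted; standard errors combine in quadrature.
    Offsetting all product values by a constant leaves the estimate unchanged.
    """

    def window_slope(c: ProgressCurve) -> tuple[float, float, int, float]:
        rel_conv = (c.product - c.product[0]) / c.substrate0
        keep = rel_conv <= max_conversion
        keep[: min(3, len(keep))] = True
        t, p = c.times[keep], c.product[keep]
        if len(t) < 2:
            raise InsufficientDataError(
                f"curve {c.label!r}: fewer than 2 usable points in the initial-rate window"
            )
        if np.ptp(p) == 0.0:  # flat curve: slope 0 with no scatter
            return 0.0, 0.0, len(t), float(t[-1])
        res = stats.linregress(t, p)
        se = float(res.stderr) if len(t) > 2 else 0.0
        return float(res.slope), se, len(t), float(t[-1])

    v0, se, n, t_end = window_slope(curve)
    if blank is not None:
        vb, seb, _, _ = window_slope(blank)
        v0 -= vb
        se = float(np.hypot(se, seb))
    return RateEstimate(v0=v0, stderr=se, n_points_used=n, window_end=t_end)


def specific_activity(rate: RateEstimate, enzyme_loading: float) -> SpecificActivity:
    """U/mg from an initial rate in mM/s.  1 mM = 1 umol/mL, so
    U/mg = v0 [mM/s] * 60 [s/min] / loading [mg/mL]."""
    if enzyme_loading <= 0:
        raise InvalidParameterError(f"enzyme loading must be > 0, got {enzyme_loading}")
    factor = 60.0 / enzyme_loading
    return SpecificActivity(value=rate.v0 * factor, sd=rate.stderr * factor)


def site_concentration(enzyme_loading: float, subunit_mass_kda: float) -> float:
    """Enzyme-site concentration (mM) from loading (mg/mL) and subunit mass (kDa)."""
    if enzyme_loading <= 0 or subunit_mass_kda <= 0:
        raise InvalidParameterError("loading and subunit mass must be > 0")
    return enzyme_loading / subunit_mass_kda  # (g/L)/(kg/mol) = mmol/L


def _prepare_fit(data: KineticDataset, min_distinct: int = 5) -> np.ndarray | None:
    if np.unique(data.s).size < min_distinct:
        raise InsufficientDataError(
            f"need >= {min_distinct} distinct concentrations, got {np.unique(data.s).size}"
        )
    if data.sd is not None and np.all(data.sd > 0):
        return data.sd  # inverse-variance weighting
    return None


def _check_span(data: KineticDataset, half_sat: float, name: str) -> None:
    if not (np.min(data.s) < half_sat < np.max(data.s)):
        warnings.warn(
            f"fitted {name} = {half_sat:.3g} mM lies outside the sampled concentration "
            f"range [{np.min(data.s):g}, {np.max(data.s):g}]; parameters may be poorly "
            "constrained",
            PoorFitWarning,
            stacklevel=3,
        )


def _ratio_se(num: float, den: float, cov: np.ndarray, i: int, j: int) -> float:
    """First-order SE of num/den given the (i, j) entries of the fit covariance."""
    g = np.zeros(cov.shape[0])
    g[i] = 1.0 / den
    g[j] = -num / den**2
    var = float(g @ cov @ g)
    return float(np.sqrt(max(var, 0.0)))


def _half_sat_guess(s: np.ndarray, rate: np.ndarray) -> float:
    half = 0.5 * np.max(rate)
    idx = int(np.argmin(np.abs(rate - half)))
    guess = s[idx]
    return float(guess) if guess > 0 else float(np.median(s[s > 0]))


def fit_michaelis_menten(data: KineticDataset) -> MMFit:
    """Weighted nonlinear least-squares fit of the hyperbolic rate law."""
    sigma = _prepare_fit(data)
    vmax0 = 1.05 * np.max(data.rate)
    km0 = _half_sat_guess(data.s, data.rate)
    best = None
    for km_start in (km0, km0 / 4, km0 * 4):
        try:
            popt, pcov = optimize.curve_fit(
                michaelis_menten_rate, data.s, data.rate, p0=[vmax0, km_start],
                sigma=sigma, bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = float(np.sum((michaelis_menten_rate(data.s, *popt) - data.rate) ** 2))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        raise FitFailureError("Michaelis-Menten fit failed to converge from all starts")
    popt, pcov, _ = best
    kcat, km = popt
    _check_span(data, km, "KM")
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return MMFit(
        kcat=float(kcat), km=float(km), se_kcat=float(se[0]), se_km=float(se[1]),
        efficiency=float(kcat / km), se_efficiency=_ratio_se(kcat, km, pcov, 0, 1),
    )


def fit_hill(data: KineticDataset, n_h_bounds: tuple[float, float] = (0.3, 10.0)) -> HillFit:
    """Multi-start weighted fit of the cooperative (Hill) rate law.

    The k50/n_h likelihood ridge is shallow, so the fit starts from
    n_h in {1, 2, 4} and keeps the lowest-residual solution; n_h is bounded
    to [0.3, 10].
    """
    sigma = _prepare_fit(data)
    kmax0 = 1.05 * np.max(data.rate)
    k50_0 = _half_sat_guess(data.s, data.rate)
    lo = [0.0, 1e-12, n_h_bounds[0]]
    hi = [np.inf, np.inf, n_h_bounds[1]]
    best = None
    starts = {min(max(nh0, n_h_bounds[0]), n_h_bounds[1]) for nh0 in (1.0, 2.0, 4.0)}
    for nh0 in sorted(starts):
        try:
            popt, pcov = optimize.curve_fit(
                hill_rate, data.s, data.rate, p0=[kmax0, k50_0, nh0],
                sigma=sigma, bounds=(lo, hi), maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = float(np.sum((hill_rate(data.s, *popt) - data.rate) ** 2))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        raise FitFailureError("Hill fit failed to converge from all starts")
    popt, pcov, _ = best
    kobs_max, k50, n_h = popt
    _check_span(data, k50, "K50")
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return HillFit(
        kobs_max=float(kobs_max), k50=float(k50), n_h=float(n_h),
        se_kobs_max=float(se[0]), se_k50=float(se[1]), se_n_h=float(se[2]),
        efficiency=float(kobs_max / k50), se_efficiency=_ratio_se(kobs_max, k50, pcov, 0, 1),
    )
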