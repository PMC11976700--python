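"""Synthetic-data generators standing in for the wet-lab instruments.

Every input the pipeline consumes can be generated here with the
statistical structure the downstream analyses assume:

* kinetic resolutions drawn from the irreversible two-enantiomer
  first-order model with a prescribed true enantiomeric ratio;
* enzymatic progress curves (cooperative or hyperbolic rate law) with a
  first-order chemical-background companion;
* two-wavelength indicator plate reads obtained by inverting the assay
  quantification chain, so generator followed by quantifier is the identity
  at zero noise;
* logistic thermofluor melt curves;
* multivariate-Gaussian coordinate ensembles with prescribed inter-residue
  correlations, the statistical stand-in for MD frames.

Noise models: additive Gaussian on absorbance and fluorescence,
multiplicative Gaussian (constant CV) on rates.  Every generator is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import InvalidParameterError, RangeError
from .indicator_assay import (
    AssayScenario,
    ProgressCurve,
    WellTimeSeries,
    buffer_ionized_fraction,
    fraction_from_ph,
)
from .kinetics import KineticDataset, hill_rate
from .selectivity import ResolutionObservation
from .spm import CoordinateEnsemble
from .thermal_shift import MeltCurve

__all__ = [
    "TrueKinetics",
    "ResolutionTruth",
    "EnsembleSpec",
    "E_TRUE_CAP",
    "simulate_resolution_outcome",
    "simulate_progress_curve",
    "simulate_plate_timeseries",
    "simulate_rate_dataset",
    "simulate_ensemble",
    "simulate_melt_curve",
]

# enantiomeric ratios above this are treated as "E = infinity"
E_TRUE_CAP = 1e9


@dataclass(frozen=True)
class TrueKinetics:
    """Generating truth for rate data: per-site rate law plus chemical background."""

    model: str  # "michaelis_menten" | "hill"
    vmax_equivalent: float  # s^-1, per enzyme site (kcat or k_obs,max)
    half_saturation: float  # mM (KM or K50)
    hill_n: float = 1.0
    background_rate_constant: float = 0.0  # s^-1, uncatalyzed first-order rate

    def __post_init__(self) -> None:
        if self.model not in ("michaelis_menten", "hill"):
            raise InvalidParameterError(f"unknown model {self.model!r}")
        if self.half_saturation <= 0:
            raise InvalidParameterError("half_saturation must be > 0")
        if self.hill_n < 0.5:
            raise InvalidParameterError("hill_n must be >= 0.5")
        if self.model == "michaelis_menten" and self.hill_n != 1.0:
            raise InvalidParameterError("michaelis_menten requires hill_n = 1")
        if self.background_rate_constant < 0:
            raise InvalidParameterError("background_rate_constant must be >= 0")

    def rate(self, s) -> np.ndarray:
        """Per-site rate (s^-1) at substrate concentration s (mM)."""
        return hill_rate(s, self.vmax_equivalent, self.half_saturation, self.hill_n)


@dataclass(frozen=True)
class ResolutionTruth:
    """Generating truth for a kinetic resolution."""

    e_true: float
    target_conversion: float
    preferred_enantiomer: str = "S"

    def __post_init__(self) -> None:
        if self.e_true < 1.0:
            raise InvalidParameterError(f"e_true must be >= 1, got {self.e_true}")
        if not 0.0 <= self.target_conversion < 1.0:
            raise InvalidParameterError("target_conversion must lie in [0, 1)")
        if self.preferred_enantiomer not in ("S", "R"):
            raise InvalidParameterError("preferred_enantiomer must be 'S' or 'R'")


@dataclass(frozen=True)
class EnsembleSpec:
    """Specification of a Gaussian coordinate ensemble with target correlations."""

    mean_coordinates: np.ndarray  # n x 3, A
    correlation_targets: np.ndarray  # n x n, symmetric PSD, unit diagonal
    fluctuation_scale: float = 1.0  # A
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean_coordinates, dtype=float)
        corr = np.asarray(self.correlation_targets, dtype=float)
        object.__setattr__(self, "mean_coordinates", mean)
        object.__setattr__(self, "correlation_targets", corr)
        n = mean.shape[0]
        if mean.ndim != 2 or mean.shape[1] != 3:
            raise InvalidParameterError("mean_coordinates must have shape (n_residues, 3)")
        if corr.shape != (n, n):
            raise InvalidParameterError("correlation_targets must be n_residues x n_residues")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise InvalidParameterError("correlation_targets must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise InvalidParameterError("correlation_targets must have unit diagonal")
        if self.fluctuation_scale <= 0:
            raise InvalidParameterError("fluctuation_scale must be > 0")
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")

    @property
    def n_residues(self) -> int:
        return self.mean_coordinates.shape[0]


def _slow_conversion(x_fast: float, e: float) -> float:
    return 1.0 - (1.0 - x_fast) ** (1.0 / e)


def simulate_resolution_outcome(truth: ResolutionTruth) -> ResolutionObservation:
    """Exact (C, ee_S, ee_P) of an irreversible first-order kinetic resolution.

    The fast and slow enantiomers deplete as first-order processes whose
    rate-constant ratio is ``e_true``, so their conversions obey
    x_slow = 1 - (1 - x_fast)^(1/E).  Given the overall conversion
    C = (x_fast + x_slow)/2 of the racemate, x_fast is found numerically and
    the excesses follow:

        ee_P = (x_fast - x_slow) / (x_fast + x_slow)
        ee_S = (x_fast - x_slow) / (2 - x_fast - x_slow)
    """
    e = min(truth.e_true, E_TRUE_CAP)
    c = truth.target_conversion
    if c == 0.0:
        return ResolutionObservation(
            conversion=0.0, ee_p=0.0, ee_s=0.0,
            preferred_enantiomer=truth.preferred_enantiomer, label="synthetic",
        )
    if e == 1.0:
        x_fast = x_slow = c
    else:
        # Solve in u = -ln(1 - x_fast), which stays well conditioned when the
        # fast enantiomer is all but consumed: x_fast = 1 - e^-u and
        # x_slow = 1 - e^(-u/E), so C = 1 - (e^-u + e^(-u/E))/2.
        def mean_conversion_gap(u: float) -> float:
            return 1.0 - 0.5 * (np.exp(-u) + np.exp(-u / e)) - c

        u_lo = -np.log1p(-c)  # both enantiomers equally converted
        u_hi = max(-e * np.log1p(-c), u_lo + 1.0)  # slow enantiomer at C already
        u = brentq(mean_conversion_gap, u_lo, u_hi, xtol=1e-300, rtol=8.9e-16)
        x_fast = -np.expm1(-u)
        x_slow = -np.expm1(-u / e)
    ee_p = (x_fast - x_slow) / (x_fast + x_slow) if c > 0 else 0.0
    ee_s = (x_fast - x_slow) / (2.0 - x_fast - x_slow)
    return ResolutionObservation(
        conversion=c,
        ee_p=float(min(ee_p, 1.0)),
        ee_s=float(min(ee_s, 1.0)),
        preferred_enantiomer=truth.preferred_enantiomer,
        label="synthetic",
    )


def simulate_progress_curve(
    truth: TrueKinetics,
    s0: float,
    enzyme_site_conc: float,
    times,
) -> tuple[ProgressCurve, ProgressCurve]:
    """Noiseless product-vs-time curves: catalyzed-plus-background and background.

    Integrates dP/dt = [E]_site * v(S) + k_bg * S with S = s0 - P, where v is
    the per-site rate law of ``truth``; the background companion is the
    closed-form first-order curve P_bg = s0 (1 - exp(-k_bg t)).
    """
    times = np.asarray(times, dtype=float)
    if s0 <= 0 or enzyme_site_conc < 0:
        raise InvalidParameterError("concentrations must be positive (enzyme may be 0)")
    if times.size < 1 or np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise InvalidParameterError("times must be nonnegative and strictly increasing")

    kbg = truth.background_rate_constant

    def rhs(_t, p):
        s = max(s0 - p[0], 0.0)
        return [enzyme_site_conc * float(truth.rate(s)) + kbg * s]

    t_span = (0.0, float(times[-1])) if times[-1] > 0 else (0.0, 1.0)
    if enzyme_site_conc == 0.0 and kbg == 0.0:
        product = np.zeros_like(times)
    else:
        sol = solve_ivp(
            rhs, t_span, [0.0], t_eval=times, method="LSODA", rtol=1e-10, atol=1e-12
        )
        if not sol.success:
            raise RuntimeError(f"progress-curve integration failed: {sol.message}")
        product = np.clip(sol.y[0], 0.0, s0)
    background = s0 * -np.expm1(-kbg * times)
    full = ProgressCurve(times=times, product=product, substrate0=s0, label="catalyzed+background")
    blank = ProgressCurve(times=times, product=background, substrate0=s0, label="background")
    return full, blank


def simulate_plate_timeseries(
    curve: ProgressCurve,
    scenario: AssayScenario,
    noise_sd: float = 0.0,
    seed: int = 0,
    a_iso_reference: float = 1.0,
    well_id: str = "synthetic",
) -> WellTimeSeries:
    """Two-wavelength plate reads that quantify back to ``curve``.

    Inverts the assay chain: product -> in-mixture consumed protons ->
    buffer ionization -> pH -> indicator fraction -> absorbance ratio.
    A t=0 reference read at the scenario's initial pH is prepended when the
    curve does not start at t=0.  Additive Gaussian noise (sd in absorbance
    units) is applied to both wavelengths.
    """
    cal = scenario.calibration
    buf = scenario.buffer
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    times = curve.times
    product = curve.product
    if times.size == 0 or times[0] > 0:
        times = np.concatenate([[0.0], times])
        product = np.concatenate([[0.0], product])
    alpha0 = buffer_ionized_fraction(buf.initial_ph, buf)
    a_report = np.empty_like(times)
    a_iso = np.full_like(times, a_iso_reference)
    span = cal.ratio_base - cal.ratio_acid
    for k, (t, p) in enumerate(zip(times, product)):
        consumed = p / scenario.dilution_factor  # mM in the read mixture
        alpha = alpha0 + consumed / buf.total_conc
        if not 0.0 < alpha < 1.0:
            raise RangeError(
                f"t = {t:g} s: buffer ionization {alpha:.4f} outside (0, 1); "
                "product exceeds the buffer capacity"
            )
        ph = buf.pka_apparent + np.log10(alpha / (1.0 - alpha))
        f = fraction_from_ph(ph, cal)
        if not 0.02 <= f <= 0.98:
            raise RangeError(
                f"t = {t:g} s: indicator fraction {f:.4f} outside the dynamic "
                "range [0.02, 0.98]"
            )
        a_report[k] = (cal.ratio_acid + f * span) * a_iso_reference
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a_report = a_report + rng.normal(0.0, noise_sd, size=a_report.shape)
        a_iso = a_iso + rng.normal(0.0, noise_sd, size=a_iso.shape)
    return WellTimeSeries(well_id=well_id, times=times, a_report=a_report, a_iso=a_iso)


def simulate_rate_dataset(
    truth: TrueKinetics,
    concentrations,
    n_replicates: int = 2,
    cv: float = 0.02,
    seed: int = 0,
    varied_species: str = "substrate",
    aggregate: bool = False,
) -> KineticDataset:
    """Noisy rate-vs-concentration data from a true rate law.

    Each concentration is measured ``n_replicates`` times with multiplicative
    Gaussian noise of the given coefficient of variation.  By default the
    replicate-level points are returned (unweighted fitting); with
    ``aggregate`` replicates are averaged and their SD attached, enabling
    inverse-variance weighting downstream.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("concentrations must be >= 0")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    if cv < 0:
        raise InvalidParameterError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    true = np.asarray(truth.rate(conc), dtype=float)
    reps = true[None, :] * (1.0 + cv * rng.standard_normal((n_replicates, conc.size)))
    if aggregate and n_replicates > 1:
        return KineticDataset(
            s=conc,
            rate=reps.mean(axis=0),
            sd=reps.std(axis=0, ddof=1),
            varied_species=varied_species,
        )
    return KineticDataset(
        s=np.tile(conc, n_replicates),
        rate=reps.ravel(),
        varied_species=varied_species,
    )


def _correlation_factor(corr: np.ndarray) -> np.ndarray:
    """Square root of a PSD correlation matrix (eigen-based, singular OK)."""
    w, v = np.linalg.eigh(corr)
    if np.min(w) < -1e-8:
        raise InvalidParameterError(
            f"correlation_targets not positive semidefinite (min eigenvalue {np.min(w):.3g})"
        )
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_ensemble(spec: EnsembleSpec) -> CoordinateEnsemble:
    """Gaussian coordinate ensemble with prescribed inter-residue correlations.

    Isotropic per-residue displacements are built by applying one square-root
    factor of the target correlation matrix identically to the x, y and z
    components, which makes the scalar DCCM equal the target in expectation
    (and exactly for duplicated or mirrored rows).
    """
    factor = _correlation_factor(spec.correlation_targets)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, 3, spec.n_residues))
    disp = spec.fluctuation_scale * np.einsum("fki,ji->fjk", z, factor)
    frames = spec.mean_coordinates[None, :, :] + disp
    return CoordinateEnsemble(frames=frames)


def simulate_melt_curve(
    tm: float,
    steepness: float,
    plateaus: tuple[float, float],
    t_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> MeltCurve:
    """Logistic thermofluor melt curve with additive Gaussian noise.

    F(T) = low + (high - low) / (1 + exp((tm - T)/steepness)); the first
    derivative peaks at tm, matching the derivative-max extraction criterion.
    """
    if steepness <= 0:
        raise InvalidParameterError(f"steepness must be > 0, got {steepness}")
    t = np.asarray(t_grid, dtype=float)
    if t.size < 10:
        raise InvalidParameterError("t_grid needs at least 10 points")
    low, high = plateaus
    f = low + (high - low) / (1.0 + np.exp((tm - t) / steepness))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return MeltCurve(temperature=t, fluorescence=f, label=label)
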