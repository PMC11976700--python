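# Methods

This note records the models, conventions and numerical choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Ratiometric indicator quantification

The chain is: two-wavelength read → indicator deprotonation fraction → pH →
consumed protons → product concentration.

- **Isometric normalization.** The reporter/isosbestic absorbance ratio
  r = A₆₁₆/A₄₉₉ is linear in the deprotonation fraction *f* between the
  calibration endpoints `ratio_acid` (fully protonated) and `ratio_base`
  (fully deprotonated): f = (r − r_acid)/(r_base − r_acid).  Because both
  wavelengths share path length and indicator concentration, *f* is
  invariant under their uniform scaling — the property that makes the assay
  quantitative in a plate format.
- **Calibration is empirical.** The 1:1 methanol quench shifts the apparent
  pKa of both indicator and buffer, so `pka_apparent` (default 7.10 for BTB,
  7.20 for MOPS), `ratio_acid` and `ratio_base` are per-batch calibration
  inputs measured in the quench matrix, never literature constants.
  Temperature dependence of the pKa values is ignored; calibration should be
  performed at assay temperature.
- **Buffer-strength trace-back.** One product molecule consumes one proton
  (strong acid converted to weak acid), so
  Δn = B·(α(pH₁) − α(pH₀)) with α the buffer's conjugate-base fraction.
  Two optional minor terms (indicator self-buffering, change in free
  protons) are implemented but off by default: at 1 mM in-mixture buffer
  and ~0.03 mM indicator they contribute <3% and the upstream calibration
  uncertainty dominates.  The flag exists because it is genuinely unknown
  whether the original analysis included them.
- **Concentration conventions.** Buffer and indicator concentrations are
  expressed in the read mixture; product is reported on the sample scale
  via `dilution_factor` (default 2 for the 100 µL + 100 µL quench).
- **Clamping.** *f* is clamped to [1e−4, 1−1e−4] with a warning — hard
  failure would lose whole wells to a single saturated read.  Product is
  deliberately *not* clamped to [0, S₀]: noise must pass through unbiased
  so that rate fits downstream are not truncation-biased.

## Halide-release quantification

Purely empirical: an ordinary least-squares line through the (0–3.3 mM)
halide standards, intercept fitted (the Fe(SCN)/Hg(SCN)₂ reagent blank has
nonzero absorbance and varies by batch; forcing zero would bias low
concentrations).  r² < 0.98 warns; readings outside the standard range are
returned with an extrapolation warning rather than refused.

## Initial rates and model fits

- **Window rule.** The sampling schedule (30–360 s) targets the linear
  regime; the estimator additionally drops points beyond 10% conversion
  *relative to the first point* (which also makes the slope invariant to a
  constant product offset), keeping at least the three earliest points.
  Blank (no-enzyme) curves are sloped identically and subtracted; standard
  errors combine in quadrature.
- **Units.** 1 mM ≡ 1 µmol/mL, so specific activity is
  v₀ [mM/s] × 60 / loading [mg/mL] in U/mg.  Per-site rate normalization
  divides by the site concentration from loading and a user-supplied
  subunit molar mass — per-subunit by default, configurable, because the
  per-subunit vs per-oligomer convention is not universal.
- **Fitting.** `scipy.optimize.curve_fit` (trust-region with bounds).
  Hill fits multi-start from n_H ∈ {1, 2, 4} (the K₅₀/n_H likelihood ridge
  is shallow) with n_H bounded to [0.3, 10]; initialization uses the
  concentration nearest half-maximal rate and 1.05× the maximal observed
  rate.  Weighting is inverse-variance when aggregated replicate SDs are
  attached, otherwise unweighted on replicate-level points — the generator
  defaults to replicate-level output because duplicate-based SDs make
  erratic weights.  Standard errors are asymptotic (covariance at the
  optimum); the catalytic efficiency k_cat/K_M carries a first-order
  propagated SE using the full covariance.  Hill with n_H pinned at 1
  reproduces the Michaelis–Menten fit (nesting), which the tests assert.

## Enantio- and regioselectivity

- E = ln[1 − C(1+ee_P)]/ln[1 − C(1−ee_P)], the closed form for an
  irreversible, product-inhibition-free resolution.  The first argument is
  computed as (1−C) − C·ee_P to limit cancellation when the fast enantiomer
  is nearly spent.  Display convention: two significant figures, ">200"
  above 200.  Enantiopreference (S/R) is metadata from the chiral analysis,
  never inferred.
- When substrate and product excesses are both measured, conversion follows
  from two-species mass balance C = ee_S/(ee_S + ee_P) and E from the same
  closed form.  For regiodivergent substrates (styrene oxide) this mass
  balance is *not* applied — two regio-products form and the balance does
  not close — so E_β is computed from C_β and ee_Pβ only.
- **Identifiability limit.** Once the fast enantiomer is exhausted
  (C ≥ (1 + x_slow)/2 with x_fast → 1), the pair (C, ee_P) collapses to the
  E = ∞ signature ee_P = (1−C)/C and E is unrecoverable — from real data
  and from doubles alike.  The resolution generator is exact in a
  log-parametrization (u = −ln(1−x_fast)), so it produces the correct
  saturated observables; the round-trip law is asserted only where the pair
  is informative.
- GC peak areas are corrected by per-product response factors (default 1
  with a warning) and normalized to fractions.

## Thermal shift

Tm is the temperature of maximal |dF/dT|: centered moving average (default
window 5 points ≙ 2 °C on the 0.5 °C grid), `numpy.gradient`, then a
quadratic through the peak and its neighbors for sub-grid resolution.  The
absolute-value derivative handles both dye-gain and quench-direction
transitions.  No-transition criteria: amplitude below 5× the smoothing
residual, or derivative peak within one smoothing window of a scan boundary
(the reflect padding distorts the edge region, and a transition that close
to the boundary is truncated anyway).  ΔTm between two curves is a
first-class output since stabilization is reported as a shift.  The vendor
software's exact smoothing is unknown; this implementation states its own.
No two-state ΔH fitting is attempted.

## Shortest path map

- DCCM: C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over frames, displacements
  from per-residue mean positions; a residue with zero fluctuation is an
  error naming the residue.  Reference point per residue is Cα (centroid
  fallback) when reading multi-model PDB.
- Graph: edge iff mean distance < 6 Å and |C| ≥ 0.01 (below that the weight
  −ln|C| ≳ 4.6 and the edge is effectively unusable; dropping it keeps the
  graph sparse and the threshold is exposed).  Natural log; the base only
  rescales all weights uniformly and cannot change which path is shortest.
- All-pairs shortest paths by an explicit binary-heap Dijkstra with
  deterministic tie-breaking (equal-length alternatives resolved toward the
  lowest-index predecessor) so edge-usage counts are reproducible; each
  unordered pair contributes once, bounding usage by n(n−1)/2.  Correctness
  is cross-checked in the tests against exhaustive simple-path enumeration
  on small random graphs.
- The final map keeps edges at or above the 0.8 quantile of positive usages.
  The pruning rule for drawing published maps is not standardized; the
  quantile rule is this package's explicit choice and is a parameter.

## Synthetic generators: what they emulate, and what not

All generators are deterministic given a seed and invert the exact
quantification chain, so generator ∘ quantifier is the identity at zero
noise — the property the round-trip tests exercise.

- **Resolutions**: irreversible two-enantiomer first-order model, rate
  ratio = E (no reversibility, no product inhibition) — the same framework
  the closed-form E assumes, which is what makes the round trip a
  consistency check rather than a tautology on noise.
- **Progress curves**: dP/dt = [E]_site·v(S) + k_bg·S integrated with LSODA
  (rtol 1e−10), background companion in closed form.  Emulates the
  discontinuous 30–360 s sampling with a chemical-background control.
- **Plate reads**: model inversion plus additive Gaussian absorbance noise
  on both wavelengths; rejects (naming the timepoint) curves that exceed
  the buffer capacity or push the indicator outside f ∈ [0.02, 0.98].
- **Rate datasets**: multiplicative Gaussian noise at a given CV, duplicate
  measurements by default — matching the duplicate-reaction design with
  sub-0.2 U/mg reported spreads, which at typical activities is a
  few-percent CV.  Noise magnitudes are chosen to be consistent with those
  reported spreads, not fitted to unpublished replicate data.
- **Ensembles**: isotropic Gaussian displacements built from one symmetric
  square-root factor of the target correlation matrix applied identically
  to x, y, z — the scalar DCCM then equals the target in expectation, and
  exactly ±1 for duplicated/mirrored rows.  The factor is eigendecomposition
  based so singular (PSD) targets are valid.  These are statistical
  stand-ins: no force field, no solvent, no anisotropy, no time
  correlation — so passing SPM tests demonstrates the graph analytics, not
  MD realism.
- **Melt curves**: logistic sigmoid with additive Gaussian noise on the
  10–90 °C, 0.5 °C grid.

What passing the suite does *not* show: agreement with any unpublished raw
plate/GC/fluorescence data; MD-derived correlation structure; multi-substrate
mechanism effects (one species is varied at a time, as in the experimental
design).

## Problem sizes

Stochastic checks use sizes that resolve the assertions comfortably:
12–14 concentrations × duplicates for fit recovery, 200 seeded replicates
for recovery-rate statistics, 2000-frame ensembles for network recovery,
5000 frames where sampling error bounds (~1/√n) are asserted.

## Known limitations

- Single-wavelength-pair spectral model; no deconvolution of additional
  absorbing species.
- Buffer model is a single monoprotic weak acid; polyprotic or mixed
  buffers must be approximated by an effective pKa.
- Fit uncertainties are asymptotic, not bootstrapped (the published ±
  values are assumed to be fit SEs; this is not verifiable from the text).
- The F12H enantioselectivity row in the source data does not reproduce
  from its printed conversion/ee pair (closed form gives ≈14 vs printed
  17); it is excluded from validation fixtures rather than guessed at.
- E-values above ~200 are reported as ">200" because the closed form's
  sensitivity to ee_P near 1 makes larger values quantitatively
  meaningless at GC precision.
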