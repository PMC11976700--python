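# halocat

Analysis chain for halohydrin dehalogenase (HHDH) engineering campaigns:
quantitative plate-assay readouts, enzyme-kinetics fitting, selectivity
metrics, thermal-stability extraction, and residue-communication network
analysis — with a synthetic-data generator that emulates every instrument
input so the whole pipeline is testable offline.

## Who this is for

Enzyme engineers characterizing HHDH variants (or similar lyases) measure
epoxide ring-opening activity with a ratiometric bromothymol-blue (BTB) pH
assay, dehalogenation with a colorimetric halide-release assay, selectivity
by chiral GC, stability by differential scanning fluorimetry, and
conformational communication from MD ensembles.  `halocat` implements the
numerical chain from raw tabular instrument output to the publishable
quantities.

## The models at the core

**Indicator quantification.** Azidolysis of an epoxide consumes one proton
per turnover (HN₃, a strong acid in water at neutral pH, becomes a weak-acid
azido alcohol).  Two-wavelength reads are reduced isometrically —
normalizing the 616 nm reporter band by the 499 nm isosbestic band removes
path length and indicator concentration — giving the deprotonation fraction
*f*, hence pH = pK<sub>a,ind</sub> + log₁₀(*f*/(1−*f*)), and the consumed
protons via the buffer strength:

Δn = B·[α(pH₁) − α(pH₀)],  α(pH) = 1/(1 + 10^(pKa,buf − pH))

**Kinetics.** Initial rates from the early linear window (≤10% conversion,
background-subtracted) are fitted with the hyperbolic law
v = k_cat·S/(K_M + S) or, for cooperative nucleophile/epoxide binding, the
Hill law k_obs = k_obs,max·Sⁿ/(K₅₀ⁿ + Sⁿ).

**Enantioselectivity.** For an irreversible kinetic resolution the
enantiomeric ratio follows in closed form from conversion *C* and product
excess ee_P:

E = ln[1 − C(1 + ee_P)] / ln[1 − C(1 − ee_P)]

**Thermal shift.** T<sub>m</sub> is the temperature of maximal fluorescence
change (smoothed-derivative maximum, quadratically refined).

**Shortest path map (SPM).** From a coordinate ensemble, residue pairs
closer than 6 Å (mean distance) are connected with weight
d<sub>ij</sub> = −ln|C<sub>ij</sub>| from the dynamic cross-correlation
matrix; edges are scored by how many all-pairs shortest paths use them,
tracing correlated-motion pathways.

## Worked example

Simulate an epoxide ring-opening reaction of a high-activity variant
(k_obs,max = 60.2 s⁻¹, K₅₀ = 14.2 mM, n_H = 2.32), read it through the
simulated plate reader, and quantify it back:

```python
import numpy as np
from halocat.indicator_assay import AssayScenario, BufferSpec, quantify_timeseries
from halocat.synthetic_data import TrueKinetics, simulate_progress_curve, \
    simulate_plate_timeseries, simulate_rate_dataset
from halocat.kinetics import fit_hill, initial_rate, specific_activity
from halocat.selectivity import e_from_c_eep

scenario = AssayScenario(
    buffer=BufferSpec(total_conc=1.0, pka_apparent=7.20, initial_ph=7.00),
    substrate0=10.0)                      # 2 mM sample buffer quenched 1:1
truth = TrueKinetics(model="hill", vmax_equivalent=60.2, half_saturation=14.2,
                     hill_n=2.32, background_rate_constant=1e-4)
full, blank = simulate_progress_curve(truth, s0=10.0, enzyme_site_conc=1e-4,
                                      times=[30, 60, 180, 270, 360])
reads = simulate_plate_timeseries(full, scenario)
curve = quantify_timeseries(reads, scenario)
print(np.round(curve.product, 4))
# [0.     0.085  0.1689 0.4949 0.7294 0.9556]   <- mM product, exact round trip

sa = specific_activity(initial_rate(curve), enzyme_loading=0.05)
print(round(sa.value, 3))                 # 3.191 U/mg

data = simulate_rate_dataset(truth, np.geomspace(1, 150, 12),
                             n_replicates=2, cv=0.02, seed=1)
fit = fit_hill(data)
print(f"kobs_max={fit.kobs_max:.1f}  K50={fit.k50:.2f}  nH={fit.n_h:.2f}")
# kobs_max=60.9  K50=14.45  nH=2.28        <- 2% noise, duplicates

print(e_from_c_eep(0.453, 0.938).display)  # "74"
```

The quantified curve is the simulated one to 1e−9 mM (the generator inverts
exactly the chain the quantifier applies); the Hill fit recovers the
generating parameters to a few percent at realistic noise; the E of 74
corresponds to a 45.3% conversion with 93.8% product ee.

A `halocat` console command exposes the same stages
(`quantify`, `halide`, `selectivity`, `tm`, `spm`, `run`); see
`halocat --help`.

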