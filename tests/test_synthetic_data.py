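"""Tests for the synthetic instrument-data generators."""

import numpy as np
import pytest

from halocat.errors import InvalidParameterError, RangeError
from halocat.indicator_assay import quantify_timeseries
from halocat.kinetics import initial_rate
from halocat.synthetic_data import (
    EnsembleSpec,
    ResolutionTruth,
    TrueKinetics,
    simulate_ensemble,
    simulate_melt_curve,
    simulate_plate_timeseries,
    simulate_progress_curve,
    simulate_rate_dataset,
    simulate_resolution_outcome,
)


class TestResolutionGenerator:
    def test_unselective_limit(self):
        obs = simulate_resolution_outcome(ResolutionTruth(e_true=1.0, target_conversion=0.40))
        assert obs.ee_p == 0.0
        assert obs.ee_s == 0.0
        assert obs.conversion == 0.40

    def test_infinite_selectivity_cap(self):
        obs = simulate_resolution_outcome(ResolutionTruth(e_true=1e12, target_conversion=0.30))
        assert obs.ee_p == pytest.approx(1.0, abs=1e-6)

    def test_derived_table_point(self):
        obs = simulate_resolution_outcome(ResolutionTruth(e_true=22.4, target_conversion=0.465))
        assert obs.ee_p == pytest.approx(0.826, abs=5e-4)

    def test_substrate_excess_mass_balance(self):
        obs = simulate_resolution_outcome(ResolutionTruth(e_true=30.0, target_conversion=0.40))
        # two-product mass balance: C = ee_s / (ee_s + ee_p)
        assert obs.ee_s / (obs.ee_s + obs.ee_p) == pytest.approx(0.40, rel=1e-9)


class TestProgressCurves:
    def test_flat_zero_without_enzyme_or_background(self):
        truth = TrueKinetics(model="michaelis_menten", vmax_equivalent=5.0, half_saturation=1.0)
        full, blank = simulate_progress_curve(truth, 10.0, 0.0, [30.0, 60.0, 360.0])
        assert np.allclose(full.product, 0.0)
        assert np.allclose(blank.product, 0.0)

    def test_pure_background_closed_form(self):
        truth = TrueKinetics(model="michaelis_menten", vmax_equivalent=5.0,
                             half_saturation=1.0, background_rate_constant=1e-3)
        full, blank = simulate_progress_curve(truth, 10.0, 0.0, [30.0])
        expected = 10.0 * (1.0 - np.exp(-0.03))
        assert full.product[0] == pytest.approx(expected, rel=1e-6)
        assert blank.product[0] == pytest.approx(expected, rel=1e-9)

    def test_saturating_initial_rate(self):
        truth = TrueKinetics(model="hill", vmax_equivalent=10.0, half_saturation=1.0, hill_n=2.0)
        e_site = 1e-5
        full, _ = simulate_progress_curve(truth, 1000.0, e_site, [1.0, 2.0, 3.0])
        v0 = initial_rate(full).v0
        assert v0 == pytest.approx(e_site * 10.0, rel=0.01)

    def test_monotone_and_bounded(self):
        truth = TrueKinetics(model="hill", vmax_equivalent=60.0, half_saturation=14.0,
                             hill_n=2.3, background_rate_constant=1e-4)
        full, _ = simulate_progress_curve(truth, 10.0, 1e-3, np.linspace(10, 3600, 30))
        assert np.all(np.diff(full.product) >= -1e-12)
        assert np.all(full.product <= 10.0 + 1e-9)

    def test_invalid_inputs(self):
        truth = TrueKinetics(model="michaelis_menten", vmax_equivalent=1.0, half_saturation=1.0)
        with pytest.raises(InvalidParameterError):
            simulate_progress_curve(truth, -1.0, 0.0, [30.0])
        with pytest.raises(InvalidParameterError):
            simulate_progress_curve(truth, 10.0, 0.0, [60.0, 30.0])


class TestPlateGenerator:
    def test_zero_product_constant_ratio(self, scenario):
        from halocat.indicator_assay import ProgressCurve

        curve = ProgressCurve(times=np.array([30.0, 60.0]), product=np.zeros(2), substrate0=10.0)
        ts = simulate_plate_timeseries(curve, scenario)
        ratios = ts.a_report / ts.a_iso
        assert np.allclose(ratios, ratios[0], atol=1e-12)

    def test_noiseless_round_trip_identity(self, scenario, sampling_times):
        truth = TrueKinetics(model="hill", vmax_equivalent=60.2, half_saturation=14.2,
                             hill_n=2.32, background_rate_constant=1e-4)
        full, _ = simulate_progress_curve(truth, 10.0, 1e-4, sampling_times)
        ts = simulate_plate_timeseries(full, scenario, noise_sd=0.0)
        recovered = quantify_timeseries(ts, scenario)
        assert np.max(np.abs(recovered.product[1:] - full.product)) < 1e-9

    def test_noisy_recovery_within_propagated_tolerance(self, scenario, sampling_times):
        truth = TrueKinetics(model="hill", vmax_equivalent=60.2, half_saturation=14.2, hill_n=2.32)
        full, _ = simulate_progress_curve(truth, 10.0, 1e-4, sampling_times)
        noise_sd = 1e-4
        ts = simulate_plate_timeseries(full, scenario, noise_sd=noise_sd, seed=5)
        recovered = quantify_timeseries(ts, scenario)
        # crude propagated bound: d(product)/d(ratio) ~ few mM per ratio unit here
        assert np.max(np.abs(recovered.product[1:] - full.product)) < 3 * noise_sd * 50

    def test_buffer_capacity_excursion_names_timepoint(self, scenario):
        from halocat.indicator_assay import ProgressCurve

        curve = ProgressCurve(times=np.array([30.0, 60.0]), product=np.array([0.1, 50.0]),
                              substrate0=60.0)
        with pytest.raises(RangeError, match="60"):
            simulate_plate_timeseries(curve, scenario)

    def test_seed_determinism(self, scenario, sampling_times):
        from halocat.indicator_assay import ProgressCurve

        curve = ProgressCurve(times=sampling_times, product=np.linspace(0.05, 0.6, 5),
                              substrate0=10.0)
        a = simulate_plate_timeseries(curve, scenario, noise_sd=0.002, seed=9)
        b = simulate_plate_timeseries(curve, scenario, noise_sd=0.002, seed=9)
        assert np.array_equal(a.a_report, b.a_report)
        assert np.array_equal(a.a_iso, b.a_iso)


class TestRateDatasets:
    def test_replicate_layout(self):
        truth = TrueKinetics(model="hill", vmax_equivalent=10.0, half_saturation=5.0, hill_n=2.0)
        ds = simulate_rate_dataset(truth, [1.0, 2.0, 4.0], n_replicates=3, cv=0.02, seed=0)
        assert len(ds.s) == 9 and ds.sd is None

    def test_aggregate_layout(self):
        truth = TrueKinetics(model="hill", vmax_equivalent=10.0, half_saturation=5.0, hill_n=2.0)
        ds = simulate_rate_dataset(truth, [1.0, 2.0, 4.0], n_replicates=4, cv=0.02,
                                   seed=0, aggregate=True)
        assert len(ds.s) == 3 and ds.sd is not None and np.all(ds.sd > 0)

    def test_zero_cv_is_exact(self):
        truth = TrueKinetics(model="michaelis_menten", vmax_equivalent=2.0, half_saturation=1.0)
        ds = simulate_rate_dataset(truth, [0.5, 1.0, 2.0], n_replicates=1, cv=0.0, seed=0)
        assert np.allclose(ds.rate, truth.rate(ds.s))


class TestEnsembleGenerator:
    def test_identity_targets_decorrelate(self):
        spec = EnsembleSpec(mean_coordinates=np.zeros((3, 3)),
                            correlation_targets=np.eye(3), n_frames=5000, seed=0)
        from halocat.spm import dccm

        c = dccm(simulate_ensemble(spec))
        assert np.all(np.abs(c[np.triu_indices(3, 1)]) < 0.1)

    def test_perfect_and_mirrored_targets_exact(self):
        corr = np.array([[1.0, 1.0, -1.0], [1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
        spec = EnsembleSpec(mean_coordinates=np.zeros((3, 3)),
                            correlation_targets=corr, n_frames=100, seed=1)
        from halocat.spm import dccm

        c = dccm(simulate_ensemble(spec))
        assert c[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert c[0, 2] == pytest.approx(-1.0, abs=1e-10)

    def test_non_psd_rejected(self):
        corr = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        spec_kwargs = dict(mean_coordinates=np.zeros((3, 3)), n_frames=100, seed=0)
        with pytest.raises(InvalidParameterError):
            simulate_ensemble(EnsembleSpec(correlation_targets=corr, **spec_kwargs))

    def test_seed_determinism(self):
        spec = EnsembleSpec(mean_coordinates=np.zeros((4, 3)),
                            correlation_targets=np.eye(4), n_frames=50, seed=3)
        assert np.array_equal(simulate_ensemble(spec).frames, simulate_ensemble(spec).frames)


def test_melt_generator_matches_logistic():
    grid = np.arange(10.0, 90.5, 0.5)
    curve = simulate_melt_curve(50.0, 2.0, (0.2, 1.2), grid)
    expected = 0.2 + 1.0 / (1.0 + np.exp((50.0 - grid) / 2.0))
    assert np.allclose(curve.fluorescence, expected, atol=1e-12)
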