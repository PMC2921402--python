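import numpy as np
import pytest

import dielcycle as dc
from dielcycle.histfit import (
    PhaseMixtureModel,
    build_histogram,
    fit_dna_histogram,
    fractions_series,
)


def _sample(events, t=0.0):
    return dc.EventSample(t=t, events=np.asarray(events, dtype=float))


class TestBuildHistogram:
    def test_identical_events_fill_one_bin(self):
        hist = build_histogram(
            _sample(np.full(10, 200.0)), n_bins=256, range_policy=(0, 512),
            min_events=1,
        )
        assert np.count_nonzero(hist.counts) == 1
        assert hist.counts.max() == 10
        assert hist.n_events == 10

    def test_two_values_fill_two_bins(self):
        events = np.concatenate([np.full(6, 200.0), np.full(4, 400.0)])
        hist = build_histogram(
            _sample(events), n_bins=256, range_policy=(0, 512), min_events=1
        )
        assert np.count_nonzero(hist.counts) == 2

    def test_too_few_events_reported_with_count(self):
        with pytest.raises(ValueError, match="42"):
            build_histogram(_sample(np.full(42, 200.0)), min_events=5000)

    def test_out_of_range_events_counted_not_dropped(self):
        events = np.concatenate([np.full(50, 100.0), np.full(7, 900.0)])
        hist = build_histogram(
            _sample(events), n_bins=64, range_policy=(0, 512), min_events=1
        )
        assert hist.n_above == 7
        assert hist.n_events == 50

    def test_simulator_modes_at_gain_and_twice_gain(self, instrument):
        """A mixed G1/G2 sample is bimodal with modes at gain and 2*gain."""
        sample = dc.events_from_fractions(
            [0.55, 0.0, 0.45], 100_000, instrument, seed=4
        )
        hist = build_histogram(sample)
        width = np.diff(hist.bin_edges)[0]
        counts = hist.counts
        lower = counts.copy()
        lower[hist.centers > 300.0] = 0
        upper = counts.copy()
        upper[hist.centers <= 300.0] = 0
        assert abs(hist.centers[np.argmax(lower)] - 200.0) <= width
        assert abs(hist.centers[np.argmax(upper)] - 400.0) <= width


class TestMixtureFit:
    def test_noiseless_two_spike_recovery_is_exact(self):
        events = np.concatenate([np.full(6000, 200.0), np.full(4000, 400.0)])
        hist = build_histogram(_sample(events), range_policy=(0, 512))
        fit = fit_dna_histogram(hist)
        assert fit.f_g1 == pytest.approx(0.60, abs=1e-6)
        assert fit.f_g2 == pytest.approx(0.40, abs=1e-6)
        assert fit.f_s == pytest.approx(0.0, abs=1e-6)

    def test_mixture_recovery_within_tolerance(self, instrument):
        truth = np.array([0.60, 0.25, 0.15])
        sample = dc.events_from_fractions(truth, 100_000, instrument, seed=0)
        fit = fit_dna_histogram(build_histogram(sample))
        assert fit.converged
        assert np.max(np.abs(np.array(fit.fractions) - truth)) <= 0.02
        assert fit.m == pytest.approx(200.0, rel=0.02)
        assert fit.cv == pytest.approx(0.03, rel=0.2)

    def test_all_g1_sample_identified(self, instrument):
        sample = dc.events_from_fractions([1.0, 0.0, 0.0], 50_000, instrument, seed=9)
        fit = fit_dna_histogram(build_histogram(sample))
        assert fit.f_g1 >= 0.98

    def test_fractions_normalized_and_bounded(self, instrument):
        sample = dc.events_from_fractions([0.3, 0.4, 0.3], 50_000, instrument, seed=2)
        fit = fit_dna_histogram(build_histogram(sample))
        assert fit.f_g1 + fit.f_s + fit.f_g2 == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= f <= 1.0 for f in fit.fractions)

    def test_rescaling_fluorescence_axis_leaves_fractions(self, instrument):
        """A global gain change must not move the estimated fractions."""
        sample = dc.events_from_fractions([0.5, 0.3, 0.2], 50_000, instrument, seed=3)
        scaled = dc.EventSample(t=sample.t, events=sample.events * 3.7)
        fit_a = fit_dna_histogram(build_histogram(sample))
        fit_b = fit_dna_histogram(build_histogram(scaled))
        assert np.allclose(fit_a.fractions, fit_b.fractions, atol=0.005)
        assert fit_b.m == pytest.approx(3.7 * fit_a.m, rel=0.01)

    def test_more_events_tighten_recovery(self, instrument):
        """Fraction RMSE at 1e5 events is no worse than at 1e4 events."""
        truth = np.array([0.60, 0.25, 0.15])
        rmse = {}
        for n in (10_000, 100_000):
            errs = []
            for seed in range(20):
                sample = dc.events_from_fractions(truth, n, instrument, seed=seed)
                fit = fit_dna_histogram(build_histogram(sample, min_events=1000))
                errs.append(np.array(fit.fractions) - truth)
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[100_000] <= rmse[10_000]

    def test_degenerate_single_bin_rejected(self):
        hist = build_histogram(
            _sample(np.full(6000, 200.0)), range_policy=(0, 512), min_events=1
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit_dna_histogram(hist)

    def test_free_ratio_stays_near_two(self, instrument):
        sample = dc.events_from_fractions([0.5, 0.2, 0.3], 80_000, instrument, seed=6)
        fit = fit_dna_histogram(build_histogram(sample), free_ratio=True)
        assert 1.9 <= fit.r <= 2.1

    def test_sklearn_param_interface(self):
        model = PhaseMixtureModel(n_s_segments=12)
        params = model.get_params()
        assert params["n_s_segments"] == 12
        clone = PhaseMixtureModel().set_params(**params)
        assert clone.get_params() == params


class TestFractionsSeries:
    def test_duplicate_samples_give_identical_fractions(self, instrument):
        base = dc.events_from_fractions([0.6, 0.2, 0.2], 20_000, instrument, seed=1)
        samples = [
            dc.EventSample(t=float(t), events=base.events) for t in (6.0, 9.0, 12.0, 15.0)
        ]
        series = fractions_series(samples)
        assert np.ptp(series.f_s) == 0.0
        assert np.ptp(series.f_g1) == 0.0

    def test_all_g1_series_is_flat(self, instrument):
        samples = [
            dc.events_from_fractions([1.0, 0.0, 0.0], 20_000, instrument, seed=s, t=float(3 * s))
            for s in range(5)
        ]
        series = fractions_series(samples)
        assert np.all(series.f_g1 > 0.97)

    def test_too_few_timepoints_rejected(self, instrument):
        samples = [
            dc.events_from_fractions([1.0, 0.0, 0.0], 20_000, instrument, seed=s, t=float(s))
            for s in range(3)
        ]
        with pytest.raises(ValueError, match="4 usable"):
            fractions_series(samples)

    def test_tracks_simulated_wave_shape(self, hl_sim):
        """Fitted f_S rises and falls with the simulated replication wave."""
        result, samples = hl_sim
        series = fractions_series(samples)
        truth = result.truth
        # the fitted S curve must correlate strongly with the truth curve
        r = np.corrcoef(series.f_s, truth.f_s)[0, 1]
        assert r > 0.95
        # and peak within one sampling step of the true peak
        assert abs(
            int(np.argmax(series.f_s)) - int(np.argmax(truth.f_s))
        ) <= 1
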