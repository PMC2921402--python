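import numpy as np
import pytest

import dielcycle as dc
from dielcycle import growth, timing
from dielcycle.reference import batch_columns
from dielcycle.timing import (
    FlatSeriesError,
    estimate_delay,
    estimate_phase_durations,
    find_phase_peaks,
    sync_index,
    t_g1_from_identity,
)

LN2 = np.log(2.0)


def bump_series(t_s_peak=18.0, t_g2_peak=22.0, width=1.5, n=24, amp=0.6):
    """Smooth circular Gaussian bumps for f_S and f_G2 on an hourly grid."""
    t = np.arange(n) * (24.0 / n)

    def bump(center):
        d = np.minimum(np.abs(t - center), 24.0 - np.abs(t - center))
        return amp * np.exp(-0.5 * (d / width) ** 2)

    f_s = bump(t_s_peak)
    f_g2 = bump(t_g2_peak)
    return dc.PhaseFractionSeries(t=t, f_g1=1 - f_s - f_g2, f_s=f_s, f_g2=f_g2)


class TestFindPhasePeaks:
    def test_hl_pattern_peaks_four_hours_apart(self):
        """S peak at dusk, G2 peak 4 h later: the high-light batch pattern."""
        peaks = find_phase_peaks(bump_series(18.0, 22.0))
        assert peaks.t_s_max == pytest.approx(18.0, abs=0.05)
        assert peaks.t_g2_max == pytest.approx(22.0, abs=0.05)
        assert peaks.delta_t == pytest.approx(4.0, abs=0.1)

    def test_off_grid_peak_refined_subsample(self):
        peaks = find_phase_peaks(bump_series(17.6, 21.6), window=1)
        assert peaks.t_s_max == pytest.approx(17.6, abs=0.1)

    def test_wave_across_midnight_not_clipped(self):
        """Circular handling: a G2 peak just after midnight still works."""
        peaks = find_phase_peaks(bump_series(20.0, 0.5))
        assert peaks.delta_t == pytest.approx(4.5, abs=0.1)

    def test_identical_curves_give_zero_delay(self):
        series = bump_series(18.0, 18.0, amp=0.4)
        peaks = find_phase_peaks(series)
        assert peaks.delta_t == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError, match="coincide"):
            estimate_phase_durations(peaks, series, mu_cc=0.67)

    def test_flat_series_raises(self):
        t = np.arange(24.0)
        flat = dc.PhaseFractionSeries(
            t=t, f_g1=np.full(24, 0.8), f_s=np.full(24, 0.1), f_g2=np.full(24, 0.1)
        )
        with pytest.raises(FlatSeriesError):
            find_phase_peaks(flat)

    def test_degenerate_simulation_delay_exact(self, degenerate_sim):
        peaks = find_phase_peaks(degenerate_sim.truth, window=1)
        assert peaks.delta_t == pytest.approx(4.0, abs=1e-9)

    def test_peak_delay_matches_half_summed_durations(self):
        """Peak-to-peak delay equals (T_S + T_G2)/2 for a resolved wave."""
        params = dc.SimParams(
            n0=20_000, sigma_sync=1.0, jitter_s=0.0, jitter_g2=0.0,
            frac_arrested=0.0, t_s=3.0, t_g2=5.0, seed=7,
        )
        res = dc.simulate_population(
            params, sample_times=np.arange(0, 24, 0.25), n_days=1
        )
        peaks = find_phase_peaks(res.truth, window=1)
        assert peaks.delta_t == pytest.approx((3.0 + 5.0) / 2, abs=0.3)


class TestPhaseDurations:
    def test_equal_areas_split_durations_evenly(self):
        series = bump_series(18.0, 22.0)
        peaks = find_phase_peaks(series, window=1)
        durations = estimate_phase_durations(peaks, series, mu_cc=0.67)
        assert durations.t_s_plus_g2 == pytest.approx(2 * peaks.delta_t, abs=1e-9)
        assert durations.t_s == pytest.approx(durations.t_g2, abs=0.05)
        assert durations.t_g1 == pytest.approx(16.8, abs=0.1)

    def test_generation_time_identity_closed_forms(self):
        assert t_g1_from_identity(0.68, 6.0) == pytest.approx(18.46, abs=0.005)
        assert t_g1_from_identity(24 * LN2 / 24.0, 8.0) == pytest.approx(16.0)

    def test_inconsistent_inputs_raise(self):
        series = bump_series(18.0, 22.0)
        peaks = find_phase_peaks(series, window=1)
        with pytest.raises(ValueError, match="inconsistent"):
            estimate_phase_durations(peaks, series, mu_cc=3.0)

    def test_identity_reproduces_printed_g1_across_batch_columns(self):
        """24 ln2/mu - (T_S+T_G2) recovers every published batch T_G1.

        The comparison tolerance per column combines the reconstruction
        slack (0.1 h) with the propagated rounding of the printed two-
        decimal growth rate, |dT/dmu| * 0.005 = 24 ln2 * 0.005 / mu^2,
        which dominates for slow-growing columns.
        """
        for key, vals in batch_columns().items():
            mu = vals["mu_cc"]
            predicted = t_g1_from_identity(mu, vals["t_s"] + vals["t_g2"])
            tol = 0.1 + 24 * LN2 * 0.005 / mu**2
            assert predicted == pytest.approx(vals["t_g1"], abs=tol), key


class TestSyncIndex:
    def test_perfect_synchrony_gives_zero(self, degenerate_sim):
        assert sync_index(degenerate_sim.truth) == pytest.approx(0.0, abs=0.2)

    def test_wider_entry_spread_increases_index(self):
        values = []
        for sigma in (0.25, 0.75, 1.5, 3.0):
            params = dc.SimParams(
                n0=10_000, sigma_sync=sigma, jitter_s=0.0, jitter_g2=0.0,
                frac_arrested=0.0, seed=3,
            )
            res = dc.simulate_population(
                params, sample_times=np.arange(0, 24, 0.5), n_days=1
            )
            values.append(sync_index(res.truth))
        assert np.all(np.diff(values) > 0)

    def test_uniform_curve_gives_metric_maximum(self):
        t = np.arange(24.0)
        flat = dc.PhaseFractionSeries(
            t=t, f_g1=np.full(24, 0.5), f_s=np.full(24, 0.3), f_g2=np.full(24, 0.2)
        )
        assert sync_index(flat) == pytest.approx(timing.SYNC_INDEX_MAX)


class TestEstimateDelay:
    def test_self_delay_is_zero(self):
        series = bump_series(18.0, 22.0)
        assert estimate_delay(series, series) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_two_hour_shift_recovered_exactly(self):
        a = bump_series(18.0, 22.0)
        b = bump_series(20.0, 0.0)
        assert estimate_delay(a, b, phase="S") == pytest.approx(2.0, abs=1e-9)

    def test_antisymmetry(self):
        a = bump_series(18.0, 22.0)
        b = bump_series(20.5, 23.5)
        lag_ab = estimate_delay(a, b)
        lag_ba = estimate_delay(b, a)
        assert lag_ab == pytest.approx(-lag_ba, abs=1e-9)

    def test_flat_series_rejected(self):
        a = bump_series(18.0, 22.0)
        t = np.arange(24.0)
        flat = dc.PhaseFractionSeries(
            t=t, f_g1=np.full(24, 0.9), f_s=np.full(24, 0.05), f_g2=np.full(24, 0.05)
        )
        with pytest.raises(FlatSeriesError):
            estimate_delay(a, flat)

    def test_different_grids_resampled(self):
        a = bump_series(18.0, 22.0, n=24)
        b = bump_series(20.0, 0.0, n=48)
        assert estimate_delay(a, b) == pytest.approx(2.0, abs=0.1)
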