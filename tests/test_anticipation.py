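import numpy as np
import pytest

from ptarmigan_rhythms.anticipation import (dawn_profile, fit_segmented,
                                            secondary_peak,
                                            summarize_breakpoints, zt_to_hhmm)
from ptarmigan_rhythms.light import SP_PROTOCOL, build_light_schedule
from ptarmigan_rhythms.series import ActivitySeries, TbSeries
from ptarmigan_rhythms.simulate import HusbandryLog


def make_tb(values, interval=1.0, bird="b"):
    t = interval * np.arange(len(values))
    return TbSeries(bird, "SP", t, np.asarray(values, dtype=float), interval)


def brute_force_hinge(x, y, grid_step=1.0 / 60.0):
    """Exhaustive 1-minute grid search oracle for the hinge RSS minimum."""
    best = (None, np.inf)
    lo, hi = x[1], x[-2]
    for psi in np.arange(lo + 1e-9, hi - 1e-9, grid_step):
        design = np.column_stack([np.ones_like(x), x, np.maximum(0, x - psi)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ beta) ** 2))
        if rss < best[1] - 1e-15:
            best = (psi, rss)
    return best


class TestDawnProfile:
    def _schedule(self, n_days=8):
        return build_light_schedule(SP_PROTOCOL, n_days)

    def test_constant_tb_gives_constant_grid_means(self):
        tb = make_tb([40.0] * 8 * 24)
        prof = dawn_profile(tb, self._schedule(), days=range(1, 6))
        np.testing.assert_array_equal(prof.tb_mean, 40.0)
        np.testing.assert_array_equal(prof.offsets,
                                      [-5.0, -4.0, -3.0, -2.0, -1.0, 0.0, 1.0])

    def test_constant_activity_gives_unit_presample_means(self):
        tb = make_tb([40.0] * 8 * 24)
        act = ActivitySeries("b", "SP", np.arange(8 * 1440) / 60.0,
                             np.ones(8 * 1440))
        prof = dawn_profile(tb, self._schedule(), days=range(1, 6), activity=act)
        np.testing.assert_allclose(prof.act_mean, 1.0)

    def test_matches_brute_force_day_averaging(self, rng):
        vals = 40.0 + rng.random(8 * 24)
        tb = make_tb(vals)
        days = [1, 2, 3, 4, 5]
        prof = dawn_profile(tb, self._schedule(), days=days)
        # oracle: lights-on at clock 0, so grid hours are 19..24+1 of day d-1
        for j, off in enumerate([-5, -4, -3, -2, -1, 0, 1]):
            expected = np.mean([vals[24 * d + off] for d in days])
            assert prof.tb_mean[j] == pytest.approx(expected, abs=1e-12)

    def test_husbandry_day_excluded(self):
        tb = make_tb([40.0] * 8 * 24)
        # visit at 2 h before lights-on of day 3 (t = 70)
        log = HusbandryLog(visits=np.array([70.0]), mode="fixed-time",
                           n_days=8)
        prof = dawn_profile(tb, self._schedule(), days=range(1, 6),
                            husbandry=log)
        assert prof.excluded_days == [3]
        assert prof.n_days == 4

    def test_too_few_days_rejected(self):
        tb = make_tb([40.0] * 8 * 24)
        with pytest.raises(ValueError, match="5 days"):
            dawn_profile(tb, self._schedule(), days=[1, 2, 3])


class TestHingeFit:
    def test_exact_hinge_recovered_noiselessly(self):
        """Flat at 40.0 until t = -3, then +0.5 °C/h: psi, slopes exact."""
        x = np.arange(-5.0, 2.0)
        y = 40.0 + 0.5 * np.maximum(0.0, x + 3.0)
        fit = fit_segmented(x, y)
        assert fit.psi == pytest.approx(-3.0, abs=1e-6)
        assert fit.slope_pre == pytest.approx(0.0, abs=1e-9)
        assert fit.slope_post == pytest.approx(0.5, abs=1e-9)
        assert fit.anticipatory and fit.identifiable

    def test_matches_exhaustive_grid_search_on_noisy_data(self, rng):
        x = np.arange(-5.0, 2.0)
        for _ in range(10):
            y = np.maximum(0.0, x + 2.5) * 0.6 + rng.normal(0, 0.1, len(x))
            fit = fit_segmented(x, y)
            psi_oracle, rss_oracle = brute_force_hinge(x, y)
            assert fit.rss <= rss_oracle + 1e-12
            assert abs(fit.psi - psi_oracle) <= 1.0 / 60.0 + 1e-9

    def test_pure_line_reduces_to_single_segment_rss(self, rng):
        """beta2 = 0 data: hinge RSS matches ordinary regression RSS."""
        x = np.arange(-5.0, 2.0)
        y = 1.0 + 0.3 * x + rng.normal(0, 0.05, len(x))
        fit = fit_segmented(x, y)
        design = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss_line = float(np.sum((y - design @ beta) ** 2))
        assert fit.rss <= rss_line + 1e-9

    def test_flat_data_flagged_non_identifiable(self):
        x = np.arange(-5.0, 2.0)
        fit = fit_segmented(x, np.full_like(x, 40.0))
        assert not fit.identifiable

    def test_declining_post_slope_flagged_not_forced(self):
        x = np.arange(-5.0, 2.0)
        y = -0.5 * np.maximum(0.0, x + 2.0)
        fit = fit_segmented(x, y)
        assert not fit.anticipatory
        assert fit.slope_post < fit.slope_pre

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            fit_segmented([0, 1, 2], [1, 2, 3])

    def test_bias_under_default_noise_below_10_minutes(self, rng):
        """200 noisy replicates at the default profile noise level:
        mean breakpoint bias < 10 min for a true onset 3 h before dawn."""
        x = np.arange(-5.0, 2.0)
        true_psi = -3.0
        noise_sd = 0.15 / np.sqrt(5)  # 5-day mean of hourly noise
        slope = 2.0 / 4.0  # ~2 °C rise over the 4 h to saturation
        psis = []
        for _ in range(200):
            y = slope * np.maximum(0.0, x - true_psi) + rng.normal(0, noise_sd, len(x))
            psis.append(fit_segmented(x, y).psi)
        assert abs(np.mean(psis) - true_psi) < 10.0 / 60.0


class TestSummaries:
    class F:
        def __init__(self, psi):
            self.psi = psi

    def test_two_point_mean_and_sd(self):
        # fits at ZT 21:00 and 21:30 -> mean 21:15, SD ~21 min
        s = summarize_breakpoints([self.F(-3.0), self.F(-2.5)])
        assert s.mean_zt == pytest.approx(21.25)
        assert s.sd_h * 60 == pytest.approx(21.2, abs=0.2)
        assert zt_to_hhmm(s.mean_zt) == "ZT 21:15"

    def test_identical_fits_have_zero_sd(self):
        s = summarize_breakpoints([self.F(-2.0), self.F(-2.0)])
        assert s.sd_h == 0.0

    def test_single_fit_sd_undefined(self):
        s = summarize_breakpoints([self.F(-2.0)])
        assert s.sd_h is None
        assert "undefined" in str(s)


class TestSecondaryPeak:
    def test_triangular_bump_recovered_exactly(self):
        """A single symmetric bump at ZT 12 in an otherwise flat dark phase."""
        sched = build_light_schedule(SP_PROTOCOL, 6)
        day = np.full(24, 40.0)
        for k, h in ((10, 0.2), (11, 0.5), (12, 1.0), (13, 0.5), (14, 0.2)):
            day[k] += h
        tb = make_tb(np.tile(day, 6))
        mean, sd, peaks = secondary_peak(tb, sched, "dark", range(1, 6))
        assert mean == pytest.approx(12.0)
        assert sd == 0.0 and len(peaks) == 5

    def test_matches_bruteforce_smoothed_argmax(self, rng):
        sched = build_light_schedule(SP_PROTOCOL, 6)
        day = np.full(24, 40.0)
        day[10:15] += [0.3, 0.8, 1.5, 0.8, 0.3]
        vals = np.tile(day, 6) + rng.normal(0, 0.05, 6 * 24)
        tb = make_tb(vals)
        mean, sd, peaks = secondary_peak(tb, sched, "dark", [2])
        # oracle: circular 3-point moving average, interior max in dark window
        x = tb.tb[2 * 24:3 * 24]
        sm = np.convolve(np.r_[x[-1:], x, x[:1]], np.ones(3) / 3, "valid")
        win = np.arange(24)[(np.arange(24) >= 8.0)]
        sub = sm[win]
        interior = [i for i in range(1, len(sub) - 1)
                    if sub[i] > sub[i - 1] and sub[i] >= sub[i + 1]]
        expected = win[max(interior, key=lambda i: sub[i])]
        assert peaks[0] == pytest.approx(float(expected))

    def test_monotone_window_skips_day(self):
        sched = build_light_schedule(SP_PROTOCOL, 6)
        day = 41.0 - np.linspace(0, 1, 24)  # strictly decreasing all day
        tb = make_tb(np.tile(day, 6))
        mean, sd, peaks = secondary_peak(tb, sched, "dark", range(1, 6))
        assert peaks == [] and mean is None

    def test_invalid_phase_rejected(self):
        sched = build_light_schedule(SP_PROTOCOL, 6)
        with pytest.raises(ValueError, match="phase"):
            secondary_peak(make_tb([40.0] * 144), sched, "dusk", [1])
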