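import numpy as np
import pytest

from ptarmigan_rhythms.light import (DD_PROTOCOL, LL_PROTOCOL, SP_PROTOCOL,
                                     build_light_schedule)
from ptarmigan_rhythms.simulate import (BirdParams, simulate_activity,
                                        simulate_husbandry, simulate_tb,
                                        TB_RESOLUTION_C)


class TestTbGenerator:
    def test_deterministic_given_seed(self, sp_bird_params, sp_schedule):
        a = simulate_tb(sp_bird_params, sp_schedule)
        b = simulate_tb(sp_bird_params, sp_schedule)
        np.testing.assert_array_equal(a.tb, b.tb)

    def test_output_quantized_to_logger_resolution(self, sp_bird_params, sp_schedule):
        tb = simulate_tb(sp_bird_params, sp_schedule)
        scaled = tb.tb / TB_RESOLUTION_C
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)

    def test_noiseless_daily_range_equals_target_exactly(self):
        """With no noise, bumps or spikes the calibrated template amplitude
        reproduces the target range in every day (up to quantization)."""
        p = BirdParams(bird_id="x", seed=0, target_daily_range=2.0,
                       noise_sd_tb=0.0, ramp_onset_zt=21.0)
        sched = build_light_schedule(SP_PROTOCOL, 5)
        tb = simulate_tb(p, sched)
        ranges = np.ptp(tb.tb.reshape(5, 24), axis=1)
        np.testing.assert_allclose(ranges, 2.0, atol=TB_RESOLUTION_C)

    def test_calibration_within_2pct_over_1000_days(self):
        """Mean observed daily range tracks target_daily_range to 2 %."""
        sched = build_light_schedule(SP_PROTOCOL, 1000)
        p = BirdParams(bird_id="x", seed=7, target_daily_range=2.52,
                       ramp_onset_zt=21.0 + 4 / 60.0,
                       nocturnal_peak_zt=11.0, nocturnal_peak_height=0.6)
        ranges = np.ptp(simulate_tb(p, sched).tb.reshape(1000, 24), axis=1)
        assert abs(ranges.mean() - 2.52) / 2.52 < 0.02

        dd = build_light_schedule(DD_PROTOCOL, 1000)
        hus = simulate_husbandry(dd, "randomized", seed=3)
        pdd = BirdParams(bird_id="d", seed=8, target_daily_range=1.30)
        ranges = np.ptp(simulate_tb(pdd, dd, husbandry=hus).tb.reshape(1000, 24),
                        axis=1)
        assert abs(ranges.mean() - 1.30) / 1.30 < 0.02

    def test_light_phase_warmer_than_dark_phase(self, cohort1):
        """Entrained cohorts: mean Tb in light exceeds mean Tb in dark."""
        for treatment in ("SP", "LP"):
            sched = cohort1.schedules[treatment]
            for s in cohort1.tb_by_treatment(treatment):
                light = sched.is_light(s.t)
                assert s.tb[light].mean() > s.tb[~light].mean()

    def test_infeasible_target_range_rejected(self):
        sched = build_light_schedule(DD_PROTOCOL, 20)
        hus = simulate_husbandry(sched, "fixed-time", fixed_hour=9.0)
        p = BirdParams(bird_id="x", seed=0, target_daily_range=0.05)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_tb(p, sched, husbandry=hus)

    def test_constant_conditions_damp_24h_template(self):
        """Under constant darkness with zero noise and no visits the series
        is flat at the (quantized) mesor: no residual circadian component."""
        sched = build_light_schedule(DD_PROTOCOL, 600)
        p = BirdParams(bird_id="x", seed=1, target_daily_range=1.30)
        tb = simulate_tb(p, sched).tb
        # range comes from noise extremes only: day-mean profile is flat
        profile = tb.reshape(600, 24).mean(axis=0)
        assert np.ptp(profile) < 0.1  # no systematic daily waveform

    def test_half_hour_sampling_supported(self, sp_bird_params):
        sched = build_light_schedule(SP_PROTOCOL, 4)
        tb = simulate_tb(sp_bird_params, sched, sampling_interval=0.5)
        assert len(tb) == 4 * 48
        assert tb.sampling_interval == 0.5


class TestActivityGenerator:
    def test_dark_phase_silent_before_onset(self):
        """With onset at lights-on, every dark-phase count is zero."""
        p = BirdParams(bird_id="x", seed=3, activity_onset_zt=24.0)
        sched = build_light_schedule(SP_PROTOCOL, 3)
        act = simulate_activity(p, sched)
        dark = ~sched.is_light(act.t)
        assert act.counts[dark].max() == 0.0

    def test_anticipatory_ramp_precedes_lights_on(self):
        p = BirdParams(bird_id="x", seed=3, activity_onset_zt=22.0,
                       light_rate_cpm=60.0)
        sched = build_light_schedule(SP_PROTOCOL, 10)
        act = simulate_activity(p, sched)
        zt = act.t % 24.0
        pre_dawn = act.counts[(zt >= 23.0) & (zt < 24.0)].mean()
        silent = act.counts[(zt >= 12.0) & (zt < 21.0)].mean()
        assert pre_dawn > 5 * max(silent, 0.01)

    def test_mean_counts_scale_linearly_with_rate(self):
        """Doubling the rate parameter doubles total counts within 5 %."""
        sched = build_light_schedule(SP_PROTOCOL, 14)
        lo = simulate_activity(BirdParams(bird_id="x", seed=5,
                                          light_rate_cpm=10.0), sched)
        hi = simulate_activity(BirdParams(bird_id="x", seed=5,
                                          light_rate_cpm=20.0), sched)
        assert hi.counts.sum() / lo.counts.sum() == pytest.approx(2.0, rel=0.05)

    def test_deterministic_given_seed(self):
        p = BirdParams(bird_id="x", seed=11, ultradian_relamp=0.9)
        sched = build_light_schedule(LL_PROTOCOL, 5)
        a = simulate_activity(p, sched)
        b = simulate_activity(p, sched)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestHusbandry:
    def test_fixed_time_visits_every_day_same_hour(self):
        sched = build_light_schedule(SP_PROTOCOL, 20)
        log = simulate_husbandry(sched, "fixed-time", fixed_hour=9.0)
        assert len(log.visits) == 20
        assert np.all(log.visits % 24.0 == 9.0)

    def test_randomized_log_reproducible(self):
        sched = build_light_schedule(DD_PROTOCOL, 20)
        a = simulate_husbandry(sched, "randomized", seed=42)
        b = simulate_husbandry(sched, "randomized", seed=42)
        np.testing.assert_array_equal(a.visits, b.visits)
        c = simulate_husbandry(sched, "randomized", seed=43)
        assert not np.array_equal(a.visits, c.visits)

    def test_visits_confined_to_window(self):
        sched = build_light_schedule(DD_PROTOCOL, 30)
        log = simulate_husbandry(sched, "randomized", seed=1, window=(8.0, 16.0))
        hours = log.visits % 24.0
        assert hours.min() >= 8.0 and hours.max() < 16.0

    def test_invalid_mode_rejected(self):
        sched = build_light_schedule(DD_PROTOCOL, 5)
        with pytest.raises(ValueError, match="mode"):
            simulate_husbandry(sched, "weekly")
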