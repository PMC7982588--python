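import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptarmigan_rhythms.light import SP_PROTOCOL, DD_PROTOCOL, build_light_schedule
from ptarmigan_rhythms.series import (ActivitySeries, TbSeries, bin_series,
                                      normalize_activity, read_series,
                                      to_zeitgeber, write_series)


def make_tb(n=48, interval=1.0, value=41.0):
    t = interval * np.arange(n)
    return TbSeries("B1", "SP", t, np.full(n, value), sampling_interval=interval)


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        tb = TbSeries("B1", "SP", np.arange(72.0),
                      np.round(40 + rng.random(72), 4))
        path = tmp_path / "tb.csv"
        write_series(tb, path)
        back = read_series(path, "tb", treatment="SP")
        np.testing.assert_array_equal(back.t, tb.t)
        np.testing.assert_array_equal(back.tb, tb.tb)
        assert back.bird_id == "B1"

        act = ActivitySeries("B1", "SP", np.arange(600) / 60.0,
                             rng.poisson(5, 600).astype(float))
        path2 = tmp_path / "act.csv"
        write_series(act, path2)
        back2 = read_series(path2, "activity", treatment="SP",
                            sampling_interval=1 / 60.0)
        np.testing.assert_allclose(back2.t, act.t, atol=1e-9)
        np.testing.assert_array_equal(back2.counts, act.counts)

    def test_48_day_hourly_fixture_has_1152_samples(self, tmp_path):
        from ptarmigan_rhythms.simulate import BirdParams, simulate_tb

        sched = build_light_schedule(SP_PROTOCOL, 48)
        tb = simulate_tb(BirdParams(bird_id="X", seed=0), sched)
        path = tmp_path / "tb.csv"
        write_series(tb, path)
        assert len(read_series(path, "tb")) == 48 * 24 == 1152

    def test_duplicated_timestamp_rejected(self, tmp_path):
        df = pd.DataFrame({"bird_id": "b", "day": [0, 0, 0], "zt_hour": [0, 1, 1],
                           "tb_c": [40.0, 40.5, 40.5]})
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="increasing|uniform"):
            read_series(path, "tb")

    def test_non_uniform_sampling_names_first_offender(self, tmp_path):
        df = pd.DataFrame({"bird_id": "b", "day": 0, "zt_hour": [0, 1, 3, 4],
                           "tb_c": 40.0})
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="3"):
            read_series(path, "tb", sampling_interval=1.0)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("bird_id,day,zt_hour,tb_c\nb,0,0,40.0\nb,0,oops,40.5\n")
        with pytest.raises(ValueError, match="line 3"):
            read_series(path, "tb")

    def test_tb_outside_calibration_range_rejected(self):
        with pytest.raises(ValueError, match="35"):
            make_tb(value=50.0)


class TestNormalize:
    def test_scales_by_bird_maximum(self):
        act = ActivitySeries("b", "SP", np.arange(3) / 60.0,
                            np.array([0.0, 5.0, 10.0]))
        out = normalize_activity(act)
        np.testing.assert_array_equal(out.counts, [0.0, 0.5, 1.0])
        assert out.normalized

    def test_all_zero_series_flagged(self):
        act = ActivitySeries("b", "SP", np.arange(5) / 60.0, np.zeros(5))
        out = normalize_activity(act)
        assert out.all_zero and out.normalized
        assert (out.counts == 0).all()

    def test_idempotent(self):
        act = ActivitySeries("b", "SP", np.arange(4) / 60.0,
                            np.array([1.0, 2.0, 3.0, 4.0]))
        once = normalize_activity(act)
        twice = normalize_activity(once)
        np.testing.assert_array_equal(once.counts, twice.counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ActivitySeries("b", "SP", np.arange(2) / 60.0, np.array([1.0, -2.0]))


class TestBinning:
    def test_sum_of_sixty_minutes(self):
        act = ActivitySeries("b", "SP", np.arange(60) / 60.0, np.ones(60))
        out = bin_series(act, 1.0, "sum")
        assert len(out) == 1 and out.counts[0] == 60.0
        assert out.sampling_interval == 1.0

    def test_mean_of_constant_is_constant(self):
        tb = make_tb(48, value=41.25)
        out = bin_series(tb, 4.0, "mean")
        assert (out.tb == 41.25).all() and len(out) == 12

    def test_matches_brute_force_on_random_series(self, rng):
        vals = rng.random(1000)
        act = ActivitySeries("b", "SP", np.arange(1000) / 60.0, vals,
                             sampling_interval=1 / 60.0)
        out = bin_series(act, 0.25, "sum")  # 15-minute bins
        expected = [vals[i * 15:(i + 1) * 15].sum() for i in range(1000 // 15)]
        np.testing.assert_allclose(out.counts, expected, rtol=1e-12)

    def test_sum_binning_conserves_total_up_to_tail(self, rng):
        vals = rng.random(1000)
        act = ActivitySeries("b", "SP", np.arange(1000) / 60.0, vals)
        out = bin_series(act, 0.5, "sum")
        kept = (1000 // 30) * 30
        assert out.counts.sum() == pytest.approx(vals[:kept].sum(), rel=1e-12)

    def test_incompatible_bin_width_rejected(self):
        tb = make_tb(48)
        with pytest.raises(ValueError, match="multiple"):
            bin_series(tb, 1.5)


class TestZeitgeber:
    def test_sample_before_lights_on_wraps_to_zt23(self):
        from ptarmigan_rhythms.light import LightProtocol, build_light_schedule

        proto = LightProtocol("SP8", ((0, 6.0, 8.0),))  # lights-on at 08:00
        sched = build_light_schedule(proto, 2)
        tb = make_tb(48)
        out = to_zeitgeber(tb, sched)
        assert out.zt[7] == 23.0  # clock 07:00
        assert out.zt[8] == 0.0   # exactly at lights-on

    def test_sp_light_phase_samples_have_zt_below_6(self, sp_schedule):
        tb = make_tb(48 * 24)
        out = to_zeitgeber(tb, sp_schedule)
        light = sp_schedule.is_light(out.t)
        assert (out.zt[light] < 6.0).all()
        assert (out.zt[~light] >= 6.0).all()

    def test_constant_darkness_has_no_zeitgeber(self):
        sched = build_light_schedule(DD_PROTOCOL, 2)
        with pytest.raises(ValueError, match="ZT undefined"):
            to_zeitgeber(make_tb(48), sched)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=1, max_value=20), st.integers(min_value=0, max_value=2**31 - 1))
def test_binning_output_length_matches_floor(k, seed):
    """bin_series output length is floor(n / k) for any bin multiple k."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(k, 300))
    act = ActivitySeries("b", "SP", np.arange(n) / 60.0, rng.random(n))
    out = bin_series(act, k / 60.0, "mean")
    assert len(out) == n // k
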