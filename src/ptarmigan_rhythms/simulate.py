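"""Synthetic Tb and activity generator with range calibration.

The generator emulates the statistical structure of core body temperature
(Tb) and locomotor activity recordings in an arctic galliform under four
light regimes:

* entrained days (0 < photoperiod < 24): a mesor-centred 24 h template —
  dark trough, linear anticipatory ramp starting at ``ramp_onset_zt`` and
  saturating 1 h after lights-on, light-phase plateau, post-dusk decay —
  plus optional Gaussian Tb bumps (a long-photoperiod "afternoon peak" and
  a short-photoperiod nocturnal bump);
* constant light/darkness: the 24 h template amplitude is zero and the
  observed daily range arises from noise extremes (and husbandry masking);
* additive Gaussian sensor noise, exponential-decay stress spikes at
  husbandry visits, and quantization to the 0.0625 °C logger resolution.

The free scale (template amplitude under entrained schedules, noise SD
under constant conditions) is auto-calibrated by root-finding against a
fixed-seed Monte-Carlo estimate so that the *expected* observed daily
max − min equals ``target_daily_range``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .light import LightSchedule
from .series import ActivitySeries, TbSeries

__all__ = [
    "BirdParams",
    "HusbandryLog",
    "simulate_tb",
    "simulate_activity",
    "simulate_husbandry",
    "quantize_tb",
    "TB_RESOLUTION_C",
]

TB_RESOLUTION_C = 0.0625  # logger quantization step
_CALIBRATION_SEED = 20210308
_CALIBRATION_DAYS = 400


@dataclass(frozen=True)
class BirdParams:
    """Per-bird generator parameters (temperatures in °C, times in ZT hours)."""

    bird_id: str
    seed: int
    mesor: float = 40.8
    target_daily_range: float = 2.5
    noise_sd_tb: float = 0.15
    ramp_onset_zt: float = 21.0
    activity_onset_zt: float = 22.0
    ramp_saturation_h: float = 1.0  # ramp tops out this long after lights-on
    dusk_decay_h: float = 2.0
    afternoon_peak_zt: float | None = None
    afternoon_peak_height: float = 0.0
    nocturnal_peak_zt: float | None = None
    nocturnal_peak_height: float = 0.0
    peak_width_h: float = 1.0
    ultradian_period_h: float = 4.0
    ultradian_relamp: float = 0.0  # 0 = no ultradian modulation of activity
    ultradian_duty: float = 0.5
    light_rate_cpm: float = 18.0  # mean activity counts/min at full drive
    stress_spike_c: float = 0.8
    stress_spike_half_life_h: float = 0.5
    logger_bias_c: float = 0.0  # per-logger accuracy offset

    def __post_init__(self) -> None:
        if self.target_daily_range <= 0:
            raise ValueError("target_daily_range must be > 0")
        if self.noise_sd_tb < 0:
            raise ValueError("noise_sd_tb must be >= 0")
        if self.ultradian_period_h <= 0:
            raise ValueError("ultradian_period_h must be > 0")
        if not 0.0 <= self.ultradian_relamp <= 1.0:
            raise ValueError("ultradian_relamp must be in [0, 1]")


@dataclass
class HusbandryLog:
    """Times of husbandry visits (experiment hours since start)."""

    visits: np.ndarray
    mode: str  # "fixed-time" | "randomized"
    window: tuple[float, float] = (0.0, 24.0)  # clock-hour window for visits
    n_days: int = 0

    def __post_init__(self) -> None:
        self.visits = np.sort(np.asarray(self.visits, dtype=float))
        if self.mode not in ("fixed-time", "randomized"):
            raise ValueError("mode must be 'fixed-time' or 'randomized'")
        if self.n_days and len(self.visits):
            if self.visits.min() < 0 or self.visits.max() >= 24.0 * self.n_days:
                raise ValueError("visits outside the experiment span")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"day": (self.visits // 24).astype(int), "hour": self.visits % 24.0}
        )


def quantize_tb(x: np.ndarray) -> np.ndarray:
    """Snap temperatures to the 1/16 °C logger grid."""
    return np.round(np.asarray(x, dtype=float) / TB_RESOLUTION_C) * TB_RESOLUTION_C


# ---------------------------------------------------------------------------
# waveform template


def _template_shape(zt, photoperiod: float, ramp_onset: float,
                    sat_h: float, decay_h: float) -> np.ndarray:
    """Unit-amplitude daily Tb shape in [0, 1] as a function of ZT.

    Trough 0 from end of dusk decay to ``ramp_onset``; linear rise to 1 at
    ``sat_h`` after lights-on (ZT 0); plateau 1 until lights-off
    (ZT = photoperiod); linear decay back to 0 over ``decay_h``.
    """
    p, psi = photoperiod, ramp_onset
    if not (p + decay_h) < psi < 24.0:
        raise ValueError(
            f"ramp_onset_zt {psi} must lie in the trough ({p + decay_h}, 24)")
    if sat_h >= p:
        raise ValueError("ramp saturation must precede lights-off")
    zt = np.mod(np.asarray(zt, dtype=float), 24.0)
    ramp_len = 24.0 - psi + sat_h
    s = np.zeros_like(zt)
    pre = zt >= psi  # ramp before midnight
    s[pre] = (zt[pre] - psi) / ramp_len
    post = zt < sat_h  # ramp tail after midnight
    s[post] = (zt[post] + 24.0 - psi) / ramp_len
    s[(zt >= sat_h) & (zt < p)] = 1.0
    dec = (zt >= p) & (zt < p + decay_h)
    s[dec] = 1.0 - (zt[dec] - p) / decay_h
    return s


def _circular_bump(zt, center: float, height: float, width: float) -> np.ndarray:
    d = np.mod(np.asarray(zt, dtype=float) - center + 12.0, 24.0) - 12.0
    return height * np.exp(-0.5 * (d / width) ** 2)


def _bumps(zt, params: BirdParams) -> np.ndarray:
    out = np.zeros_like(np.asarray(zt, dtype=float))
    if params.afternoon_peak_zt is not None and params.afternoon_peak_height:
        out += _circular_bump(zt, params.afternoon_peak_zt,
                              params.afternoon_peak_height, params.peak_width_h)
    if params.nocturnal_peak_zt is not None and params.nocturnal_peak_height:
        out += _circular_bump(zt, params.nocturnal_peak_zt,
                              params.nocturnal_peak_height, params.peak_width_h)
    return out


def _spike_elevation(t: np.ndarray, visits: np.ndarray, height: float,
                     half_life: float) -> np.ndarray:
    """Additive stress-hyperthermia pulses: height * 2^(-(t-v)/half_life)."""
    out = np.zeros_like(t, dtype=float)
    if height <= 0 or len(visits) == 0:
        return out
    horizon = 8.0 * half_life
    for v in visits:
        lo = np.searchsorted(t, v)
        hi = np.searchsorted(t, v + horizon, side="right")
        out[lo:hi] += height * np.exp2(-(t[lo:hi] - v) / half_life)
    return out


# ---------------------------------------------------------------------------
# calibration


def _spike_key(params: BirdParams, husbandry: HusbandryLog | None):
    if husbandry is None or params.stress_spike_c <= 0:
        return None
    fixed_hour = float(husbandry.visits[0] % 24.0) if (
        husbandry.mode == "fixed-time" and len(husbandry.visits)) else None
    per_day = (
        len(husbandry.visits) / max(husbandry.n_days, 1) if husbandry.n_days else 1.0
    )
    return (params.stress_spike_c, params.stress_spike_half_life_h,
            husbandry.mode, fixed_hour, husbandry.window, round(per_day))


def _calibration_spikes(spike_key, n_days: int, t: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    if spike_key is None:
        return np.zeros_like(t)
    height, half_life, mode, fixed_hour, window, per_day = spike_key
    per_day = max(int(per_day), 1)
    if mode == "fixed-time":
        visits = 24.0 * np.arange(n_days) + (fixed_hour if fixed_hour is not None else 9.0)
    else:
        lo, hi = window
        visits = (24.0 * np.repeat(np.arange(n_days), per_day)
                  + rng.uniform(lo, hi, size=n_days * per_day))
    return _spike_elevation(t, np.sort(visits), height, half_life)


_CAL_CACHE: dict = {}


def _calibrate(kind: str, key: tuple, signal_day: np.ndarray | None,
               fixed_day: np.ndarray | None, noise_sd: float, target: float,
               spike_key, samples_per_day: int) -> float:
    """Root-find the free scale so E[daily max - min] = target.

    ``kind`` is "amplitude" (scale the unit template; noise and the fixed
    °C bumps stay put) or "noise" (scale the noise SD; template absent).
    Uses a fixed calibration seed and common random numbers across scale
    evaluations, so the objective is smooth and monotone.
    """
    cache_key = (kind, key)
    if cache_key in _CAL_CACHE:
        return _CAL_CACHE[cache_key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    n_days, k = _CALIBRATION_DAYS, samples_per_day
    z = rng.standard_normal((n_days, k))
    t = (24.0 / k) * np.arange(n_days * k)
    spikes = _calibration_spikes(spike_key, n_days, t, rng).reshape(n_days, k)

    if kind == "amplitude":
        base = spikes + noise_sd * z
        if fixed_day is not None:
            base = base + fixed_day[None, :]

        def mean_range(a: float) -> float:
            return float(np.ptp(a * signal_day[None, :] + base, axis=1).mean())
    else:
        def mean_range(a: float) -> float:
            return float(np.ptp(a * z + spikes, axis=1).mean())

    if mean_range(0.0) > target:
        raise ValueError(
            f"target_daily_range {target} °C infeasible: noise/masking alone "
            f"already produce an expected daily range of {mean_range(0.0):.3f} °C"
        )
    hi = max(target, 1.0)
    while mean_range(hi) < target:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("calibration failed to bracket the target range")
    scale = brentq(lambda a: mean_range(a) - target, 0.0, hi, xtol=1e-6)
    _CAL_CACHE[cache_key] = float(scale)
    return float(scale)


def _entrained_day_key(photoperiod: float, lights_on: float, params: BirdParams,
                       sampling_interval: float):
    return (round(photoperiod, 6), round(lights_on, 6), round(params.ramp_onset_zt, 6),
            params.ramp_saturation_h, params.dusk_decay_h,
            params.afternoon_peak_zt, params.afternoon_peak_height,
            params.nocturnal_peak_zt, params.nocturnal_peak_height,
            params.peak_width_h, round(params.noise_sd_tb, 9),
            round(params.target_daily_range, 9), sampling_interval)


def _entrained_signal_day(photoperiod: float, lights_on: float, params: BirdParams,
                          sampling_interval: float):
    """(template deviations, bumps) on one day's sampling grid, plus s-bar."""
    k = int(round(24.0 / sampling_interval))
    clock = sampling_interval * np.arange(k)
    zt = np.mod(clock - lights_on, 24.0)
    fine = np.arange(0.0, 24.0, 1.0 / 60.0)
    s_bar = _template_shape(fine, photoperiod, params.ramp_onset_zt,
                            params.ramp_saturation_h, params.dusk_decay_h).mean()
    s = _template_shape(zt, photoperiod, params.ramp_onset_zt,
                        params.ramp_saturation_h, params.dusk_decay_h)
    return s - s_bar, _bumps(zt, params)


def simulate_tb(params: BirdParams, schedule: LightSchedule,
                sampling_interval: float = 1.0,
                husbandry: HusbandryLog | None = None) -> TbSeries:
    """Simulate one bird's Tb series over the schedule's span.

    Deterministic given ``params.seed``.  Entrained days carry the calibrated
    24 h template plus bumps; constant-condition days carry noise (calibrated
    when the whole schedule is constant) and husbandry spikes only.  Output
    is quantized to the logger resolution.
    """
    k = 24.0 / sampling_interval
    if abs(k - round(k)) > 1e-9:
        raise ValueError("sampling_interval must divide 24 h evenly")
    k = int(round(k))
    n = schedule.n_days * k
    t = sampling_interval * np.arange(n)
    day = np.minimum((t // 24).astype(int), schedule.n_days - 1)
    photoperiods = schedule.lights_off - schedule.lights_on
    entrained_day = (photoperiods > 1e-9) & (photoperiods < 24.0 - 1e-9)
    spike_key = _spike_key(params, husbandry)

    signal = np.zeros(n)
    if entrained_day.any():
        # calibrate the template amplitude on the modal entrained day
        pairs = np.stack([photoperiods[entrained_day],
                          schedule.lights_on[entrained_day]], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        p_mode, on_mode = uniq[np.argmax(counts)]
        dev, bumps = _entrained_signal_day(p_mode, on_mode, params, sampling_interval)
        key = _entrained_day_key(p_mode, on_mode, params, sampling_interval) + (spike_key,)
        amplitude = _calibrate("amplitude", key, dev, bumps,
                               params.noise_sd_tb, params.target_daily_range,
                               spike_key, k)
        noise_sd = params.noise_sd_tb
        for (p, on) in uniq:
            dev_u, bumps_u = _entrained_signal_day(p, on, params, sampling_interval)
            day_mask = entrained_day[day] & (photoperiods[day] == p) & (
                schedule.lights_on[day] == on)
            idx_in_day = (np.arange(n) % k)
            signal[day_mask] = amplitude * dev_u[idx_in_day[day_mask]] + \
                bumps_u[idx_in_day[day_mask]]
    else:
        key = ("const", round(params.target_daily_range, 9), sampling_interval, spike_key)
        noise_sd = _calibrate("noise", key, None, None, 0.0,
                              params.target_daily_range, spike_key, k)
        amplitude = 0.0

    rng = np.random.default_rng(params.seed)
    noise = noise_sd * rng.standard_normal(n)
    spikes = (_spike_elevation(t, husbandry.visits, params.stress_spike_c,
                               params.stress_spike_half_life_h)
              if husbandry is not None else 0.0)
    tb = params.mesor + params.logger_bias_c + signal + spikes + noise
    return TbSeries(bird_id=params.bird_id, treatment=schedule.name, t=t,
                    tb=quantize_tb(tb), sampling_interval=sampling_interval)


# ---------------------------------------------------------------------------
# activity


def _activity_rate_day(photoperiod: float, lights_on: float, params: BirdParams,
                       minutes: np.ndarray) -> np.ndarray:
    """Expected counts/min over one entrained day (per-minute grid)."""
    zt = np.mod(minutes / 60.0 - lights_on, 24.0)
    onset = params.activity_onset_zt
    if onset <= 0.0:  # onset exactly at lights-on
        onset = 24.0
    sat = params.ramp_saturation_h
    if not photoperiod < onset <= 24.0:
        raise ValueError("activity_onset_zt must lie in the dark phase (or 24 = lights-on)")
    ramp_len = 24.0 - onset + sat
    rate = np.zeros_like(zt)  # dark phase: rest
    rate[(zt >= sat) & (zt < photoperiod)] = 1.0
    pre = zt >= onset  # anticipatory ramp before midnight
    rate[pre] = (zt[pre] - onset) / ramp_len
    tail = zt < sat  # ramp completes after lights-on
    rate[tail] = (zt[tail] + 24.0 - onset) / ramp_len
    return params.light_rate_cpm * rate


def simulate_activity(params: BirdParams, schedule: LightSchedule) -> ActivitySeries:
    """Simulate per-minute activity counts (Poisson around a driven rate).

    Entrained days: zero in the dark, a linear ramp from
    ``activity_onset_zt`` saturating 1 h after lights-on, full drive through
    the light phase.  Constant conditions: an ultradian square-wave bout
    process (period ``ultradian_period_h``, duty ``ultradian_duty``)
    modulating the rate by ``ultradian_relamp``.  Deterministic given seed.
    """
    n_days = schedule.n_days
    n = n_days * 1440
    t = np.arange(n) / 60.0
    day = np.minimum((t // 24).astype(int), n_days - 1)
    photoperiods = schedule.lights_off - schedule.lights_on
    rate = np.empty(n)

    minutes_of_day = np.arange(1440, dtype=float)
    # group days by (photoperiod, lights_on) to reuse the day profile
    pairs = np.stack([photoperiods, schedule.lights_on], axis=1)
    uniq = np.unique(pairs, axis=0)
    idx_in_day = np.arange(n) % 1440
    for (p, on) in uniq:
        mask = (photoperiods[day] == p) & (schedule.lights_on[day] == on)
        if 1e-9 < p < 24.0 - 1e-9:
            day_rate = _activity_rate_day(p, on, params, minutes_of_day)
            rate[mask] = day_rate[idx_in_day[mask]]
        else:
            # ultradian bout process, phase continuous across days
            phase = np.mod(t[mask], params.ultradian_period_h)
            bout = phase < params.ultradian_duty * params.ultradian_period_h
            rate[mask] = params.light_rate_cpm * np.where(
                bout, 1.0, 1.0 - params.ultradian_relamp)

    rng = np.random.default_rng(params.seed + 1)
    counts = rng.poisson(rate).astype(float)
    return ActivitySeries(bird_id=params.bird_id, treatment=schedule.name,
                          t=t, counts=counts, sampling_interval=1.0 / 60.0)


def simulate_husbandry(schedule: LightSchedule, mode: str = "randomized",
                       seed: int = 0, fixed_hour: float = 3.0,
                       window: tuple[float, float] = (0.0, 24.0),
                       visits_per_day: int = 1) -> HusbandryLog:
    """Generate a husbandry-visit log over the schedule's span.

    ``fixed-time``: the same clock hour every day.  ``randomized``: visit
    hour uniform over ``window``, independent across days.  Deterministic
    given ``seed``.
    """
    n_days = schedule.n_days
    if mode == "fixed-time":
        visits = 24.0 * np.arange(n_days) + fixed_hour
        return HusbandryLog(visits=visits, mode=mode,
                            window=(fixed_hour, fixed_hour), n_days=n_days)
    if mode != "randomized":
        raise ValueError("mode must be 'fixed-time' or 'randomized'")
    lo, hi = window
    if not (0.0 <= lo < hi <= 24.0):
        raise ValueError("window must satisfy 0 <= lo < hi <= 24")
    rng = np.random.default_rng(seed)
    days = np.repeat(np.arange(n_days), visits_per_day)
    visits = 24.0 * days + rng.uniform(lo, hi, size=len(days))
    return HusbandryLog(visits=visits, mode=mode, window=window, n_days=n_days)
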