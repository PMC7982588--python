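"""Default experimental cohorts: group sizes, durations and bird-level
parameter draws matching the study conditions.

Four groups:

* SP  — short photoperiod L:D 6:18, 7 birds for 48 days (one bird, SP2,
  for 30 days; two birds logged half-hourly and are excluded from the
  amplitude model),
* LP/LL — 8 birds, 23 days under L:D 16:8 then 14 days of constant light
  (same birds, so the bird random intercept is shared across the two
  treatments),
* DD  — 3 birds, 83 days of constant darkness.

Group mean daily Tb ranges are 2.52 / 2.27 / 1.46 / 1.30 °C (SP/LP/LL/DD)
and the between-bird SD of the range is 0.33 °C, consistent with group
standard errors of roughly 0.12-0.19 °C at these group sizes.  Bird range
offsets are drawn once per cohort and centred to sum to zero within the
birds entering the amplitude model, so every simulated cohort realises
the group means exactly while keeping realistic between-bird spread
(moment matching).

Anticipation onsets: Tb ramps start at ZT 21:04 (SP) and ZT 23:17 (LP);
activity rises at ZT 22:20 (SP) and ZT 23:26 (LP); per-bird onset jitter
SD 10 min.  Secondary Tb peaks sit at ZT 11:05 (SP, nocturnal, +0.6 °C)
and ZT 8:51 (LP, afternoon, +0.5 °C).  Activity under constant light
shows ~4 h ultradian bouts.  Husbandry: one visit/day — fixed-time at
ZT 3 under entrained schedules, randomized over the full day under
constant conditions (the regime used for analysis windows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .light import (DD_PROTOCOL, LL_PROTOCOL, LP_PROTOCOL, SP_PROTOCOL,
                    build_light_schedule)
from .series import TbSeries
from .simulate import (BirdParams, simulate_activity, simulate_husbandry,
                       simulate_tb)

__all__ = ["Cohort", "default_cohort", "default_activity_cohort",
           "GROUP_TARGET_RANGE", "GROUP_SIZES", "BETWEEN_BIRD_SD"]

GROUP_TARGET_RANGE = {"SP": 2.52, "LP": 2.27, "LL": 1.46, "DD": 1.30}
GROUP_SIZES = {"SP": 7, "LP": 8, "LL": 8, "DD": 3}
GROUP_DAYS = {"SP": 48, "LP": 23, "LL": 14, "DD": 83}
BETWEEN_BIRD_SD = 0.33  # °C, bird-level SD of the daily range
MESOR_SD = 0.15  # °C
ONSET_JITTER_SD = 1.0 / 6.0  # h (10 min)

TB_RAMP_ONSET = {"SP": 21.0 + 4.0 / 60.0, "LP": 23.0 + 17.0 / 60.0}
ACT_ONSET = {"SP": 22.0 + 20.0 / 60.0, "LP": 23.0 + 26.0 / 60.0}
NOCTURNAL_PEAK_ZT = 11.0 + 5.0 / 60.0  # SP dark-phase bump
AFTERNOON_PEAK_ZT = 8.0 + 51.0 / 60.0  # LP light-phase bump

# activity recording durations (3 birds per group)
ACT_DAYS = {"SP": (12, 18, 31), "LP": (9, 9, 9), "LL": (14, 14, 14),
            "DD": (66, 66, 66)}


@dataclass
class Cohort:
    """One simulated experiment: series, schedules and husbandry logs."""

    tb: list  # TbSeries, one per bird-treatment segment
    schedules: dict  # treatment -> LightSchedule
    husbandry: dict  # treatment -> HusbandryLog
    params: dict  # (bird_id, treatment) -> BirdParams
    seed: int = 0

    def tb_by_treatment(self, treatment: str) -> list:
        return [s for s in self.tb if s.treatment == treatment]


def _centered_offsets(rng: np.random.Generator, n: int, sd: float,
                      clip: float) -> np.ndarray:
    """Sum-to-zero bird offsets with given spread (clipped, then centred)."""
    b = np.clip(rng.normal(0.0, sd, size=n), -clip, clip)
    return b - b.mean()


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _base_params(group: str, bird_id: str, seed: int, target: float,
                 mesor: float, onset_jit: float, act_jit: float) -> BirdParams:
    common = dict(bird_id=bird_id, seed=seed, mesor=mesor,
                  target_daily_range=target, noise_sd_tb=0.15)
    if group == "SP":
        return BirdParams(ramp_onset_zt=TB_RAMP_ONSET["SP"] + onset_jit,
                          activity_onset_zt=ACT_ONSET["SP"] + act_jit,
                          nocturnal_peak_zt=NOCTURNAL_PEAK_ZT,
                          nocturnal_peak_height=0.6, **common)
    if group == "LP":
        return BirdParams(ramp_onset_zt=TB_RAMP_ONSET["LP"] + onset_jit,
                          activity_onset_zt=ACT_ONSET["LP"] + act_jit,
                          afternoon_peak_zt=AFTERNOON_PEAK_ZT,
                          afternoon_peak_height=0.5, **common)
    if group == "LL":
        return BirdParams(ultradian_relamp=0.95, ultradian_period_h=4.0, **common)
    if group == "DD":
        return BirdParams(ultradian_relamp=0.8, ultradian_period_h=4.0,
                          light_rate_cpm=10.0, **common)
    raise ValueError(f"unknown group {group!r}")


def default_cohort(seed: int = 0, quick: bool = False) -> Cohort:
    """Simulate the full default Tb cohort (18 birds, 4 treatments).

    ``quick`` shrinks durations to 5 days and 2-3 birds per group for
    smoke runs; the defaults are the full study conditions.
    """
    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    days = {g: (5 if quick else d) for g, d in GROUP_DAYS.items()}
    n_sp = 3 if quick else GROUP_SIZES["SP"]
    n_lp = 2 if quick else GROUP_SIZES["LP"]
    n_dd = 2 if quick else GROUP_SIZES["DD"]

    schedules = {
        "SP": build_light_schedule(SP_PROTOCOL, days["SP"]),
        "LP": build_light_schedule(LP_PROTOCOL, days["LP"]),
        "LL": build_light_schedule(LL_PROTOCOL, days["LL"]),
        "DD": build_light_schedule(DD_PROTOCOL, days["DD"]),
    }
    husbandry = {
        "SP": simulate_husbandry(schedules["SP"], "fixed-time",
                                 fixed_hour=3.0),
        "LP": simulate_husbandry(schedules["LP"], "fixed-time",
                                 fixed_hour=3.0),
        "LL": simulate_husbandry(schedules["LL"], "randomized",
                                 seed=_child_seed(master.spawn(1)[0])),
        "DD": simulate_husbandry(schedules["DD"], "randomized",
                                 seed=_child_seed(master.spawn(1)[0])),
    }

    tb_series: list[TbSeries] = []
    params: dict = {}

    # --- SP group: 7 birds; SP2 runs 30 d; SP6/SP7 log half-hourly -------
    half_hour = {"SP6", "SP7"} if not quick else set()
    sp_ids = [f"SP{i + 1}" for i in range(n_sp)]
    hourly_ids = [b for b in sp_ids if b not in half_hour]
    offsets = dict(zip(hourly_ids,
                       _centered_offsets(rng, len(hourly_ids), BETWEEN_BIRD_SD, 0.66)))
    for b in sp_ids:
        off = offsets.get(b)
        if off is None:  # half-hour birds: uncentred draw (excluded from the model)
            off = float(np.clip(rng.normal(0.0, BETWEEN_BIRD_SD), -0.66, 0.66))
        p = _base_params(
            "SP", b, _child_seed(master.spawn(1)[0]),
            GROUP_TARGET_RANGE["SP"] + off,
            40.8 + float(np.clip(rng.normal(0.0, MESOR_SD), -0.45, 0.45)),
            float(np.clip(rng.normal(0.0, ONSET_JITTER_SD), -0.33, 0.33)),
            float(np.clip(rng.normal(0.0, ONSET_JITTER_SD), -0.33, 0.33)))
        n_days = 30 if b == "SP2" and not quick else days["SP"]
        sched = schedules["SP"] if n_days == days["SP"] else \
            build_light_schedule(SP_PROTOCOL, n_days)
        interval = 0.5 if b in half_hour else 1.0
        tb_series.append(simulate_tb(p, sched, sampling_interval=interval,
                                     husbandry=husbandry["SP"]))
        params[(b, "SP")] = p

    # --- LP/LL group: 8 birds, 23 d LP then 14 d LL, shared intercept ----
    lp_ids = [f"LPLL{i + 1}" for i in range(n_lp)]
    lp_offsets = _centered_offsets(rng, n_lp, BETWEEN_BIRD_SD, 0.66)
    for b, off in zip(lp_ids, lp_offsets):
        mesor = 40.8 + float(np.clip(rng.normal(0.0, MESOR_SD), -0.45, 0.45))
        onset_jit = float(np.clip(rng.normal(0.0, ONSET_JITTER_SD), -0.33, 0.33))
        act_jit = float(np.clip(rng.normal(0.0, ONSET_JITTER_SD), -0.33, 0.33))
        p_lp = _base_params("LP", b, _child_seed(master.spawn(1)[0]),
                            GROUP_TARGET_RANGE["LP"] + off, mesor, onset_jit, act_jit)
        p_ll = _base_params("LL", b, _child_seed(master.spawn(1)[0]),
                            GROUP_TARGET_RANGE["LL"] + off, mesor, 0.0, 0.0)
        tb_series.append(simulate_tb(p_lp, schedules["LP"], husbandry=husbandry["LP"]))
        tb_series.append(simulate_tb(p_ll, schedules["LL"], husbandry=husbandry["LL"]))
        params[(b, "LP")] = p_lp
        params[(b, "LL")] = p_ll

    # --- DD group: 3 birds, 83 d -----------------------------------------
    dd_ids = [f"DD{i + 1}" for i in range(n_dd)]
    dd_offsets = _centered_offsets(rng, n_dd, BETWEEN_BIRD_SD, 0.66)
    for b, off in zip(dd_ids, dd_offsets):
        p = _base_params("DD", b, _child_seed(master.spawn(1)[0]),
                         GROUP_TARGET_RANGE["DD"] + off,
                         40.8 + float(np.clip(rng.normal(0.0, MESOR_SD), -0.45, 0.45)),
                         0.0, 0.0)
        tb_series.append(simulate_tb(p, schedules["DD"], husbandry=husbandry["DD"]))
        params[(b, "DD")] = p

    return Cohort(tb=tb_series, schedules=schedules, husbandry=husbandry,
                  params=params, seed=seed)


def default_activity_cohort(seed: int = 0, n_days: dict | None = None):
    """Activity recordings for 3 birds per group (separate sensor subset).

    Returns (activity series list, schedules dict, params dict).
    """
    master = np.random.SeedSequence(seed + 1_000_003)
    rng = np.random.default_rng(master.spawn(1)[0])
    days = dict(ACT_DAYS)
    if n_days:
        days.update(n_days)
    protocols = {"SP": SP_PROTOCOL, "LP": LP_PROTOCOL,
                 "LL": LL_PROTOCOL, "DD": DD_PROTOCOL}
    series, params, schedules = [], {}, {}
    for group, durations in days.items():
        for i, nd in enumerate(durations):
            b = f"{group}A{i + 1}"
            act_jit = float(np.clip(rng.normal(0.0, ONSET_JITTER_SD), -0.33, 0.33)) \
                if group in ("SP", "LP") else 0.0
            p = _base_params(group, b, _child_seed(master.spawn(1)[0]),
                             GROUP_TARGET_RANGE[group], 40.8, 0.0, act_jit)
            sched = build_light_schedule(protocols[group], nd)
            series.append(simulate_activity(p, sched))
            params[(b, group)] = p
            schedules.setdefault(group, sched)
    return series, schedules, params


def dawn_cohort(group: str, seed: int = 0, n_birds: int = 3, n_days: int = 7):
    """Paired Tb + activity recordings for the dawn-anticipation analysis.

    Three birds per photoperiod with both modalities over the same
    undisturbed span (husbandry scheduled in the light phase, away from
    the dawn window).  Returns (list of (tb, activity, params), schedule).
    """
    if group not in ("SP", "LP"):
        raise ValueError("dawn anticipation is defined for entrained groups (SP, LP)")
    master = np.random.SeedSequence(seed + 7_000_017)
    rng = np.random.default_rng(master.spawn(1)[0])
    protocol = SP_PROTOCOL if group == "SP" else LP_PROTOCOL
    sched = build_light_schedule(protocol, n_days)
    hus = simulate_husbandry(sched, "fixed-time", fixed_hour=3.0)
    birds = []
    for i in range(n_birds):
        b = f"{group}D{i + 1}"
        onset_jit = float(np.clip(rng.normal(0.0, ONSET_JITTER_SD), -0.33, 0.33))
        act_jit = float(np.clip(rng.normal(0.0, ONSET_JITTER_SD), -0.33, 0.33))
        p = _base_params(group, b, _child_seed(master.spawn(1)[0]),
                         GROUP_TARGET_RANGE[group],
                         40.8 + float(np.clip(rng.normal(0.0, MESOR_SD), -0.45, 0.45)),
                         onset_jit, act_jit)
        tb = simulate_tb(p, sched, husbandry=hus)
        act = simulate_activity(p, sched)
        birds.append((tb, act, p))
    return birds, sched
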