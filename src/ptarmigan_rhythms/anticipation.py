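"""Dawn anticipation: pre-dawn Tb/activity profiles, two-segment regression
breakpoints, and secondary (afternoon / nocturnal) Tb peaks.

The dawn window runs from 5 h before lights-on to 1 h after, sampled at the
7 hourly Tb grid points.  The onset of the anticipatory rise is the
breakpoint psi of the continuous hinge model

    y = b0 + b1 * t + b2 * max(0, t - psi)

fitted by least squares with psi optimized on a dense 1-minute grid and
refined by golden-section search.  Activity enters as the mean of the 10
one-minute counts immediately preceding each Tb grid time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .light import LightSchedule
from .series import ActivitySeries, TbSeries
from .simulate import HusbandryLog

__all__ = [
    "DawnProfile",
    "BreakpointFit",
    "BreakpointSummary",
    "dawn_profile",
    "fit_segmented",
    "summarize_breakpoints",
    "secondary_peak",
    "zt_to_hhmm",
]

log = logging.getLogger(__name__)

DAWN_WINDOW = (-5.0, 1.0)  # hours relative to lights-on, inclusive


def zt_to_hhmm(zt_hours: float) -> str:
    """Format a decimal ZT hour as ZT hh:mm (modulo 24)."""
    z = zt_hours % 24.0
    h = int(z)
    m = int(round((z - h) * 60.0))
    if m == 60:
        h, m = (h + 1) % 24, 0
    return f"ZT {h:02d}:{m:02d}"


@dataclass
class DawnProfile:
    """Mean dawn-window profile for one bird over a span of days."""

    bird_id: str
    offsets: np.ndarray  # hours relative to lights-on: -5 ... +1
    tb_mean: np.ndarray
    tb_sd: np.ndarray
    act_mean: np.ndarray | None
    act_sd: np.ndarray | None
    n_days: int
    excluded_days: list = field(default_factory=list)


@dataclass
class BreakpointFit:
    """Continuous two-segment least-squares fit."""

    psi: float  # breakpoint, hours relative to lights-on (negative = before)
    intercept: float
    slope_pre: float
    slope_post: float
    rss: float
    anticipatory: bool  # post-slope >= pre-slope
    identifiable: bool = True

    def psi_zt(self, lights_on: float = 0.0) -> float:
        return (lights_on + self.psi) % 24.0


def dawn_profile(tb: TbSeries, schedule: LightSchedule, days,
                 activity: ActivitySeries | None = None,
                 husbandry: HusbandryLog | None = None) -> DawnProfile:
    """Average the dawn window over the given days for one bird.

    Tb at each hourly grid point is the mean across days of the sample at
    that instant; activity is the mean of the 10 one-minute counts
    immediately preceding the grid time, averaged across days.  Days with a
    husbandry visit inside the window are excluded (logged).  Requires a
    fixed lights-on time across the selected days.
    """
    days = list(days)
    if len(days) < 5:
        raise ValueError("dawn profile needs at least 5 days")
    ons = {float(schedule.lights_on[d]) for d in days}
    if len(ons) != 1:
        raise ValueError(f"lights-on varies over the selected days: {sorted(ons)}")
    lights_on = ons.pop()
    offsets = np.arange(DAWN_WINDOW[0], DAWN_WINDOW[1] + 0.5)  # -5 ... +1

    used, excluded = [], []
    tb_rows, act_rows = [], []
    dt = tb.sampling_interval
    for d in days:
        grid = 24.0 * d + lights_on + offsets
        if husbandry is not None and len(husbandry.visits):
            in_win = (husbandry.visits >= grid[0]) & (husbandry.visits <= grid[-1])
            if in_win.any():
                excluded.append(d)
                log.info("bird %s day %d excluded from dawn profile: husbandry in window",
                         tb.bird_id, d)
                continue
        idx = np.round((grid - tb.t[0]) / dt).astype(int)
        if idx.min() < 0 or idx.max() >= len(tb):
            raise ValueError(f"day {d}: dawn window outside the Tb series span")
        if np.max(np.abs(tb.t[idx] - grid)) > 1e-6:
            raise ValueError(f"day {d}: Tb samples do not fall on the dawn grid")
        tb_rows.append(tb.tb[idx])
        if activity is not None:
            adt = activity.sampling_interval
            vals = []
            for g in grid:
                j1 = int(round((g - activity.t[0]) / adt))
                j0 = j1 - int(round((1.0 / 6.0) / adt))  # 10 minutes
                if j0 < 0 or j1 > len(activity):
                    raise ValueError(f"day {d}: activity series does not cover the window")
                vals.append(float(np.nanmean(activity.counts[j0:j1])))
            act_rows.append(vals)
        used.append(d)

    if not used:
        raise ValueError("no usable days left for the dawn profile")
    tb_mat = np.vstack(tb_rows)
    act_mat = np.vstack(act_rows) if act_rows else None
    return DawnProfile(
        bird_id=tb.bird_id,
        offsets=offsets,
        tb_mean=tb_mat.mean(axis=0),
        tb_sd=tb_mat.std(axis=0, ddof=1) if len(used) > 1 else np.zeros_like(offsets),
        act_mean=act_mat.mean(axis=0) if act_mat is not None else None,
        act_sd=(act_mat.std(axis=0, ddof=1) if act_mat is not None and len(used) > 1
                else (np.zeros_like(offsets) if act_mat is not None else None)),
        n_days=len(used),
        excluded_days=excluded,
    )


def _hinge_rss(x: np.ndarray, y: np.ndarray, psi: float):
    design = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        return np.inf, beta
    resid = y - design @ beta
    return float(resid @ resid), beta


def fit_segmented(x, y, grid_step: float = 1.0 / 60.0,
                  flat_tol: float = 1e-10) -> BreakpointFit:
    """Least-squares hinge fit with dense-grid + golden-section breakpoint.

    The breakpoint is constrained to keep at least two points on each side.
    On RSS ties the earliest grid optimum wins.  Flat data (RSS profile
    flat within ``flat_tol``) are flagged non-identifiable, not rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points to fit a two-segment model")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.ptp(x) <= 0:
        raise ValueError("degenerate design: all x equal")
    lo, hi = x[1], x[-2]  # >= 2 points on each side
    if hi <= lo:
        raise ValueError("window too short to place a breakpoint")
    eps = 1e-9
    grid = np.arange(lo + eps, hi - eps + grid_step / 2, grid_step)
    rss = np.empty(len(grid))
    for i, psi in enumerate(grid):
        rss[i], _ = _hinge_rss(x, y, psi)
    best = int(np.argmin(rss))  # argmin returns the earliest tie
    identifiable = bool(np.ptp(rss) > flat_tol)

    # golden-section refinement inside the bracketing grid cells
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, _ = _hinge_rss(x, y, c)
    fd, _ = _hinge_rss(x, y, d)
    for _ in range(40):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc, _ = _hinge_rss(x, y, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd, _ = _hinge_rss(x, y, d)
    psi_ref = (a + b) / 2.0
    rss_ref, _ = _hinge_rss(x, y, psi_ref)
    psi = psi_ref if rss_ref < rss[best] - 1e-15 and identifiable else grid[best]
    rss_best, beta = _hinge_rss(x, y, psi)
    slope_pre, slope_post = float(beta[1]), float(beta[1] + beta[2])
    return BreakpointFit(psi=float(psi), intercept=float(beta[0]),
                         slope_pre=slope_pre, slope_post=slope_post,
                         rss=rss_best, anticipatory=slope_post >= slope_pre,
                         identifiable=identifiable)


@dataclass
class BreakpointSummary:
    mean_offset_h: float  # hours relative to lights-on
    sd_h: float | None
    n: int
    per_fit_offsets: np.ndarray
    lights_on: float = 0.0

    @property
    def mean_zt(self) -> float:
        return (self.lights_on + self.mean_offset_h) % 24.0

    def __str__(self) -> str:
        sd = "undefined" if self.sd_h is None else f"{int(self.sd_h * 60):d} min"
        return f"{zt_to_hhmm(self.mean_zt)} ± {sd} (n={self.n})"


def summarize_breakpoints(fits, lights_on: float = 0.0) -> BreakpointSummary:
    """Mean ± SD of breakpoints over replicate fits (per bird or per day).

    The window never exceeds 6 h, so linear statistics on hours relative to
    lights-on are valid; the mean is reported on the ZT scale.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to summarize")
    offs = np.array([f.psi for f in fits])
    sd = float(offs.std(ddof=1)) if len(offs) > 1 else None
    return BreakpointSummary(mean_offset_h=float(offs.mean()), sd_h=sd,
                             n=len(offs), per_fit_offsets=offs, lights_on=lights_on)


def _moving_average(vals: np.ndarray, width: int) -> np.ndarray:
    """Centered circular moving average (odd width)."""
    kernel = np.ones(width) / width
    padded = np.concatenate([vals[-(width // 2):], vals, vals[: width // 2]])
    return np.convolve(padded, kernel, mode="valid")


def secondary_peak(tb: TbSeries, schedule: LightSchedule, phase: str, days,
                   smooth_h: float = 3.0):
    """Locate a secondary Tb peak as the highest *interior local maximum*
    of a centered 3 h moving average, per day, within a phase window.

    ``phase="dark"``: the dark phase (for the short-photoperiod nocturnal
    bump); ``phase="light"``: ZT 6-16 (the long-photoperiod afternoon
    peak).  Monotone windows (no interior maximum) skip the day.  Returns
    (mean ZT, SD, per-day list of ZT peaks).
    """
    if phase not in ("dark", "light"):
        raise ValueError("phase must be 'dark' or 'light'")
    dt = tb.sampling_interval
    per_day = int(round(24.0 / dt))
    width = max(1, int(round(smooth_h / dt)))
    if width % 2 == 0:
        width += 1
    peaks = []
    for d in days:
        lights_on = float(schedule.lights_on[d])
        photoperiod = schedule.photoperiod(d)
        i0 = int(round((24.0 * d - tb.t[0]) / dt))
        if i0 < 0 or i0 + per_day > len(tb):
            raise ValueError(f"day {d} outside the Tb series span")
        vals = tb.tb[i0: i0 + per_day]
        zt = np.mod(tb.t[i0: i0 + per_day] - lights_on, 24.0)
        smoothed = _moving_average(vals, width)
        if phase == "dark":
            # trim the dusk decay so its shoulder is not mistaken for a peak
            win = (zt >= photoperiod + 2.0) & (zt < 24.0)
        else:
            win = (zt >= 6.0) & (zt <= 16.0)
        idx = np.flatnonzero(win)
        if len(idx) < 3:
            continue
        sub = smoothed[idx]
        interior = np.flatnonzero((sub[1:-1] > sub[:-2]) & (sub[1:-1] >= sub[2:])) + 1
        if len(interior) == 0:
            log.info("bird %s day %d: monotone window, no interior peak", tb.bird_id, d)
            continue
        best = interior[np.argmax(sub[interior])]
        peaks.append(float(zt[idx[best]]))
    if not peaks:
        return None, None, []
    arr = np.array(peaks)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, peaks
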