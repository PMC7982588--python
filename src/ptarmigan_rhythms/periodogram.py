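"""Actogram construction and chi-squared periodogram rhythmicity testing.

The periodogram statistic folds a uniformly sampled series at each
candidate period P into B = P/dt phase bins and compares the variance of
the bin means with the total variance:

    Qp = K * sum_h (M_h - M)^2 / sigma2,   sigma2 = sum_i (X_i - M)^2 / N

with K = N/B the mean number of samples per bin.  Under the null of no
rhythm at P, Qp is approximately chi-squared with B - 1 degrees of
freedom; a period is significant when Qp exceeds the upper-alpha quantile.
Incomplete final cycles are included (bins may hold unequal counts).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2

__all__ = [
    "PeriodogramResult",
    "chi2_periodogram",
    "default_period_grid",
    "analysis_window",
    "Actogram",
    "build_actogram",
]


@dataclass
class PeriodogramResult:
    periods: np.ndarray  # hours
    qp: np.ndarray
    df: np.ndarray  # bins - 1 per period
    critical: np.ndarray  # pointwise upper-alpha quantile
    alpha: float
    degenerate: bool = False  # constant input

    @property
    def significant(self) -> np.ndarray:
        return self.qp > self.critical

    @property
    def significant_periods(self) -> np.ndarray:
        return self.periods[self.significant]

    @property
    def qp_ratio(self) -> np.ndarray:
        """Qp relative to its critical value; >1 means significant."""
        return self.qp / self.critical

    def peak_significant_period(self, max_period: float | None = None) -> float | None:
        """Period with the largest Qp/critical ratio among significant ones.

        The ratio (not raw Qp) discriminates a fundamental period from its
        subharmonics at integer multiples, which carry similar Qp but more
        degrees of freedom.
        """
        mask = self.significant
        if max_period is not None:
            mask = mask & (self.periods <= max_period)
        if not mask.any():
            return None
        idx = np.flatnonzero(mask)
        return float(self.periods[idx[np.argmax(self.qp_ratio[idx])]])

    def is_significant_at(self, period: float) -> bool:
        i = int(np.argmin(np.abs(self.periods - period)))
        return bool(self.significant[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"period_h": self.periods, "qp": self.qp, "df": self.df,
             "crit": self.critical, "significant": self.significant}
        )


def default_period_grid(sampling_interval: float,
                        lo: float = 1.0, hi: float = 30.0) -> np.ndarray:
    """All integer multiples of the sampling interval within [lo, hi] hours."""
    k_lo = int(np.ceil(lo / sampling_interval - 1e-9))
    k_hi = int(np.floor(hi / sampling_interval + 1e-9))
    return sampling_interval * np.arange(max(k_lo, 2), k_hi + 1)


def chi2_periodogram(series, period_grid: np.ndarray | None = None,
                     alpha: float = 0.05, bonferroni: bool = False) -> PeriodogramResult:
    """Sokolove–Bushell style chi-squared periodogram of a uniform series.

    ``series`` is any object with ``values``, ``t`` and
    ``sampling_interval`` attributes (TbSeries/ActivitySeries), or a bare
    ndarray (then ``sampling_interval`` = 1 h).  NaNs are excluded from
    their phase bins.  A constant series yields Qp = 0 everywhere with the
    ``degenerate`` flag set.
    """
    if isinstance(series, np.ndarray):
        x = np.asarray(series, dtype=float)
        dt = 1.0
    else:
        x = np.asarray(series.values, dtype=float)
        dt = float(series.sampling_interval)
    if period_grid is None:
        period_grid = default_period_grid(dt)
    period_grid = np.atleast_1d(np.asarray(period_grid, dtype=float))
    ratios = period_grid / dt
    if np.any(np.abs(ratios - np.round(ratios)) > 1e-6):
        raise ValueError("period grid points must be integer multiples of the sampling interval")
    span = len(x) * dt
    if period_grid.max() > span / 2 + 1e-9:
        raise ValueError(
            f"series span {span} h must be at least twice the longest candidate period")

    mask = np.isfinite(x)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("series contains no finite samples")
    xm = x[mask]
    grand = xm.mean()
    sigma2 = float(np.square(xm - grand).sum()) / n
    idx = np.flatnonzero(mask)

    qp = np.zeros(len(period_grid))
    df = np.zeros(len(period_grid), dtype=int)
    degenerate = sigma2 <= 0.0
    for j, p in enumerate(period_grid):
        b = int(round(p / dt))
        df[j] = b - 1
        if degenerate:
            continue
        phase = idx % b
        counts = np.bincount(phase, minlength=b)
        sums = np.bincount(phase, weights=xm, minlength=b)
        occupied = counts > 0
        means = np.zeros(b)
        means[occupied] = sums[occupied] / counts[occupied]
        k_mean = n / b
        qp[j] = k_mean * float(np.square(means[occupied] - grand).sum()) / sigma2
    level = alpha / len(period_grid) if bonferroni else alpha
    critical = chi2.ppf(1.0 - level, df)
    return PeriodogramResult(periods=period_grid, qp=qp, df=df,
                             critical=critical, alpha=alpha, degenerate=degenerate)


def analysis_window(series, start_day: int, n_days: int = 10,
                    min_completeness: float = 0.9):
    """Contiguous ``n_days``-day sub-series starting at ``start_day``.

    Rejects windows that overlap the series end or fall below the
    completeness threshold (fraction of finite samples).
    """
    t0, t1 = 24.0 * start_day, 24.0 * (start_day + n_days)
    if t0 < series.t[0] - 1e-9 or t1 > series.t[-1] + series.sampling_interval + 1e-9:
        raise ValueError(
            f"window days [{start_day}, {start_day + n_days}) outside the "
            f"series span [{series.t[0]}, {series.t[-1]}] h")
    sel = (series.t >= t0 - 1e-9) & (series.t < t1 - 1e-9)
    vals = series.values[sel]
    expected = n_days * int(round(24.0 / series.sampling_interval))
    complete = np.isfinite(vals).sum() / expected
    if complete < min_completeness:
        raise ValueError(
            f"window completeness {complete:.2f} below {min_completeness}: "
            f"gaps at t={list(series.t[sel][~np.isfinite(vals)][:5])}")
    from .series import TbSeries

    if isinstance(series, TbSeries):
        return replace(series, t=series.t[sel], tb=vals, zt=None)
    return replace(series, t=series.t[sel], counts=vals, zt=None)


# ---------------------------------------------------------------------------
# actograms


@dataclass
class Actogram:
    """Raster of daily traces; values in [0, 1] (NaN = no data/blank pad)."""

    matrix: np.ndarray  # rows = days, columns = bins over 24 h (48 h doubled)
    bin_width: float  # hours
    mode: str  # "activity" | "tb"
    double_plot: bool = True

    @property
    def n_days(self) -> int:
        return self.matrix.shape[0]

    def plot(self, ax=None, title: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.25 * self.n_days + 1))
        n_bins = self.matrix.shape[1]
        hours = self.bin_width * np.arange(n_bins)
        for r in range(self.n_days):
            vals = np.nan_to_num(self.matrix[r], nan=0.0)
            ax.bar(hours, 0.9 * vals, width=self.bin_width, align="edge",
                   bottom=self.n_days - 1 - r, color="black")
        ax.set_xlim(0, self.bin_width * n_bins)
        ax.set_ylim(0, self.n_days)
        ax.set_xlabel("time (h)" + (" — double-plotted" if self.double_plot else ""))
        ax.set_ylabel("day")
        if title:
            ax.set_title(title)
        return ax


def build_actogram(series, double_plot: bool = True,
                   tb_range: tuple[float, float] | None = None,
                   bin_width: float | None = None) -> Actogram:
    """Build an actogram matrix from a Tb or activity series.

    Tb mode (``tb_range=(lo, hi)``): bar height = clamp((tb-lo)/(hi-lo), 0, 1)
    so readings below ``lo`` are blank and above ``hi`` full-height.
    Activity mode: counts normalized to the bird's maximum, mean-binned.
    Double plotting puts day d and day d+1 on row d (the last row is padded
    with blanks).
    """
    from .series import ActivitySeries

    mode = "tb" if tb_range is not None else "activity"
    dt = float(series.sampling_interval)
    vals = np.asarray(series.values, dtype=float)
    if tb_range is not None:
        lo, hi = tb_range
        if lo >= hi:
            raise ValueError("tb_range must satisfy lo < hi")
        vals = np.where(np.isfinite(vals),
                        np.clip((vals - lo) / (hi - lo), 0.0, 1.0), np.nan)
    else:
        if isinstance(series, ActivitySeries) and not series.normalized:
            peak = np.nanmax(vals) if len(vals) else 0.0
            vals = vals / peak if peak > 0 else vals
    if bin_width is not None and bin_width > dt:
        k = int(round(bin_width / dt))
        if abs(bin_width / dt - k) > 1e-9:
            raise ValueError("bin_width must be an integer multiple of the sampling interval")
        nb = len(vals) // k
        vals = np.nanmean(vals[: nb * k].reshape(nb, k), axis=1)
        dt = bin_width
    per_day = int(round(24.0 / dt))
    n_days = len(vals) // per_day
    if n_days < 1:
        raise ValueError("series must span at least one whole day")
    mat = vals[: n_days * per_day].reshape(n_days, per_day)
    if double_plot:
        nxt = np.vstack([mat[1:], np.full((1, per_day), np.nan)])
        mat = np.hstack([mat, nxt])
    return Actogram(matrix=mat, bin_width=dt, mode=mode, double_plot=double_plot)
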