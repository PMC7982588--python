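"""Containers and CSV I/O for body-temperature and activity series.

Schemas (plain CSV, sorted by time):

* ``tb.csv``       — bird_id, day, zt_hour, tb_c
* ``activity.csv`` — bird_id, day, zt_minute, counts
* ``schedule.csv`` — day, lights_on, lights_off
* ``husbandry.csv``— day, hour

Timestamps inside the containers are decimal hours since experiment start
(``t = 24*day + hour``); calendar parsing is purely a reader concern.
Missing values are kept as NaN and listed in ``gaps`` — never silently
dropped.  Core Tb must fall in the 35–45 °C logger calibration range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .light import LightSchedule

__all__ = [
    "TbSeries",
    "ActivitySeries",
    "read_series",
    "write_series",
    "normalize_activity",
    "bin_series",
    "to_zeitgeber",
]

TB_VALID_RANGE = (35.0, 45.0)


def _validate_time_axis(t: np.ndarray, interval: float) -> None:
    if len(t) == 0:
        return
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = t[1:][dt <= 0][0]
        raise ValueError(f"timestamps not strictly increasing at t={bad!r} h")
    if np.any(np.abs(dt - interval) > 1e-6):
        bad = t[1:][np.abs(dt - interval) > 1e-6][0]
        raise ValueError(
            f"non-uniform sampling: expected {interval} h steps, "
            f"first offending timestamp t={bad!r} h"
        )


@dataclass
class TbSeries:
    """Hourly (or half-hourly) core body temperature for one bird."""

    bird_id: str
    treatment: str
    t: np.ndarray  # hours since experiment start
    tb: np.ndarray  # °C, NaN where missing
    sampling_interval: float = 1.0
    zt: np.ndarray | None = None
    gaps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tb = np.asarray(self.tb, dtype=float)
        if self.t.shape != self.tb.shape:
            raise ValueError("t and tb must have equal length")
        _validate_time_axis(self.t, self.sampling_interval)
        finite = self.tb[np.isfinite(self.tb)]
        if finite.size and (finite.min() < TB_VALID_RANGE[0] or finite.max() > TB_VALID_RANGE[1]):
            raise ValueError(
                f"Tb outside logger calibration range {TB_VALID_RANGE}: "
                f"[{finite.min():.2f}, {finite.max():.2f}] °C"
            )
        self.gaps = list(self.t[~np.isfinite(self.tb)])

    def __len__(self) -> int:
        return len(self.t)

    @property
    def values(self) -> np.ndarray:
        return self.tb

    def with_values(self, values: np.ndarray) -> "TbSeries":
        return replace(self, tb=np.asarray(values, dtype=float))


@dataclass
class ActivitySeries:
    """Per-minute (or binned) activity counts for one bird."""

    bird_id: str
    treatment: str
    t: np.ndarray
    counts: np.ndarray
    sampling_interval: float = 1.0 / 60.0
    normalized: bool = False
    all_zero: bool = False
    zt: np.ndarray | None = None
    gaps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.t.shape != self.counts.shape:
            raise ValueError("t and counts must have equal length")
        _validate_time_axis(self.t, self.sampling_interval)
        finite = self.counts[np.isfinite(self.counts)]
        if finite.size and finite.min() < 0:
            raise ValueError("activity counts must be non-negative")
        if self.normalized and finite.size and finite.max() > 1.0 + 1e-9:
            raise ValueError("normalized activity must lie in [0, 1]")
        self.gaps = list(self.t[~np.isfinite(self.counts)])

    def __len__(self) -> int:
        return len(self.t)

    @property
    def values(self) -> np.ndarray:
        return self.counts

    def with_values(self, values: np.ndarray, **kw) -> "ActivitySeries":
        return replace(self, counts=np.asarray(values, dtype=float), **kw)


def _frame_to_series(df: pd.DataFrame, kind: str, bird_id, treatment, sampling_interval):
    if kind == "tb":
        t = 24.0 * df["day"].to_numpy(float) + df["zt_hour"].to_numpy(float)
        if sampling_interval is None:
            sampling_interval = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return TbSeries(
            bird_id=str(bird_id),
            treatment=treatment,
            t=t,
            tb=df["tb_c"].to_numpy(float),
            sampling_interval=sampling_interval,
        )
    t = 24.0 * df["day"].to_numpy(float) + df["zt_minute"].to_numpy(float) / 60.0
    return ActivitySeries(
        bird_id=str(bird_id),
        treatment=treatment,
        t=t,
        counts=df["counts"].to_numpy(float),
        sampling_interval=sampling_interval if sampling_interval is not None else 1.0 / 60.0,
    )


def read_series(path, kind: str, bird_id: str | None = None, treatment: str = "custom",
                sampling_interval: float | None = None):
    """Read one bird's series from CSV; validates ordering and uniform spacing.

    ``kind`` is ``"tb"`` or ``"activity"``.  If the file holds several birds,
    ``bird_id`` selects one (error if omitted and ambiguous).  Malformed rows
    raise with the 1-based line number.
    """
    if kind not in ("tb", "activity"):
        raise ValueError("kind must be 'tb' or 'activity'")
    cols = ["bird_id", "day", "zt_hour", "tb_c"] if kind == "tb" else [
        "bird_id", "day", "zt_minute", "counts"]
    df = pd.read_csv(path, dtype={"bird_id": str})
    # pooled files may carry a treatment column; filter on it when asked
    if "treatment" in df.columns and treatment != "custom":
        df = df[df["treatment"] == treatment]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in cols[1:]:
        bad = pd.to_numeric(df[col], errors="coerce")
        malformed = df[col].notna() & bad.isna()
        if malformed.any():
            line = int(np.flatnonzero(malformed)[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column '{col}' at line {line}")
        df[col] = bad
    birds = df["bird_id"].unique()
    if bird_id is None:
        if len(birds) != 1:
            raise ValueError(f"{path}: multiple birds {list(birds)}; pass bird_id")
        bird_id = birds[0]
    sub = df[df["bird_id"] == str(bird_id)]
    if sub.empty:
        raise ValueError(f"{path}: no rows for bird {bird_id!r}")
    return _frame_to_series(sub, kind, bird_id, treatment, sampling_interval)


def series_to_frame(series) -> pd.DataFrame:
    """Schema-conformant frame for a series (sorted by time)."""
    day = np.floor(series.t / 24.0 + 1e-9).astype(int)
    hour = series.t - 24.0 * day
    if isinstance(series, TbSeries):
        return pd.DataFrame(
            {"bird_id": series.bird_id, "day": day,
             "zt_hour": np.round(hour, 9), "tb_c": series.tb}
        )
    return pd.DataFrame(
        {"bird_id": series.bird_id, "day": day,
         "zt_minute": np.round(hour * 60.0, 6), "counts": series.counts}
    )


def write_series(series, path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def normalize_activity(series: ActivitySeries) -> ActivitySeries:
    """Scale counts by the bird's maximum so values lie in [0, 1].

    Idempotent; an all-zero series stays all-zero with ``all_zero`` flagged.
    """
    if series.normalized:
        return series
    peak = np.nanmax(series.counts) if len(series) else 0.0
    if not np.isfinite(peak) or peak <= 0:
        return series.with_values(series.counts, normalized=True, all_zero=True)
    return series.with_values(series.counts / peak, normalized=True)


def bin_series(series, bin_width: float, statistic: str = "mean"):
    """Aggregate into left-closed right-open bins [t, t + bin_width).

    ``bin_width`` must be an integer multiple of the sampling interval;
    output length is floor(span / bin_width) — a truncated tail is dropped.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    step = series.sampling_interval
    ratio = bin_width / step
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError(
            f"bin width {bin_width} h is not an integer multiple of the "
            f"sampling interval {step} h"
        )
    n_bins = len(series) // k
    vals = series.values[: n_bins * k].reshape(n_bins, k)
    agg = vals.sum(axis=1) if statistic == "sum" else vals.mean(axis=1)
    t = series.t[: n_bins * k : k]
    if isinstance(series, TbSeries):
        return replace(series, t=t, tb=agg, sampling_interval=bin_width, zt=None)
    return replace(series, t=t, counts=agg, sampling_interval=bin_width, zt=None)


def to_zeitgeber(series, schedule: LightSchedule):
    """Annotate each sample with ZT = (clock − that day's lights-on) mod 24.

    Undefined under LL/DD (no zeitgeber): raises ``ValueError``.
    """
    if not schedule.has_zeitgeber():
        raise ValueError("ZT undefined without a light-dark cycle (LL/DD schedule)")
    day = np.clip((series.t // 24).astype(int), 0, schedule.n_days - 1)
    clock = series.t - 24.0 * (series.t // 24)
    zt = np.mod(clock - schedule.lights_on[day], 24.0)
    return replace(series, zt=zt)
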