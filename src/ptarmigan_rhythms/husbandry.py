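"""Husbandry masking checks: visit categories, paired tests, and the
rhythmicity of the husbandry schedule itself.

Stress at routine visits raises Tb transiently; under constant light or
darkness such masking can mimic rhythmicity.  Each Tb sample is assigned
to one of three categories — ``husbandry`` (a visit in the hour ending at
the sample), ``post_1h`` (a visit in the hour before that), ``none`` — and
per-bird category means are compared with paired t-tests.  A chi-squared
periodogram of the visit log guards analysis windows against a rhythmic
husbandry schedule.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .periodogram import PeriodogramResult, chi2_periodogram
from .series import TbSeries
from .simulate import HusbandryLog

__all__ = [
    "categorize",
    "paired_category_test",
    "husbandry_periodogram",
    "window_is_unmasked",
]

log = logging.getLogger(__name__)

CATEGORIES = ("husbandry", "post_1h", "none")


def categorize(tb: TbSeries, husbandry: HusbandryLog) -> pd.DataFrame:
    """Assign each Tb sample to husbandry / post_1h / none.

    A sample at time t is ``husbandry`` if a visit occurred in (t-1, t],
    ``post_1h`` if a visit occurred in (t-2, t-1]; overlapping visits
    resolve to the stronger (husbandry) category.  Columns: bird_id, t,
    tb, category.
    """
    visits = husbandry.visits
    cat = np.full(len(tb), "none", dtype=object)
    if len(visits):
        # count visits in (t-1, t] and (t-2, t-1]
        recent = np.searchsorted(visits, tb.t, side="right") - \
            np.searchsorted(visits, tb.t - 1.0, side="right")
        prior = np.searchsorted(visits, tb.t - 1.0, side="right") - \
            np.searchsorted(visits, tb.t - 2.0, side="right")
        cat[prior > 0] = "post_1h"
        cat[recent > 0] = "husbandry"  # husbandry wins on overlap
    return pd.DataFrame({"bird_id": tb.bird_id, "t": tb.t, "tb": tb.tb,
                         "category": cat})


def paired_category_test(table: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests on per-bird category means.

    Contrasts: husbandry vs none and post_1h vs none.  Birds lacking a
    category are dropped from that contrast (logged).  Returns columns:
    contrast, mean_diff, t, p, n_birds.
    """
    means = (table.dropna(subset=["tb"])
             .groupby(["bird_id", "category"], sort=False)["tb"].mean()
             .unstack())
    rows = []
    for cat in ("husbandry", "post_1h"):
        if cat not in means.columns or "none" not in means.columns:
            log.info("contrast %s vs none skipped: category absent", cat)
            continue
        sub = means[[cat, "none"]].dropna()
        dropped = len(means) - len(sub)
        if dropped:
            log.info("%d bird(s) dropped from %s vs none (missing a category)",
                     dropped, cat)
        if len(sub) < 2:
            raise ValueError(f"contrast {cat} vs none needs >= 2 birds with both categories")
        diff = sub[cat] - sub["none"]
        if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
            tstat, p = 0.0, 1.0
        else:
            tstat, p = stats.ttest_rel(sub[cat], sub["none"])
        rows.append((f"{cat}_vs_none", float(diff.mean()), float(tstat),
                     float(p), len(sub)))
    return pd.DataFrame(rows, columns=["contrast", "mean_diff", "t", "p", "n_birds"])


def husbandry_periodogram(husbandry: HusbandryLog, alpha: float = 0.05) -> PeriodogramResult:
    """Chi-squared periodogram of the visit schedule.

    Visits become an hourly 0/1 event series over the log span (>= 10 days
    required).  An empty log yields the degenerate (constant) result.
    """
    n_days = husbandry.n_days
    if not n_days and len(husbandry.visits):
        n_days = int(np.ceil((husbandry.visits.max() + 1e-9) / 24.0))
    if n_days < 10:
        raise ValueError("husbandry periodogram needs a log spanning >= 10 days")
    edges_hours = n_days * 24
    events = np.zeros(edges_hours)
    if len(husbandry.visits):
        # visit in (h-1, h] marks hour h (clipped into the span)
        hour_idx = np.minimum(np.ceil(husbandry.visits).astype(int),
                              edges_hours - 1)
        events[hour_idx] = 1.0
    return chi2_periodogram(events, alpha=alpha)


def window_is_unmasked(husbandry: HusbandryLog, start_day: int, n_days: int = 10,
                       alpha: float = 0.05, period: float = 24.0) -> bool:
    """True when the husbandry schedule in a window is NOT significantly
    rhythmic at the given period — the guard for reporting Tb periodograms
    under constant conditions."""
    sel = (husbandry.visits >= 24.0 * start_day) & \
        (husbandry.visits < 24.0 * (start_day + n_days))
    sub = HusbandryLog(visits=husbandry.visits[sel] - 24.0 * start_day,
                       mode=husbandry.mode, window=husbandry.window,
                       n_days=n_days)
    result = husbandry_periodogram(sub, alpha=alpha)
    return result.degenerate or not result.is_significant_at(period)
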