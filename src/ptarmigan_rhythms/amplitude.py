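"""Daily Tb amplitude extraction and mixed-model treatment comparison.

Amplitude is the raw daily range — maximum minus minimum Tb within a
calendar day, per bird — not a fitted sinusoid amplitude.  Treatments are
compared with a linear mixed model (treatment fixed effect, random
intercept per bird, REML variance components); estimated marginal means
per treatment, Tukey-adjusted pairwise contrasts, and a likelihood-ratio
test of the treatment effect from maximum-likelihood refits (LRs between
fixed-effect structures are invalid under REML).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, studentized_range

from .light import LightSchedule
from .series import TbSeries

__all__ = ["daily_extrema", "build_amplitude_table", "fit_amplitude_model", "AmplitudeFit"]

log = logging.getLogger(__name__)


def daily_extrema(series: TbSeries, schedule: LightSchedule | None = None,
                  min_completeness: float = 0.9) -> pd.DataFrame:
    """Per-day Tb max, min and amplitude for one bird.

    Day boundaries at clock midnight.  Days with fewer than
    ``min_completeness`` of their expected samples are dropped (logged).
    Returns columns: bird_id, treatment, day, tb_max, tb_min, amplitude.
    """
    rows = []
    if len(series) == 0:
        return pd.DataFrame(columns=["bird_id", "treatment", "day",
                                     "tb_max", "tb_min", "amplitude"])
    per_day = int(round(24.0 / series.sampling_interval))
    day = np.floor(series.t / 24.0 + 1e-9).astype(int)
    for d in np.unique(day):
        vals = series.tb[day == d]
        finite = vals[np.isfinite(vals)]
        if len(finite) < min_completeness * per_day:
            log.info("bird %s day %d dropped: %d/%d finite samples",
                     series.bird_id, d, len(finite), per_day)
            continue
        rows.append((series.bird_id, series.treatment, int(d),
                     float(finite.max()), float(finite.min()),
                     float(finite.max() - finite.min())))
    return pd.DataFrame(rows, columns=["bird_id", "treatment", "day",
                                       "tb_max", "tb_min", "amplitude"])


def _transition_days(schedule: LightSchedule) -> np.ndarray:
    """Days whose photoperiod differs from the previous day's."""
    p = schedule.lights_off - schedule.lights_on
    changed = np.flatnonzero(np.abs(np.diff(p)) > 1e-9) + 1
    return changed


def build_amplitude_table(series_list, schedules: dict[str, LightSchedule] | None = None,
                          exclude_transitions: bool = True,
                          exclude_half_hour: bool = True) -> pd.DataFrame:
    """Pool per-bird daily extrema into one amplitude table.

    Mirrors the analysis filters: birds sampled at other than 1 h are
    excluded, as are days on which the photoperiod was in transition.
    """
    parts = []
    for series in series_list:
        if exclude_half_hour and abs(series.sampling_interval - 1.0) > 1e-9:
            log.info("bird %s excluded: sampling interval %.2f h",
                     series.bird_id, series.sampling_interval)
            continue
        schedule = (schedules or {}).get(series.treatment)
        tab = daily_extrema(series, schedule)
        if exclude_transitions and schedule is not None:
            tab = tab[~tab["day"].isin(_transition_days(schedule))]
        parts.append(tab)
    if not parts:
        return pd.DataFrame(columns=["bird_id", "treatment", "day",
                                     "tb_max", "tb_min", "amplitude"])
    return pd.concat(parts, ignore_index=True)


@dataclass
class AmplitudeFit:
    """Mixed-model amplitude comparison across photoperiod treatments."""

    emmeans: pd.DataFrame  # treatment, estimate, se
    contrasts: pd.DataFrame  # a, b, estimate, se, t, p_adj
    lr_stat: float
    lr_df: int
    lr_p: float
    var_bird: float
    var_resid: float
    boundary_fit: bool = False  # between-bird variance at/near zero
    notes: list = field(default_factory=list)

    def emm(self, treatment: str) -> float:
        row = self.emmeans[self.emmeans["treatment"] == treatment]
        return float(row["estimate"].iloc[0])

    def contrast_p(self, a: str, b: str) -> float:
        c = self.contrasts
        row = c[((c["a"] == a) & (c["b"] == b)) | ((c["a"] == b) & (c["b"] == a))]
        return float(row["p_adj"].iloc[0])


def fit_amplitude_model(table: pd.DataFrame) -> AmplitudeFit:
    """Random-intercept mixed model of daily amplitude on treatment.

    Requires >= 2 treatments, >= 2 birds per treatment, >= 2 days per bird.
    """
    import statsmodels.formula.api as smf

    table = table.copy()
    treatments = sorted(table["treatment"].unique())
    if len(treatments) < 2:
        raise ValueError("need at least two treatments")
    per_treat_birds = table.groupby("treatment")["bird_id"].nunique()
    if (per_treat_birds < 2).any():
        raise ValueError("need at least two birds per treatment")
    per_bird_days = table.groupby("bird_id")["day"].nunique()
    if (per_bird_days < 2).any():
        raise ValueError("need at least two days per bird")

    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("amplitude ~ C(treatment)", data=table, groups="bird_id")
        fit = model.fit(reml=True)
        var_bird = float(fit.cov_re.iloc[0, 0])
        var_resid = float(fit.scale)
        boundary = var_bird < 1e-8 * max(var_resid, 1e-12)
        if boundary:
            notes.append("between-bird variance at boundary (~0); "
                         "estimates equal ordinary group means")

        # estimated marginal means: design row per treatment
        params = fit.fe_params
        cov = fit.cov_params().iloc[: len(params), : len(params)]
        names = list(params.index)

        def design_row(treat: str) -> np.ndarray:
            row = np.zeros(len(names))
            row[names.index("Intercept")] = 1.0
            key = f"C(treatment)[T.{treat}]"
            if key in names:
                row[names.index(key)] = 1.0
            return row

        emm_rows = []
        for tr in treatments:
            r = design_row(tr)
            est = float(r @ params.values)
            se = float(np.sqrt(r @ cov.values @ r))
            emm_rows.append((tr, est, se))
        emmeans = pd.DataFrame(emm_rows, columns=["treatment", "estimate", "se"])

        # Tukey-adjusted pairwise contrasts on the fixed-effect covariance
        k = len(treatments)
        resid_df = len(table) - k
        contrast_rows = []
        for a, b in itertools.combinations(treatments, 2):
            r = design_row(a) - design_row(b)
            est = float(r @ params.values)
            se = float(np.sqrt(r @ cov.values @ r))
            tval = est / se if se > 0 else np.inf * np.sign(est)
            q = abs(tval) * np.sqrt(2.0)
            p_adj = float(studentized_range.sf(q, k, resid_df))
            contrast_rows.append((a, b, est, se, tval, min(max(p_adj, 0.0), 1.0)))
        contrasts = pd.DataFrame(
            contrast_rows, columns=["a", "b", "estimate", "se", "t", "p_adj"])

        # LR test of the treatment effect from ML refits
        ml_full = smf.mixedlm("amplitude ~ C(treatment)", data=table,
                              groups="bird_id").fit(reml=False)
        ml_null = smf.mixedlm("amplitude ~ 1", data=table,
                              groups="bird_id").fit(reml=False)
        lr = float(max(0.0, 2.0 * (ml_full.llf - ml_null.llf)))
        lr_df = k - 1
        lr_p = float(chi2.sf(lr, lr_df))

    return AmplitudeFit(emmeans=emmeans, contrasts=contrasts, lr_stat=lr,
                        lr_df=lr_df, lr_p=lr_p, var_bird=var_bird,
                        var_resid=var_resid, boundary_fit=boundary, notes=notes)
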