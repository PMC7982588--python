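"""Config-driven orchestration: simulate a cohort to CSV fixtures, run the
full analysis, and emit the paper-shaped outputs (periodogram tables,
amplitude table with contrasts, breakpoint and secondary-peak summaries,
husbandry tests) plus a machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .amplitude import build_amplitude_table, fit_amplitude_model
from .anticipation import (dawn_profile, fit_segmented, secondary_peak,
                           summarize_breakpoints, zt_to_hhmm)
from .cohort import (Cohort, dawn_cohort, default_activity_cohort,
                     default_cohort)
from .husbandry import (categorize, husbandry_periodogram, paired_category_test,
                        window_is_unmasked)
from .periodogram import analysis_window, build_actogram, chi2_periodogram
from .series import normalize_activity, series_to_frame

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulation", "run_analysis", "run_all"]


@dataclass
class RunConfig:
    """Seeds and analysis options for a full simulated experiment."""

    master_seed: int = 0
    outdir: str = "results/run"
    alpha: float = 0.05
    window_days: int = 10
    window_start: int = 2
    quick: bool = False
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulation(config: RunConfig, force: bool = False) -> Path:
    """Simulate the default cohort and write CSV fixtures + manifest."""
    outdir = Path(config.outdir) / "fixtures"
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists; pass force=True (--force) to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = default_cohort(seed=config.master_seed, quick=config.quick)
    frames = []
    for s in cohort.tb:
        frames.append(series_to_frame(s).assign(treatment=s.treatment))
    tb_all = pd.concat(frames, ignore_index=True)
    tb_all.to_csv(outdir / "tb.csv", index=False)

    acts, act_scheds, _ = default_activity_cohort(seed=config.master_seed)
    act_frames = [series_to_frame(a).assign(treatment=a.treatment) for a in acts]
    pd.concat(act_frames, ignore_index=True).to_csv(outdir / "activity.csv", index=False)

    for treatment, sched in cohort.schedules.items():
        sched.to_frame().to_csv(outdir / f"schedule_{treatment}.csv", index=False)
    for treatment, hus in cohort.husbandry.items():
        hus.to_frame().to_csv(outdir / f"husbandry_{treatment}.csv", index=False)

    manifest = {
        "master_seed": config.master_seed,
        "quick": config.quick,
        "files": {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote %d fixture files to %s", len(manifest["files"]), outdir)
    return outdir


def _periodogram_stage(cohort: Cohort, config: RunConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    for s in cohort.tb:
        if abs(s.sampling_interval - 1.0) > 1e-9:
            continue
        hus = cohort.husbandry.get(s.treatment)
        start = config.window_start
        avail = int(s.t[-1] // 24 + 1) - start
        n_days = min(config.window_days, avail)
        guarded = True
        if s.treatment in ("LL", "DD") and hus is not None and n_days >= 10:
            guarded = window_is_unmasked(hus, start, n_days, config.alpha)
            if not guarded:
                log.warning("bird %s %s: window day %d masked by rhythmic husbandry",
                            s.bird_id, s.treatment, start)
        win = analysis_window(s, start, n_days)
        res = chi2_periodogram(win, alpha=config.alpha)
        rows.append({
            "bird_id": s.bird_id, "treatment": s.treatment,
            "window_start_day": start, "window_days": n_days,
            "sig_24h": res.is_significant_at(24.0),
            "peak_period_h": res.peak_significant_period(),
            "window_unmasked": guarded,
        })
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "periodogram_summary.csv", index=False)
    return table


def _amplitude_stage(cohort: Cohort, outdir: Path):
    table = build_amplitude_table(cohort.tb, cohort.schedules)
    fit = fit_amplitude_model(table)
    fit.emmeans.to_csv(outdir / "amplitude_emmeans.csv", index=False)
    fit.contrasts.to_csv(outdir / "amplitude_contrasts.csv", index=False)
    table.to_csv(outdir / "amplitude_table.csv", index=False)
    return fit


def _anticipation_stage(config: RunConfig, outdir: Path) -> dict:
    out = {}
    n_days = 7
    days = range(1, 6)
    for group in ("SP", "LP"):
        birds, sched = dawn_cohort(group, seed=config.master_seed, n_days=n_days)
        tb_fits, act_fits = [], []
        for tb, act, _ in birds:
            prof = dawn_profile(tb, sched, days=days,
                                activity=normalize_activity(act))
            tb_fits.append(fit_segmented(prof.offsets, prof.tb_mean))
            act_fits.append(fit_segmented(prof.offsets, prof.act_mean))
        out[group] = {
            "tb": summarize_breakpoints(tb_fits),
            "activity": summarize_breakpoints(act_fits),
        }
    rows = [{"group": g, "signal": sig, "breakpoint_zt": zt_to_hhmm(s.mean_zt),
             "breakpoint_zt_h": s.mean_zt, "sd_min": None if s.sd_h is None
             else round(s.sd_h * 60), "n_birds": s.n}
            for g, d in out.items() for sig, s in d.items()]
    pd.DataFrame(rows).to_csv(outdir / "breakpoints.csv", index=False)
    return out


def _secondary_peak_stage(cohort: Cohort, config: RunConfig, outdir: Path) -> dict:
    out = {}
    days = range(5, 15) if not config.quick else range(0, 5)
    specs = [("SP", "dark", "nocturnal_peak"), ("LP", "light", "afternoon_peak")]
    rows = []
    for treatment, phase, name in specs:
        peaks = []
        for s in cohort.tb_by_treatment(treatment)[:3]:
            if abs(s.sampling_interval - 1.0) > 1e-9:
                continue
            usable = [d for d in days if d < len(cohort.schedules[treatment].lights_on)]
            _, _, pk = secondary_peak(s, cohort.schedules[treatment], phase, usable)
            peaks += pk
        if peaks:
            out[name] = (float(np.mean(peaks)), float(np.std(peaks, ddof=1)))
            rows.append({"peak": name, "treatment": treatment,
                         "zt": zt_to_hhmm(out[name][0]), "zt_h": out[name][0],
                         "sd_h": out[name][1], "n_day_peaks": len(peaks)})
    pd.DataFrame(rows).to_csv(outdir / "secondary_peaks.csv", index=False)
    return out


def _husbandry_stage(cohort: Cohort, config: RunConfig, outdir: Path) -> pd.DataFrame:
    frames = []
    for treatment in ("LL", "DD"):
        hus = cohort.husbandry[treatment]
        cat = pd.concat([categorize(s, hus) for s in cohort.tb_by_treatment(treatment)],
                        ignore_index=True)
        res = paired_category_test(cat).assign(treatment=treatment)
        hp = husbandry_periodogram(hus, alpha=config.alpha) if hus.n_days >= 10 else None
        res["husbandry_24h_rhythmic"] = (
            hp.is_significant_at(24.0) if hp is not None else None)
        frames.append(res)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(outdir / "husbandry_tests.csv", index=False)
    return table


def _actogram_stage(cohort: Cohort, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for treatment in ("SP", "LL"):
        series = cohort.tb_by_treatment(treatment)
        if not series:
            continue
        act = build_actogram(series[0], double_plot=True, tb_range=(40.0, 42.0))
        ax = act.plot(title=f"Tb actogram, {series[0].bird_id} ({treatment})")
        ax.figure.savefig(outdir / f"actogram_tb_{treatment}.png", dpi=110,
                          bbox_inches="tight")
        plt.close(ax.figure)


def run_analysis(config: RunConfig, force: bool = False) -> dict:
    """Run every analysis stage on a freshly simulated default cohort.

    Returns the summary dict (also written to ``summary.json``); failures
    in a stage leave a FAILED marker next to the partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"master_seed": config.master_seed, "alpha": config.alpha,
                     "window_days": config.window_days}
    try:
        cohort = default_cohort(seed=config.master_seed, quick=config.quick)

        fit = _amplitude_stage(cohort, outdir)
        for _, row in fit.emmeans.iterrows():
            summary[f"amplitude_emm_{row['treatment']}"] = round(row["estimate"], 4)
            summary[f"amplitude_se_{row['treatment']}"] = round(row["se"], 4)
        summary["amplitude_lr"] = round(fit.lr_stat, 3)
        summary["amplitude_lr_p"] = float(fit.lr_p)
        summary["p_SP_vs_LP"] = fit.contrast_p("SP", "LP")
        summary["p_DD_vs_LL"] = fit.contrast_p("DD", "LL")

        per = _periodogram_stage(cohort, config, outdir)
        for treatment, grp in per.groupby("treatment"):
            summary[f"frac_sig24_{treatment}"] = float(grp["sig_24h"].mean())

        bp = _anticipation_stage(config, outdir)
        for g, d in bp.items():
            summary[f"breakpoint_tb_{g}_zt"] = round(d["tb"].mean_zt, 3)
            summary[f"breakpoint_act_{g}_zt"] = round(d["activity"].mean_zt, 3)

        peaks = _secondary_peak_stage(cohort, config, outdir)
        for name, (mean_zt, sd) in peaks.items():
            summary[f"{name}_zt"] = round(mean_zt, 3)
            summary[f"{name}_sd_h"] = round(sd, 3)

        hus = _husbandry_stage(cohort, config, outdir)
        for _, row in hus.iterrows():
            key = f"husbandry_{row['treatment']}_{row['contrast']}"
            summary[key + "_diff"] = round(row["mean_diff"], 4)
            summary[key + "_p"] = float(row["p"])

        if config.make_plots:
            _actogram_stage(cohort, outdir)
    except Exception:
        (outdir / "FAILED").write_text("analysis failed; partial outputs retained\n")
        raise
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_all(config: RunConfig, force: bool = False) -> dict:
    run_simulation(config, force=force)
    return run_analysis(config, force=force)
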