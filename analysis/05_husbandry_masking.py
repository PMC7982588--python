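"""Husbandry masking under constant conditions.

Assigns every constant-condition Tb sample to husbandry / 1-h-after /
none categories, compares per-bird category means with paired t-tests
(stress hyperthermia should elevate the husbandry category), and runs a
chi-squared periodogram on the visit log itself to confirm the
randomized schedule is not a hidden 24 h zeitgeber for the analysis
windows.

Run:  python analysis/05_husbandry_masking.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from ptarmigan_rhythms import (categorize, default_cohort,
                               husbandry_periodogram, paired_category_test,
                               window_is_unmasked)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    outdir = Path(args.out) / "husbandry"
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = default_cohort(seed=args.seed)
    frames = []
    for treatment in ("LL", "DD"):
        hus = cohort.husbandry[treatment]
        cats = pd.concat([categorize(s, hus)
                          for s in cohort.tb_by_treatment(treatment)],
                         ignore_index=True)
        res = paired_category_test(cats).assign(treatment=treatment)
        frames.append(res)
        for _, r in res.iterrows():
            print(f"{treatment} {r['contrast']:>18}: mean diff "
                  f"{r['mean_diff']:+.3f} °C, t = {r['t']:.2f}, "
                  f"p = {r['p']:.4f} (n = {r['n_birds']} birds)")
        pg = husbandry_periodogram(hus)
        sig24 = pg.is_significant_at(24.0)
        ok = window_is_unmasked(hus, 2, 10)
        print(f"{treatment} husbandry schedule: 24 h "
              f"{'significant' if sig24 else 'not significant'}; "
              f"day-2 analysis window {'clean' if ok else 'MASKED'}")
    pd.concat(frames, ignore_index=True).to_csv(outdir / "paired_tests.csv",
                                                index=False)
    print(f"tables in {outdir}")


if __name__ == "__main__":
    main()
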