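#!/usr/bin/env python
"""Compare fitted parameters between groups, per ROI and pooled.

Runs Shapiro-Wilk normality screening and Wilcoxon-Mann-Whitney tests
(exact p for the per-ROI 11-vs-9 comparisons, z approximation for the
pooled one) on the retained fits from 02_fit_parameters.py.
"""

import argparse
from pathlib import Path

import pandas as pd

from thermofit.stats import normality_test, region_stats

import warnings


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fits", type=Path, default=Path("results/fits_retained.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    fits = pd.read_csv(args.fits)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for roi, sub in fits.groupby("roi"):
            rows.extend(region_stats(sub, roi))
        rows.extend(region_stats(fits, "all 14 ROIs"))

    table = pd.DataFrame(
        {
            "roi": [s.roi_label for s in rows],
            "parameter": [s.parameter for s in rows],
            "psa_mean": [s.psa_mean for s in rows],
            "psa_sd": [s.psa_sd for s in rows],
            "hc_mean": [s.hc_mean for s in rows],
            "hc_sd": [s.hc_sd for s in rows],
            "ranksum": [s.ranksum for s in rows],
            "z": [s.z for s in rows],
            "p_value": [s.p_value for s in rows],
            "significant": [s.significant for s in rows],
        }
    )
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "group_stats.csv", index=False)

    # normality screening on the pooled parameter distributions
    for p in ("lt", "a", "d", "k"):
        for g in ("PsA", "HC"):
            _, pval = normality_test(fits.loc[fits.group == g, p])
            if pval < 0.05:
                print(f"normality rejected for {p} in {g} (Shapiro p={pval:.2e})")

    sig = table[table.significant]
    print(f"\nsignificant group differences (alpha 0.05), {len(sig)} rows:")
    for _, r in sig.iterrows():
        z = "-" if pd.isna(r.z) else f"{r.z:.2f}"
        print(f"  {r.roi:14s} {r.parameter:2s} ranksum={r.ranksum:.0f} "
              f"z={z} p={r.p_value:.4f}")


if __name__ == "__main__":
    main()
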