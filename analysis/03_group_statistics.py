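#!/usr/bin/env python
"""Run the group-level statistical plan on the extracted vHDR metrics.

Stim-vs-mock reliability (paired t per chromophore, per group, channel
average and best channel), TD-vs-fASD amplitude and latency comparisons
(Welch t), the two-way mixed ANOVA on hemisphere OHb peaks, the
laterality-index group test, and Spearman correlations of LI and OHb
amplitude with the fASD clinical scores, with Benjamini-Hochberg FDR
adjustment within each test family.

Usage: python analysis/03_group_statistics.py
       [--metrics results/subject_metrics.csv]
       [--clinical scratch/cohort/clinical.csv]
       [--out results/stats_results.csv]
"""

import argparse
from pathlib import Path

import pandas as pd

from fnirs_vhdr.io import read_clinical_csv
from fnirs_vhdr.stats import run_full_stats


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--metrics", type=Path, default=Path("results/subject_metrics.csv"))
    ap.add_argument("--clinical", type=Path, default=Path("scratch/cohort/clinical.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/stats_results.csv"))
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    metrics = pd.read_csv(args.metrics)
    clinical = read_clinical_csv(args.clinical) if args.clinical.exists() else None
    results = run_full_stats(metrics, clinical)
    results.to_csv(args.out, index=False)

    res = results.set_index("test")
    print(f"wrote {len(results)} tests to {args.out}")
    for name, label in [
        ("reliability_TD_avg_OHb", "stim vs mock, TD, avg OHb (paired t)"),
        ("reliability_ASD_avg_OHb", "stim vs mock, ASD, avg OHb (paired t)"),
        ("amplitude_avg_OHb", "TD vs ASD avg OHb amplitude (Welch t)"),
        ("hemi_anova_interaction", "hemisphere x group interaction (F)"),
        ("LI_group", "laterality index TD vs ASD (Welch t)"),
        ("corr_LI_AQ_tot", "LI vs AQ, fASD (Spearman rho)"),
    ]:
        if name in res.index:
            row = res.loc[name]
            print(f"  {label}: stat={row['statistic']:+.3f}  "
                  f"p={row['p']:.2e}  p_adj={row['p_adj']:.2e}")


if __name__ == "__main__":
    main()
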