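#!/usr/bin/env python
"""Nonparametric group comparison of every CEA outcome.

Reads results/features.csv (from 01_build_cohort.py) and writes a
supplementary-style table with group means +- SD, Kruskal-Wallis H and
Holm-adjusted p per outcome, and Dunn pairwise post-hoc p-values:

    results/group_comparison.csv
"""

import argparse
from pathlib import Path

import pandas as pd

from cealab.group_stats import group_comparison_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path,
                    default=Path("results/features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    features = pd.read_csv(args.features)
    report = group_comparison_report(features)
    args.out.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out / "group_comparison.csv", index=False)

    sig = report[report["p_adj"] < 0.05]
    print(f"{len(sig)}/{len(report)} outcomes differ between groups "
          "after Holm correction:")
    cols = ["outcome", "H", "p_adj", "control_mean", "mtbi_mean", "ppcs_mean"]
    print(sig[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
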