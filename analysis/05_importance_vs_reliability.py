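#!/usr/bin/env python
"""Does outcome reliability predict diagnostic importance?

Joins the per-outcome ICCs (02_reliability.py) with the classifier's
consensus importance ranks (04_classification.py) and computes Kendall's
tau-b between them.  Importance ranks are negated so tau > 0 means more
reliable outcomes carry more diagnostic weight.

    results/icc_vs_importance.json
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cealab.group_stats import kendall_tau_b


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reliability", type=Path,
                    default=Path("results/reliability.csv"))
    ap.add_argument("--importance", type=Path,
                    default=Path("results/importance.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    rel = pd.read_csv(args.reliability).set_index("outcome")
    imp = pd.read_csv(args.importance).set_index("outcome")
    merged = rel.join(imp).dropna(subset=["icc", "mean_rank"])
    tau, p = kendall_tau_b(merged["icc"], -merged["mean_rank"])

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "icc_vs_importance.json").write_text(json.dumps(
        {"tau_b": round(tau, 4), "p": round(p, 4),
         "n_outcomes": int(len(merged))}, indent=2))
    print(f"Kendall tau-b = {tau:.3f} (p = {p:.3f}, "
          f"n = {len(merged)} outcomes)")


if __name__ == "__main__":
    main()
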