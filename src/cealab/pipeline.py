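"""One-command pipeline: simulate -> extract -> reliability -> stats -> classify.

Writes every report as CSV/JSON plus a manifest with the configuration
hash and checksums of the outputs, so a rerun under the same
configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import run_protocol
from .config import PipelineConfig
from .features import FEATURE_COLUMNS, build_feature_table
from .group_stats import group_comparison_report, kendall_tau_b
from .reliability import reliability_report
from .synthetic_cohort import CohortSpec, simulate_cohort


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(cfg: PipelineConfig) -> dict[str, str]:
    """Run the full battery analysis; returns a name -> path map."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # 1. baseline cohort and features
    spec = CohortSpec(n_control=cfg.n_control, n_mtbi=cfg.n_mtbi,
                      n_ppcs=cfg.n_ppcs, seed=cfg.seed)
    cohort = simulate_cohort(spec, tests=cfg.tests)
    features = build_feature_table(cohort.trials)
    paths["features"] = out / "features.csv"
    features.to_csv(paths["features"], index=False)
    paths["ground_truth"] = out / "ground_truth.csv"
    cohort.ground_truth.to_csv(paths["ground_truth"], index=False)

    # 2. paired-session retest cohort (healthy controls) -> reliability
    retest_spec = CohortSpec(n_control=cfg.n_retest, n_mtbi=0, n_ppcs=0,
                             seed=cfg.seed + 1, sessions=2)
    retest = simulate_cohort(retest_spec, tests=cfg.tests)
    retest_features = build_feature_table(retest.trials)
    s1 = retest_features[retest_features["session"] == 1]
    s2 = retest_features[retest_features["session"] == 2]
    rel = reliability_report(s1, s2)
    paths["reliability"] = out / "reliability.csv"
    rel.to_csv(paths["reliability"], index=False)

    # 3. group differences
    report = group_comparison_report(features)
    paths["group_comparison"] = out / "group_comparison.csv"
    report.to_csv(paths["group_comparison"], index=False)

    # 4. classification protocol
    agg = run_protocol(features, n_seeds=cfg.n_seeds, base_seed=cfg.seed,
                       cv_folds=cfg.cv_folds)
    summary = {
        "n_seeds": agg.n_seeds,
        "kappa_mean": agg.kappa_mean, "kappa_sd": agg.kappa_sd,
        "kappa_ci": list(agg.kappa_ci),
        "auc_mean": agg.auc_mean, "auc_sd": agg.auc_sd,
        "balanced_accuracy_mean": agg.balanced_accuracy_mean,
        "top5_outcomes": agg.top_outcomes(5),
        "importance_mean_rank": agg.importance_mean_rank,
    }
    paths["classification"] = out / "classification.json"
    paths["classification"].write_text(json.dumps(summary, indent=2))
    conf = np.sum([r.confusion for r in agg.runs], axis=0)
    paths["confusion"] = out / "confusion.csv"
    pd.DataFrame(conf, index=["true_control", "true_mtbi", "true_ppcs"],
                 columns=["pred_control", "pred_mtbi", "pred_ppcs"]
                 ).to_csv(paths["confusion"])

    # 5. reliability vs importance (Kendall tau-b)
    merged = rel.set_index("outcome").join(
        pd.Series(agg.importance_mean_rank, name="mean_rank"))
    merged = merged.dropna(subset=["icc", "mean_rank"])
    # higher importance = lower rank; negate so tau > 0 means "more
    # reliable outcomes matter more"
    try:
        tau, p = kendall_tau_b(merged["icc"], -merged["mean_rank"])
    except ValueError:
        tau, p = float("nan"), float("nan")
    paths["icc_vs_importance"] = out / "icc_vs_importance.json"
    paths["icc_vs_importance"].write_text(
        json.dumps({"tau_b": tau, "p": p, "n_outcomes": int(len(merged))},
                   indent=2))

    manifest = {
        "config": json.loads(cfg.to_json()),
        "config_hash": cfg.digest(),
        "python": platform.python_version(),
        "outputs": {name: {"path": str(p), "sha256_16": _sha(p)}
                    for name, p in paths.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return {name: str(p) for name, p in paths.items()}
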