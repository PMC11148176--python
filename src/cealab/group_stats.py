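"""Nonparametric three-group comparisons with multiplicity control.

Each outcome is compared across control/mTBI/PPCS with a Kruskal-Wallis
rank test; raw p-values are Holm-adjusted across the outcome family, and
significant outcomes get Dunn's rank-sum pairwise post-hoc tests (Holm
within the outcome).  Kendall's tau-b links per-outcome reliability to
classifier importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUP_ORDER = ("control", "mtbi", "ppcs")


@dataclass
class GroupTestResult:
    outcome: str
    H: float
    df: int
    p_raw: float
    p_adj: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    group_summaries: dict[str, tuple[float, float]] = field(default_factory=dict)


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    All-identical data yields H = 0, p = 1 rather than an error.
    """
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[np.isfinite(g)] for g in clean]
    clean = [g for g in clean if len(g)]
    if len(clean) < 2:
        raise ValueError("need at least 2 non-empty groups")
    df = len(clean) - 1
    pooled = np.concatenate(clean)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*clean)
    return float(h), df, float(p)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def dunn_posthoc(groups: dict[str, Sequence[float]]) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-tests on pooled ranks, Holm-adjusted.

    Uses the pooled-rank variance with tie correction; empty groups are
    skipped.
    """
    labels = [g for g in groups if len(np.asarray(groups[g])[
        np.isfinite(np.asarray(groups[g], dtype=float))])]
    values = {g: np.asarray(groups[g], dtype=float) for g in labels}
    values = {g: v[np.isfinite(v)] for g, v in values.items()}
    pooled = np.concatenate([values[g] for g in labels])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in labels:
        stop = start + len(values[g])
        mean_ranks[g] = float(np.mean(ranks[start:stop]))
        start = stop
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    pairs = list(combinations(labels, 2))
    p_raw = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1 / len(values[a]) + 1 / len(values[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw.append(2 * stats.norm.sf(abs(z)))
    p_adj = holm_adjust(p_raw) if p_raw else np.array([])
    return {pair: float(p) for pair, p in zip(pairs, p_adj)}


def kendall_tau_b(x: Sequence[float], y: Sequence[float]
                  ) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 finite pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; tau undefined")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def group_comparison_report(features: pd.DataFrame,
                            outcomes: Sequence[str] | None = None,
                            ) -> pd.DataFrame:
    """Per-outcome group comparison table.

    Columns: group mean +- sd per group, Kruskal-Wallis H/df/p, Holm p
    across the outcome family, and Dunn pairwise Holm p within outcome.
    """
    from .features import FEATURE_COLUMNS

    outcomes = list(outcomes or FEATURE_COLUMNS)
    results: list[GroupTestResult] = []
    for outcome in outcomes:
        groups = {g: features.loc[features["group"] == g, outcome].to_numpy()
                  for g in GROUP_ORDER if (features["group"] == g).any()}
        summaries = {}
        for g, v in groups.items():
            v = v[np.isfinite(v)]
            summaries[g] = (float(np.mean(v)) if len(v) else np.nan,
                            float(np.std(v, ddof=1)) if len(v) > 1 else np.nan)
        try:
            h, df, p = kruskal_wallis(*groups.values())
        except ValueError:
            h, df, p = np.nan, len(groups) - 1, np.nan
        results.append(GroupTestResult(outcome=outcome, H=h, df=df, p_raw=p,
                                       p_adj=np.nan,
                                       pairwise=dunn_posthoc(groups)
                                       if len(groups) >= 2 else {},
                                       group_summaries=summaries))

    finite = [i for i, r in enumerate(results) if np.isfinite(r.p_raw)]
    if finite:
        adj = holm_adjust([results[i].p_raw for i in finite])
        for i, p in zip(finite, adj):
            results[i].p_adj = float(p)

    rows = []
    for r in results:
        row: dict[str, object] = {"outcome": r.outcome, "H": r.H, "df": r.df,
                                  "p_raw": r.p_raw, "p_adj": r.p_adj}
        for g in GROUP_ORDER:
            mean, sd = r.group_summaries.get(g, (np.nan, np.nan))
            row[f"{g}_mean"] = mean
            row[f"{g}_sd"] = sd
        for (a, b), p in r.pairwise.items():
            row[f"p_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
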