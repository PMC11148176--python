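"""Multiclass diagnostic classification protocol.

Mirrors the study's machine-learning pipeline: center/scale the outcome
table with parameters fitted on the training partition only, stratified
70/30 split, dropout-regularized gradient-boosted trees (DART booster)
tuned by 10-fold cross-validated Cohen's kappa, evaluation on the
held-out test set (confusion matrix, per-class balanced accuracy, mean
pairwise one-vs-one AUC, gain importance), and the whole process repeated
over 10 random seeds so no single split drives the conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix,
    make_scorer,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from . import config
from .features import FEATURE_COLUMNS

CLASS_ORDER = ("control", "mtbi", "ppcs")

#: small fixed hyperparameter grid so runs are reproducible
DEFAULT_PARAM_GRID = {
    "max_depth": [2, 3],
    "rate_drop": [0.0, 0.2],
}


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = config.TRAIN_FRACTION
    stratify: bool = True
    seed: int = 0


@dataclass
class ModelRunResult:
    seed: int
    kappa: float
    accuracy: float
    confusion: np.ndarray            # rows = truth, cols = prediction
    per_class: dict[str, dict[str, float]]
    pairwise_auc_mean: float
    pairwise_auc: dict[tuple[str, str], float]
    importance: dict[str, float]
    best_params: dict
    cv_kappa: float


@dataclass
class AggregateResult:
    n_seeds: int
    kappa_mean: float
    kappa_sd: float
    kappa_ci: tuple[float, float]
    auc_mean: float
    auc_sd: float
    balanced_accuracy_mean: dict[str, float]
    importance_mean_rank: dict[str, float]
    runs: list[ModelRunResult] = field(default_factory=list)

    def top_outcomes(self, k: int = 5) -> list[str]:
        ranked = sorted(self.importance_mean_rank, key=self.importance_mean_rank.get)
        return ranked[:k]


def _outcome_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_COLUMNS if c in features.columns]


def preprocess(features: pd.DataFrame, split: SplitSpec
               ) -> tuple[pd.DataFrame, pd.DataFrame, StandardScaler]:
    """Impute, split and normalize the FeatureTable.

    Missing outcomes are mean-imputed (within group on the training rows,
    by training-column mean on test rows, so test labels never leak).
    Constant columns after pooling are dropped with a warning attribute.
    Center/scale parameters come from the training partition only.
    """
    cols = _outcome_columns(features)
    df = features[["participant_id", "group", *cols]].copy()

    idx_train, idx_test = train_test_split(
        df.index, train_size=split.train_fraction,
        stratify=df["group"] if split.stratify else None,
        random_state=split.seed, shuffle=True)
    train = df.loc[idx_train].copy()
    test = df.loc[idx_test].copy()
    if split.stratify:
        missing = set(CLASS_ORDER) - set(train["group"])
        if missing:
            raise ValueError(f"classes absent from training partition: {missing}")

    group_means = train.groupby("group")[cols].transform("mean")
    train[cols] = train[cols].fillna(group_means)
    test[cols] = test[cols].fillna(train[cols].mean())

    constant = [c for c in cols if train[c].std(ddof=0) == 0]
    keep = [c for c in cols if c not in constant]
    scaler = StandardScaler().fit(train[keep])
    train[keep] = scaler.transform(train[keep])
    test[keep] = scaler.transform(test[keep])
    train = train.drop(columns=constant)
    test = test.drop(columns=constant)
    train.attrs["dropped_constant"] = constant
    return train, test, scaler


def _make_model(seed: int, **params) -> XGBClassifier:
    return XGBClassifier(
        booster="dart",
        n_estimators=60,
        learning_rate=0.3,
        skip_drop=0.5,
        objective="multi:softprob",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **params,
    )


def train_model(train: pd.DataFrame, cv_folds: int = config.CV_FOLDS,
                seed: int = 0,
                param_grid: dict | None = None) -> GridSearchCV:
    """Grid-search a DART gradient-boosted model by CV Cohen's kappa.

    Kappa, unlike raw accuracy, corrects for the unequal class sizes of
    the cohort (55/20/40), so a majority-class model scores ~0.
    """
    cols = _outcome_columns(train)
    x = train[cols].to_numpy(dtype=float)
    y = np.array([CLASS_ORDER.index(g) for g in train["group"]])
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train")
    # stratified folds cannot exceed the smallest class; shrink for small
    # cohorts so every fold sees every class
    folds = int(min(cv_folds, np.bincount(y).min()))
    if folds < 2:
        raise ValueError("smallest class has < 2 training members")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_model(seed),
        param_grid=param_grid or DEFAULT_PARAM_GRID,
        scoring=make_scorer(cohen_kappa_score),
        cv=cv, refit=True, n_jobs=1)
    search.fit(x, y)
    return search


def pairwise_auc(y_true: np.ndarray, scores: np.ndarray
                 ) -> dict[tuple[str, str], float]:
    """One-vs-one AUCs from class-probability scores (Hand-Till).

    For each class pair (i, j) only samples of those classes enter;
    A(i|j) ranks class-i samples by the class-i score and vice versa, and
    the pair AUC is the average of the two directions.  Midrank handling
    of ties comes from the underlying ROC computation.
    """
    out = {}
    for i, j in combinations(range(len(CLASS_ORDER)), 2):
        sel = np.isin(y_true, [i, j])
        if len(np.unique(y_true[sel])) < 2:
            continue
        a_ij = roc_auc_score((y_true[sel] == i).astype(int), scores[sel, i])
        a_ji = roc_auc_score((y_true[sel] == j).astype(int), scores[sel, j])
        out[(CLASS_ORDER[i], CLASS_ORDER[j])] = float((a_ij + a_ji) / 2)
    return out


def evaluate(model, test: pd.DataFrame, seed: int = 0) -> ModelRunResult:
    """Held-out evaluation: kappa, confusion, per-class metrics, AUC."""
    cols = _outcome_columns(test)
    x = test[cols].to_numpy(dtype=float)
    y = np.array([CLASS_ORDER.index(g) for g in test["group"]])
    pred = model.predict(x)
    scores = model.predict_proba(x)
    conf = confusion_matrix(y, pred, labels=range(len(CLASS_ORDER)))

    per_class = {}
    total = conf.sum()
    for i, name in enumerate(CLASS_ORDER):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        per_class[name] = {
            "sensitivity": float(sens), "specificity": float(spec),
            "balanced_accuracy": float((sens + spec) / 2),
        }

    aucs = pairwise_auc(y, scores)
    best = model.best_estimator_ if hasattr(model, "best_estimator_") else model
    booster = best.get_booster()
    gain = booster.get_score(importance_type="gain")
    importance = {c: float(gain.get(f"f{k}", 0.0)) for k, c in enumerate(cols)}
    return ModelRunResult(
        seed=seed,
        kappa=float(cohen_kappa_score(y, pred)),
        accuracy=float(np.mean(y == pred)),
        confusion=conf,
        per_class=per_class,
        pairwise_auc_mean=float(np.mean(list(aucs.values()))) if aucs else np.nan,
        pairwise_auc=aucs,
        importance=importance,
        best_params=dict(getattr(model, "best_params_", {})),
        cv_kappa=float(getattr(model, "best_score_", np.nan)),
    )


def run_protocol(features: pd.DataFrame, n_seeds: int = config.N_SEEDS,
                 base_seed: int = 0, cv_folds: int = config.CV_FOLDS,
                 param_grid: dict | None = None) -> AggregateResult:
    """Split -> CV-tune -> evaluate, repeated over ``n_seeds`` seeds."""
    runs: list[ModelRunResult] = []
    for k in range(n_seeds):
        seed = base_seed + k
        train, test, _ = preprocess(features, SplitSpec(seed=seed))
        model = train_model(train, cv_folds=cv_folds, seed=seed,
                            param_grid=param_grid)
        runs.append(evaluate(model, test, seed=seed))

    kappas = np.array([r.kappa for r in runs])
    aucs = np.array([r.pairwise_auc_mean for r in runs])
    half_width = 1.96 * kappas.std(ddof=1) / np.sqrt(len(runs)) if len(runs) > 1 else 0.0
    bal = {name: float(np.nanmean([r.per_class[name]["balanced_accuracy"]
                                   for r in runs])) for name in CLASS_ORDER}

    # consensus importance: mean rank of each outcome across seeds
    cols = list(runs[0].importance)
    ranks = np.zeros((len(runs), len(cols)))
    for ri, r in enumerate(runs):
        vals = np.array([r.importance[c] for c in cols])
        order = np.argsort(-vals)
        rank_of = np.empty(len(cols))
        rank_of[order] = np.arange(1, len(cols) + 1)
        ranks[ri] = rank_of
    mean_rank = {c: float(m) for c, m in zip(cols, ranks.mean(axis=0))}

    return AggregateResult(
        n_seeds=len(runs),
        kappa_mean=float(kappas.mean()),
        kappa_sd=float(kappas.std(ddof=1)) if len(runs) > 1 else 0.0,
        kappa_ci=(float(kappas.mean() - half_width),
                  float(kappas.mean() + half_width)),
        auc_mean=float(np.nanmean(aucs)),
        auc_sd=float(np.nanstd(aucs, ddof=1)) if len(runs) > 1 else 0.0,
        balanced_accuracy_mean=bal,
        importance_mean_rank=mean_rank,
        runs=runs,
    )
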