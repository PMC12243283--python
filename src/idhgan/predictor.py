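"""Gradient-boosted-tree grid harness and held-out test metrics.

A fixed 30-combination grid (six tree counts x five depths) of XGBoost
classifiers is trained on each dataset variant with all other
hyperparameters held constant, and every fit is scored on the same
held-out test table with six metrics: accuracy, precision, recall, F1
(confusion-matrix definitions at a 0.5 threshold), ROC-AUC (trapezoid)
and PR-AUC (step-interpolated average precision, the conservative
standard for imbalanced evaluation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from xgboost import XGBClassifier

from .synthetic_data import OUTCOME_COLUMN

__all__ = ["GridSpec", "MetricsRecord", "train_classifier",
           "compute_metrics", "run_experiment_grid"]


#: Fixed settings applied to every grid point (standard defaults; no
#: subsampling, L2 weight 1, no class re-weighting, fixed seed).
FIXED_XGB_PARAMS = dict(
    objective="binary:logistic",
    eval_metric=["logloss", "auc"],
    booster="gbtree",
    learning_rate=0.3,
    min_child_weight=1,
    gamma=0,
    subsample=1,
    colsample_bytree=1,
    colsample_bylevel=1,
    colsample_bynode=1,
    reg_alpha=0,
    reg_lambda=1,
    scale_pos_weight=1,
    tree_method="hist",
    max_bin=256,
    grow_policy="depthwise",
    random_state=42,
)


@dataclass(frozen=True)
class GridSpec:
    n_estimators: tuple = (80, 90, 100, 110, 120, 130)
    max_depth: tuple = (8, 10, 12, 14, 16)

    def points(self):
        return list(product(self.n_estimators, self.max_depth))

    def __len__(self):
        return len(self.n_estimators) * len(self.max_depth)


@dataclass
class MetricsRecord:
    dataset: str
    n_estimators: int
    max_depth: int
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float
    pr_auc: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def train_classifier(X: np.ndarray, y: np.ndarray, n_estimators: int,
                     max_depth: int, **overrides) -> XGBClassifier:
    """Fit one grid point; deterministic given the fixed random state."""
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    params = dict(FIXED_XGB_PARAMS)
    params.update(overrides)
    model = XGBClassifier(n_estimators=n_estimators, max_depth=max_depth,
                          **params)
    model.fit(np.asarray(X, dtype=np.float32), np.asarray(y, dtype=int))
    return model


def compute_metrics(probabilities, truth, threshold: float = 0.5,
                    dataset: str = "", n_estimators: int = 0,
                    max_depth: int = 0) -> MetricsRecord:
    """Confusion counts at the threshold, the four ratio metrics, and the
    two AUCs.  Single-class truth leaves ROC-AUC undefined (NaN)."""
    p = np.asarray(probabilities, float)
    t = np.asarray(truth, int)
    if p.shape != t.shape:
        raise ValueError("probabilities and truth must align")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (t == 1)).sum())
    tn = int(((pred == 0) & (t == 0)).sum())
    fp = int(((pred == 1) & (t == 0)).sum())
    fn = int(((pred == 0) & (t == 1)).sum())
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    if len(np.unique(t)) < 2:
        warnings.warn("single-class truth: ROC-AUC undefined")
        roc = float("nan")
        pr = float("nan")
    else:
        roc = float(roc_auc_score(t, p))
        pr = float(average_precision_score(t, p))
    return MetricsRecord(dataset=dataset, n_estimators=n_estimators,
                         max_depth=max_depth, tp=tp, tn=tn, fp=fp, fn=fn,
                         accuracy=accuracy, precision=precision,
                         recall=recall, f1=f1, roc_auc=roc, pr_auc=pr)


def run_experiment_grid(variants: dict, test: pd.DataFrame,
                        grid: GridSpec = GridSpec(),
                        feature_names: list | None = None,
                        label_column: str = OUTCOME_COLUMN) -> pd.DataFrame:
    """Train and evaluate every (variant, grid point) combination.

    ``variants`` maps a dataset name to its training table; every variant
    must share the test table's feature set.  Returns the long results
    table (one row per fit) consumed by the statistics layer.
    """
    import time

    if feature_names is None:
        feature_names = [c for c in test.columns
                         if c not in (label_column, "synthetic")]
    X_test = test[feature_names].to_numpy(dtype=np.float32)
    y_test = test[label_column].to_numpy(dtype=int)
    rows = []
    for name, table in variants.items():
        missing = [c for c in feature_names if c not in table.columns]
        if missing:
            raise ValueError(f"variant {name!r} lacks features {missing}")
        X = table[feature_names].to_numpy(dtype=np.float32)
        y = table[label_column].to_numpy(dtype=int)
        for n_est, depth in grid.points():
            t0 = time.perf_counter()
            model = train_classifier(X, y, n_est, depth)
            prob = model.predict_proba(X_test)[:, 1]
            rec = compute_metrics(prob, y_test, dataset=name,
                                  n_estimators=n_est, max_depth=depth)
            row = rec.as_dict()
            row["fit_seconds"] = time.perf_counter() - t0
            rows.append(row)
    return pd.DataFrame(rows)
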