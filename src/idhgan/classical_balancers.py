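"""From-scratch SMOTE and ADASYN oversampling benchmarks.

Both synthesize minority-class rows by linear interpolation between a
minority instance and one of its k nearest minority neighbors
(Euclidean distance in the scaled feature space, binary columns included
as 0/1 coordinates).  ADASYN additionally weights each minority point by
the fraction of majority-class points among its k nearest neighbors in
the FULL training set, concentrating synthesis near the class boundary;
per-point allocations use largest-remainder apportionment so the
generated total matches the class deficit exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .synthetic_data import OUTCOME_COLUMN

__all__ = ["OversampleConfig", "smote_balance", "adasyn_balance",
           "adasyn_allocation"]


def adasyn_allocation(r: np.ndarray, G: int) -> np.ndarray:
    """Per-point synthetic counts by largest-remainder apportionment of
    the normalized hardness weights, summing exactly to G.

    Naive per-point rounding is biased here: hardness fractions lie on a
    1/k lattice, so large blocks of points share identical fractional
    parts and round the same way, giving a surplus or deficit that grows
    with the minority count instead of averaging out.  Floor-then-assign
    by largest fractional remainder (ties to the lower index) keeps the
    allocation adaptive while hitting the requested total.
    """
    r = np.asarray(r, float)
    if r.sum() == 0:
        raise ValueError("all hardness weights are zero")
    share = r / r.sum() * G
    g = np.floor(share).astype(int)
    residual = int(G - g.sum())
    if residual > 0:
        frac = share - g
        # argsort is stable, so equal remainders resolve to lower indices
        top = np.argsort(-frac, kind="stable")[:residual]
        g[top] += 1
    return g


@dataclass(frozen=True)
class OversampleConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # 1.0 = full balance
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must be in (0, 1]")


def _split_classes(train: pd.DataFrame, label_column: str):
    y = train[label_column].to_numpy()
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    minority = 1 if n_pos < n_neg else 0
    return y, minority, min(n_pos, n_neg), max(n_pos, n_neg)


def _effective_k(k: int, n_min: int) -> int:
    if n_min < 2:
        raise ValueError("need at least 2 minority samples to oversample")
    if n_min <= k:
        warnings.warn(f"minority count {n_min} <= k={k}; reducing k to "
                      f"{n_min - 1}")
        return n_min - 1
    return k


def _interpolate(X_min: np.ndarray, anchors: np.ndarray,
                 neighbor_idx: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(size=(len(anchors), 1))
    a = X_min[anchors]
    b = X_min[neighbor_idx]
    return a + u * (b - a)


def _deficit(n_min: int, n_maj: int, ratio: float) -> int:
    return max(0, int(round(ratio * n_maj)) - n_min)


def smote_balance(train: pd.DataFrame, config: OversampleConfig = OversampleConfig(),
                  feature_names: list[str] | None = None,
                  label_column: str = OUTCOME_COLUMN) -> pd.DataFrame:
    """Synthesize (N_majority - N_minority) minority rows along random
    segments to k-nearest minority neighbors; output positive rate is
    exactly 50.00% at the default ratio."""
    if feature_names is None:
        feature_names = [c for c in train.columns if c != label_column]
    y, minority, n_min, n_maj = _split_classes(train, label_column)
    g_total = _deficit(n_min, n_maj, config.target_ratio)
    base = train.copy()
    base["synthetic"] = False
    if g_total == 0:
        return base
    k = _effective_k(config.k_neighbors, n_min)
    X_min = train.loc[y == minority, feature_names].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(config.seed)
    # Spread anchors evenly over minority points, remainder at random.
    reps = g_total // n_min
    anchors = np.concatenate([
        np.tile(np.arange(n_min), reps),
        rng.choice(n_min, size=g_total - reps * n_min, replace=False)
        if g_total - reps * n_min > 0 else np.empty(0, dtype=int),
    ]).astype(int)
    chosen = neigh[anchors, rng.integers(0, k, size=len(anchors))]
    synth_X = _interpolate(X_min, anchors, chosen, rng)
    synth = pd.DataFrame(synth_X, columns=feature_names)
    synth[label_column] = float(minority)
    synth["synthetic"] = True
    return pd.concat([base, synth], ignore_index=True)


def adasyn_balance(train: pd.DataFrame, config: OversampleConfig = OversampleConfig(),
                   feature_names: list[str] | None = None,
                   label_column: str = OUTCOME_COLUMN) -> pd.DataFrame:
    """Adaptive synthesis: minority points with more majority-class
    neighbors (harder to learn) receive proportionally more synthetic
    rows, allocated by largest-remainder apportionment of the hardness
    weights."""
    if feature_names is None:
        feature_names = [c for c in train.columns if c != label_column]
    y, minority, n_min, n_maj = _split_classes(train, label_column)
    G = _deficit(n_min, n_maj, config.target_ratio)
    base = train.copy()
    base["synthetic"] = False
    if G == 0:
        return base
    k = _effective_k(config.k_neighbors, n_min)
    X_all = train[feature_names].to_numpy(dtype=float)
    min_mask = y == minority
    X_min = X_all[min_mask]
    # r_i: majority fraction among each minority point's k nearest
    # neighbors in the full training set (self excluded).
    nn_all = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(X_all)
    neigh_all = nn_all.kneighbors(X_min, return_distance=False)[:, 1:]
    is_majority = (y != minority)[neigh_all]
    r = is_majority.mean(axis=1)
    if r.sum() == 0:
        warnings.warn("no minority point has majority neighbors; "
                      "falling back to uniform ADASYN weights")
        r = np.ones(n_min)
    g = adasyn_allocation(r, G)
    total = int(g.sum())
    if total == 0:
        return base
    nn_min = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh_min = nn_min.kneighbors(X_min, return_distance=False)[:, 1:]
    rng = np.random.default_rng(config.seed)
    anchors = np.repeat(np.arange(n_min), g.astype(int))
    chosen = neigh_min[anchors, rng.integers(0, k, size=len(anchors))]
    synth_X = _interpolate(X_min, anchors, chosen, rng)
    synth = pd.DataFrame(synth_X, columns=feature_names)
    synth[label_column] = float(minority)
    synth["synthetic"] = True
    return pd.concat([base, synth], ignore_index=True)

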