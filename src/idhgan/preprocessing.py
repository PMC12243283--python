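"""Leakage-safe preparation of measurement tables.

Chain: complete-case filtering -> dialysis-date encoding -> within-session
lagged features -> temporal train/test split -> robust tanh scaling fitted
on the training partition only.  No imputation is ever performed; rows
whose required lags are undefined are dropped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .synthetic_data import KEY_COLUMNS, OUTCOME_COLUMN

logger = logging.getLogger(__name__)

__all__ = [
    "ScalerParams",
    "SplitResult",
    "drop_incomplete",
    "encode_dialysis_date",
    "build_lagged_features",
    "temporal_split",
    "fit_robust_tanh",
    "transform_robust_tanh",
    "inverse_robust_tanh",
]


@dataclass
class ScalerParams:
    """Per-feature median/IQR plus the tanh scale constant.

    ``fit_on_train_only`` is a provenance flag asserting that no test-set
    statistic entered the fit.
    """

    medians: dict[str, float]
    iqrs: dict[str, float]
    c: float
    feature_names: list[str]
    fit_on_train_only: bool = True

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps({
            "medians": self.medians,
            "iqrs": self.iqrs,
            "c": self.c,
            "feature_names": self.feature_names,
            "fit_on_train_only": self.fit_on_train_only,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "ScalerParams":
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class SplitResult:
    train: pd.DataFrame
    test: pd.DataFrame
    cut_date: date
    train_fraction: float

    def manifest(self) -> dict:
        return {
            "cut_date": str(self.cut_date),
            "train_rows": int(len(self.train)),
            "test_rows": int(len(self.test)),
            "train_fraction": float(self.train_fraction),
        }


def drop_incomplete(table: pd.DataFrame,
                    columns: list[str] | None = None) -> pd.DataFrame:
    """Complete-case filter: keep only rows with no missing feature or
    outcome value.  Never imputes.  Exclusion counts are logged."""
    if columns is None:
        columns = [c for c in table.columns if c not in KEY_COLUMNS]
    out = table.dropna(subset=[c for c in columns if c in table.columns])
    n_dropped = len(table) - len(out)
    logger.info("complete-case filter: dropped %d of %d rows",
                n_dropped, len(table))
    if out.empty and len(table) > 0:
        warnings.warn("complete-case filtering removed every row")
    return out.reset_index(drop=True)


def encode_dialysis_date(table: pd.DataFrame,
                         mode: str = "days_elapsed") -> pd.DataFrame:
    """Add a numeric encoding of the dialysis date.

    ``days_elapsed``: integer days since the earliest date in the table
    (0 at the earliest).  ``weekday``: integer 0-6, Monday = 0 (the
    sensitivity-analysis toggle).
    """
    dates = pd.to_datetime(table["dialysis_date"])
    if dates.isna().any():
        raise ValueError("unparseable dialysis_date values")
    out = table.copy()
    if mode == "days_elapsed":
        out["dialysis_date_num"] = (dates - dates.min()).dt.days.astype(int)
    elif mode == "weekday":
        out["dialysis_date_num"] = dates.dt.weekday.astype(int)
    else:
        raise ValueError(f"unknown date mode {mode!r}")
    return out


def build_lagged_features(table: pd.DataFrame,
                          source_columns: list[str] | None = None,
                          lags: tuple[int, ...] = (1, 2)) -> pd.DataFrame:
    """Within-session lag-1/lag-2 features plus pulse-pressure derivations.

    Lags are computed strictly from earlier measurements of the SAME
    session; rows whose required lags are undefined are dropped (never
    zero-filled).  When both systolic and diastolic are present, the
    systolic-diastolic difference (pulse pressure) is added for the
    current and each lagged time point.
    """
    if source_columns is None:
        source_columns = [c for c in ("systolic", "diastolic", "pulse_rate")
                          if c in table.columns]
    missing = [c for c in source_columns if c not in table.columns]
    if missing:
        raise KeyError(f"lag source columns absent: {missing}")
    df = table.sort_values(["session_id", "measurement_index"],
                           kind="stable").reset_index(drop=True)
    grp = df.groupby("session_id", sort=False)
    lag_prefix = {1: "previous_", 2: "second_previous_"}
    new_cols = []
    for lag in lags:
        prefix = lag_prefix.get(lag, f"lag{lag}_")
        for col in source_columns:
            name = prefix + col
            df[name] = grp[col].shift(lag)
            new_cols.append(name)
    if {"systolic", "diastolic"} <= set(df.columns):
        df["systolic_diastolic_difference"] = df["systolic"] - df["diastolic"]
        for lag in lags:
            prefix = lag_prefix.get(lag, f"lag{lag}_")
            s, d = prefix + "systolic", prefix + "diastolic"
            if s in df.columns and d in df.columns:
                df[prefix + "systolic_diastolic_difference"] = df[s] - df[d]
    df = df.dropna(subset=new_cols).reset_index(drop=True)
    return df


def temporal_split(table: pd.DataFrame,
                   target_fraction: float = 0.75) -> SplitResult:
    """Chronological split at the between-date boundary whose realized
    record fraction is closest to the target; ties break to the earlier
    cut.  Sessions never straddle the cut (each session has one date)."""
    counts = (table.groupby("dialysis_date").size()
              .sort_index())
    if len(counts) < 2:
        raise ValueError("temporal split needs >= 2 distinct dialysis dates")
    cum = counts.cumsum() / counts.sum()
    # Feasible cuts: after each date except the last.
    fracs = cum.iloc[:-1]
    errors = (fracs - target_fraction).abs().to_numpy()
    best = int(np.argmin(errors))  # argmin takes the first (earlier) tie
    cut_date = counts.index[best]
    in_train = table["dialysis_date"] <= cut_date
    train = table[in_train].reset_index(drop=True)
    test = table[~in_train].reset_index(drop=True)
    return SplitResult(train=train, test=test, cut_date=cut_date,
                       train_fraction=len(train) / len(table))


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    # linear-interpolation quartile convention
    q1, q2, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(q1), float(q2), float(q3)


def fit_robust_tanh(train: pd.DataFrame, feature_names: list[str],
                    c: float = 0.5) -> ScalerParams:
    """Fit per-feature median and IQR on the training partition only.

    A constant feature (IQR == 0) falls back to IQR 1.0 with a warning,
    so its transform maps every value to 0.
    """
    if train.empty:
        raise ValueError("cannot fit scaler on an empty table")
    if c <= 0:
        raise ValueError("tanh scale constant c must be > 0")
    medians, iqrs = {}, {}
    for name in feature_names:
        x = train[name].to_numpy(dtype=float)
        q1, med, q3 = _quartiles(x)
        iqr = q3 - q1
        if iqr <= 0:
            warnings.warn(f"feature {name!r} has zero IQR; falling back to 1.0")
            iqr = 1.0
        medians[name] = med
        iqrs[name] = iqr
    return ScalerParams(medians=medians, iqrs=iqrs, c=c,
                        feature_names=list(feature_names))


def transform_robust_tanh(table: pd.DataFrame,
                          params: ScalerParams) -> pd.DataFrame:
    """x' = tanh(c * (x - median) / IQR), strictly inside (-1, 1).

    Columns not listed in the params (keys, outcome, binary features)
    pass through unchanged.
    """
    out = table.copy()
    for name in params.feature_names:
        if name not in table.columns:
            raise KeyError(f"scaler feature {name!r} missing from table")
        x = table[name].to_numpy(dtype=float)
        out[name] = np.tanh(params.c * (x - params.medians[name])
                            / params.iqrs[name])
    return out


def inverse_robust_tanh(table: pd.DataFrame,
                        params: ScalerParams) -> pd.DataFrame:
    """Inverse of :func:`transform_robust_tanh` on (-1, 1)."""
    out = table.copy()
    for name in params.feature_names:
        z = np.clip(table[name].to_numpy(dtype=float), -1 + 1e-15, 1 - 1e-15)
        out[name] = np.arctanh(z) * params.iqrs[name] / params.c \
            + params.medians[name]
    return out
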