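"""End-to-end orchestration of the five-stage workflow.

Stages: cohort generation (or CSV load) -> preprocessing -> construction
of the five dataset variants (Original, GAN Balanced, GAN Augmented,
SMOTE Balanced, ADASYN Balanced) -> distribution-fidelity report ->
hyperparameter-grid benchmark -> statistical comparison -> SHAP
interpretation.  Every stochastic stage consumes a seed derived from the
global seed by fixed offsets, recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .classical_balancers import OversampleConfig, adasyn_balance, smote_balance
from .fidelity import compare_methods, per_feature_distances
from .gan_balancer import GanConfig, assemble_dataset, sample_synthetic, train_cwgan_gp
from .interpretation import (compute_shap_matrix, export_beeswarm,
                             rank_features_by_mean_abs_shap)
from .predictor import GridSpec, run_experiment_grid, train_classifier
from .preprocessing import (build_lagged_features, drop_incomplete,
                            encode_dialysis_date, fit_robust_tanh,
                            temporal_split, transform_robust_tanh)
from .stats_eval import compare_variants, export_boxplots
from .synthetic_data import (KEY_COLUMNS, OUTCOME_COLUMN, CohortConfig,
                             generate_cohort, read_cohort, write_cohort)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_full_pipeline", "derive_seed",
           "STAGE_OFFSETS", "build_variants", "preprocess_cohort"]

#: Fixed per-stage seed offsets; stage_seed = (seed * 10 + offset) % 2**31.
STAGE_OFFSETS = {
    "cohort": 0,
    "gan": 1,
    "gan_sample": 2,
    "smote": 3,
    "adasyn": 4,
    "augment_sample": 5,
}


def derive_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 10 + STAGE_OFFSETS[stage]) % (2 ** 31)


class CohortSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = Field(40, ge=1)
    sessions_per_patient: int = Field(12, ge=1)
    measurements_per_session: int = Field(20, ge=1)
    start_date: date = date(2019, 9, 2)
    idh_target_prevalence: float = Field(0.1485, gt=0.0, lt=1.0)
    missing_rate: float = Field(0.02, ge=0.0, lt=1.0)


class PreprocessSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    date_mode: str = "days_elapsed"
    lags: tuple[int, ...] = (1, 2)
    lag_sources: tuple[str, ...] = ("systolic", "diastolic", "pulse_rate")
    scaler_c: float = Field(0.5, gt=0.0)
    train_fraction: float = Field(0.75, gt=0.0, lt=1.0)

    @field_validator("date_mode")
    @classmethod
    def _check_mode(cls, v):
        if v not in ("days_elapsed", "weekday"):
            raise ValueError("date_mode must be 'days_elapsed' or 'weekday'")
        return v


class GanSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = Field(200, ge=1)
    batch_size: int = Field(128, ge=1)
    noise_dim: int = Field(128, ge=1)
    hidden_dim: int = Field(256, ge=1)
    n_critic: int = Field(5, ge=1)
    gp_weight: float = Field(5.0, ge=0.0)
    lr_g: float = Field(1e-3, gt=0.0)
    lr_d: float = Field(2e-3, gt=0.0)
    spectral_norm: bool = True


class OversampleSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_neighbors: int = Field(5, ge=1)


class GridSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_estimators: tuple[int, ...] = (80, 90, 100, 110, 120, 130)
    max_depth: tuple[int, ...] = (8, 10, 12, 14, 16)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    input_csv: str | None = None
    cohort: CohortSettings = CohortSettings()
    preprocess: PreprocessSettings = PreprocessSettings()
    gan: GanSettings = GanSettings()
    oversample: OversampleSettings = OversampleSettings()
    grid: GridSettings = GridSettings()
    output_dir: str = "runs/latest"


def load_config(path) -> RunConfig:
    """Validated RunConfig from YAML; unknown keys are rejected with
    field-level messages."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(
        json.loads(config.model_dump_json()), sort_keys=False))


def _table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


def preprocess_cohort(table: pd.DataFrame, settings: PreprocessSettings):
    """Run the leakage-safe chain and return (split, scaler, feature names).

    Returned train/test tables hold scaled model features plus the label.
    """
    # Lags are built from true adjacent measurements first, so a missing
    # source value propagates into the lag and the row is excluded by the
    # complete-case filter, never borrowed from a non-adjacent row.
    dated = encode_dialysis_date(table, settings.date_mode)
    lagged = build_lagged_features(dated, list(settings.lag_sources),
                                   settings.lags)
    lagged = drop_incomplete(lagged)
    split = temporal_split(lagged, settings.train_fraction)

    exclude = set(KEY_COLUMNS) | {OUTCOME_COLUMN}
    feature_names = [c for c in lagged.columns if c not in exclude]
    binary = [c for c in feature_names
              if set(np.unique(lagged[c].to_numpy())) <= {0.0, 1.0}]
    continuous = [c for c in feature_names if c not in binary]
    scaler = fit_robust_tanh(split.train, continuous, c=settings.scaler_c)
    train = transform_robust_tanh(split.train, scaler)
    test = transform_robust_tanh(split.test, scaler)
    cols = feature_names + [OUTCOME_COLUMN]
    return split, scaler, feature_names, train[cols], test[cols]


def build_variants(train: pd.DataFrame, feature_names: list[str],
                   gan_settings: GanSettings,
                   oversample_settings: OversampleSettings,
                   seed: int):
    """The five dataset variants of the benchmark design."""
    gan_config = GanConfig(
        epochs=gan_settings.epochs, batch_size=gan_settings.batch_size,
        noise_dim=gan_settings.noise_dim, hidden_dim=gan_settings.hidden_dim,
        n_critic=gan_settings.n_critic, gp_weight=gan_settings.gp_weight,
        lr_g=gan_settings.lr_g, lr_d=gan_settings.lr_d,
        spectral_norm=gan_settings.spectral_norm,
        seed=derive_seed(seed, "gan"),
    )
    state = train_cwgan_gp(train, gan_config, feature_names=feature_names)
    os_config = OversampleConfig(k_neighbors=oversample_settings.k_neighbors,
                                 seed=derive_seed(seed, "smote"))
    variants = {
        "Original": train.assign(synthetic=False),
        "GAN Balanced": assemble_dataset(
            train, state, mode="balance",
            seed=derive_seed(seed, "gan_sample")),
        "GAN Augmented": assemble_dataset(
            train, state, mode="augment",
            seed=derive_seed(seed, "augment_sample")),
        "SMOTE Balanced": smote_balance(train, os_config,
                                        feature_names=feature_names),
        "ADASYN Balanced": adasyn_balance(
            train, OversampleConfig(
                k_neighbors=oversample_settings.k_neighbors,
                seed=derive_seed(seed, "adasyn")),
            feature_names=feature_names),
    }
    return variants, state


def _variant_size_table(variants: dict) -> pd.DataFrame:
    rows = []
    for name, df in variants.items():
        n = len(df)
        pos = int((df[OUTCOME_COLUMN] == 1).sum())
        rows.append({"dataset": name, "total_samples": n,
                     "positive_samples": pos,
                     "positive_rate_pct": round(100.0 * pos / n, 2)})
    return pd.DataFrame(rows)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and emit artifacts plus a reproducibility
    manifest; any stage failure aborts with a stage-tagged message."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stage_seeds": {s: derive_seed(config.seed, s)
                                      for s in STAGE_OFFSETS},
                      "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("collect")
        if config.input_csv:
            cohort = read_cohort(config.input_csv)
        else:
            cohort = generate_cohort(CohortConfig(
                seed=derive_seed(config.seed, "cohort"),
                **config.cohort.model_dump()))
        write_cohort(cohort, out / "cohort.csv")
        manifest["stages"][name] = {"rows": len(cohort),
                                    "hash": _table_hash(cohort)}

        name = stage("preprocess")
        split, scaler, feature_names, train, test = preprocess_cohort(
            cohort, config.preprocess)
        scaler.to_json(out / "scaler.json")
        (out / "split.json").write_text(json.dumps(split.manifest()))
        manifest["stages"][name] = {
            **split.manifest(),
            "n_features": len(feature_names),
        }

        name = stage("generate")
        variants, state = build_variants(train, feature_names, config.gan,
                                         config.oversample, config.seed)
        state.save(out / "gan_state.npz")
        pd.DataFrame(state.loss_history,
                     columns=["step", "kind", "loss"]).to_csv(
            out / "gan_loss_history.csv", index=False)
        sizes = _variant_size_table(variants)
        sizes.to_csv(out / "dataset_sizes.csv", index=False)
        manifest["stages"][name] = {
            "variant_sizes": sizes.to_dict(orient="records")}

        name = stage("fidelity")
        minority = 1 if (train[OUTCOME_COLUMN] == 1).sum() * 2 < len(train) \
            else 0
        real_min = train.loc[train[OUTCOME_COLUMN] == minority, feature_names]
        profiles = []
        for vname, vtab in variants.items():
            if "synthetic" not in vtab.columns or not vtab["synthetic"].any():
                continue
            synth_min = vtab.loc[vtab["synthetic"]
                                 & (vtab[OUTCOME_COLUMN] == minority),
                                 feature_names]
            if synth_min.empty:
                continue
            profiles.append(per_feature_distances(real_min, synth_min,
                                                  method=vname))
        fid_report = compare_methods(profiles)
        pd.concat([p.to_frame() for p in profiles]).to_csv(
            out / "fidelity_distances.csv", index=False)
        (out / "fidelity_tests.json").write_text(
            json.dumps(fid_report, indent=2))
        manifest["stages"][name] = {
            "methods": [p.method for p in profiles]}

        name = stage("predict")
        grid = GridSpec(n_estimators=tuple(config.grid.n_estimators),
                        max_depth=tuple(config.grid.max_depth))
        results = run_experiment_grid(variants, test, grid,
                                      feature_names=feature_names)
        results.to_csv(out / "grid_results.csv", index=False)
        manifest["stages"][name] = {"rows": len(results)}

        name = stage("evaluate")
        report = compare_variants(results)
        report.to_json(out / "comparison_report.json")
        export_boxplots(results, ("accuracy", "f1", "roc_auc", "pr_auc"),
                        out / "figures", report=report)
        manifest["stages"][name] = {
            "corrected_alpha": report.corrected_alpha}

        name = stage("interpret")
        means = results.groupby("dataset")["pr_auc"].mean()
        best_variant = means.idxmax()
        best_row = (results[results["dataset"] == best_variant]
                    .sort_values("pr_auc", ascending=False).iloc[0])
        model = train_classifier(
            variants[best_variant][feature_names].to_numpy(),
            variants[best_variant][OUTCOME_COLUMN].to_numpy(dtype=int),
            int(best_row["n_estimators"]), int(best_row["max_depth"]))
        matrix = compute_shap_matrix(model, test, feature_names)
        ranking = rank_features_by_mean_abs_shap(matrix)
        ranking.to_csv(out / "shap_ranking.csv", index=False)
        export_beeswarm(matrix, out / "figures" / "shap_beeswarm.png")
        manifest["stages"][name] = {
            "explained_variant": best_variant,
            "top_feature": ranking.iloc[0]["feature"],
        }
    except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
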