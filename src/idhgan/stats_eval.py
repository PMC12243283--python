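"""Multi-level statistical comparison of dataset variants.

For each performance metric the layer runs a one-way ANOVA across the
dataset variants with the omega-squared effect size (the proportion of
metric variance attributable to the variant), followed by pairwise
Mann-Whitney U tests under a Bonferroni-corrected significance level
(alpha / C(k,2)) with Cohen's d standardized mean differences, and box
plots of the per-variant metric distributions.

Negative omega-squared values (possible when F < 1) are reported as-is
and should be read as a negligible effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .fidelity import bonferroni_threshold, mann_whitney_u_test

__all__ = ["ComparisonReport", "one_way_anova_omega", "cohens_d",
           "pairwise_comparison_table", "compare_variants",
           "export_boxplots"]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    omega_squared: float


@dataclass
class ComparisonReport:
    anova: dict = field(default_factory=dict)      # metric -> AnovaResult
    pairwise: dict = field(default_factory=dict)   # metric -> DataFrame
    corrected_alpha: float = 0.05

    def to_json(self, path) -> None:
        from pathlib import Path

        payload = {
            "corrected_alpha": self.corrected_alpha,
            "anova": {m: vars(a) for m, a in self.anova.items()},
            "pairwise": {m: df.to_dict(orient="records")
                         for m, df in self.pairwise.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def one_way_anova_omega(groups) -> AnovaResult:
    """Textbook one-way F with omega^2 = (SS_B - df_B*MS_W)/(SS_T + MS_W)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ((all_vals - grand) ** 2).sum()
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    ms_w = ss_within / df_w
    if ms_w == 0:
        raise ZeroDivisionError("zero within-group variance everywhere; "
                                "F undefined")
    F = (ss_between / df_b) / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    omega = (ss_between - df_b * ms_w) / (ss_total + ms_w)
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p,
                       omega_squared=float(omega))


def cohens_d(a, b) -> float:
    """Standardized mean difference (first minus second) with the pooled
    standard deviation on n_a + n_b - 2 degrees of freedom."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    na, nb = len(a), len(b)
    pooled_var = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                  / (na + nb - 2))
    if pooled_var == 0:
        raise ZeroDivisionError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def pairwise_comparison_table(results: pd.DataFrame, metric: str,
                              alpha: float = 0.05,
                              dataset_column: str = "dataset") -> tuple[pd.DataFrame, float]:
    """Every variant pair: mean difference, Cohen's d, Mann-Whitney p,
    significance at alpha / C(k,2)."""
    variants = list(dict.fromkeys(results[dataset_column]))
    if len(variants) < 2:
        raise ValueError("need >= 2 dataset variants")
    groups = {v: results.loc[results[dataset_column] == v, metric].to_numpy()
              for v in variants}
    for v, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"variant {v!r} has < 2 observations")
    n_pairs = len(list(combinations(variants, 2)))
    corrected = bonferroni_threshold(alpha, n_pairs)
    rows = []
    for va, vb in combinations(variants, 2):
        a, b = groups[va], groups[vb]
        try:
            d = cohens_d(a, b)
        except ZeroDivisionError:
            d = 0.0
        _, p = mann_whitney_u_test(a, b)
        rows.append({
            "comparison": f"{va} - {vb}",
            "mean_difference": float(a.mean() - b.mean()),
            "cohens_d": d,
            "p": p,
            "significant": bool(p < corrected),
        })
    return pd.DataFrame(rows), corrected


def compare_variants(results: pd.DataFrame,
                     metrics=("accuracy", "f1", "roc_auc", "pr_auc"),
                     alpha: float = 0.05,
                     dataset_column: str = "dataset") -> ComparisonReport:
    """Full report: per-metric ANOVA + omega^2 and the pairwise table."""
    report = ComparisonReport()
    variants = list(dict.fromkeys(results[dataset_column]))
    for metric in metrics:
        groups = [results.loc[results[dataset_column] == v, metric].to_numpy()
                  for v in variants]
        report.anova[metric] = one_way_anova_omega(groups)
        table, corrected = pairwise_comparison_table(
            results, metric, alpha=alpha, dataset_column=dataset_column)
        report.pairwise[metric] = table
        report.corrected_alpha = corrected
    return report


def export_boxplots(results: pd.DataFrame, metrics, out_dir,
                    dataset_column: str = "dataset",
                    report: ComparisonReport | None = None) -> list:
    """One box-plot panel (file) per metric, one box per variant, with
    significance annotations from the pairwise table when available."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if results.empty:
        raise ValueError("empty results table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    variants = list(dict.fromkeys(results[dataset_column]))
    paths = []
    for metric in metrics:
        fig, ax = plt.subplots(figsize=(1.6 * max(4, len(variants)), 4.5))
        data = [results.loc[results[dataset_column] == v, metric].to_numpy()
                for v in variants]
        ax.boxplot(data, tick_labels=variants)
        ax.set_ylabel(metric)
        ax.set_title(f"{metric} by dataset variant")
        plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
        if report is not None and metric in report.pairwise \
                and len(variants) > 1:
            sig = report.pairwise[metric]
            stars = [r["comparison"] for _, r in sig.iterrows()
                     if r["significant"]]
            if stars:
                ax.annotate(
                    "significant (corrected): " + "; ".join(stars),
                    xy=(0.01, 1.02), xycoords="axes fraction", fontsize=7)
        fig.tight_layout()
        path = out_dir / f"boxplot_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
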