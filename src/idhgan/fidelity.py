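"""Distribution-fidelity metrics and the nonparametric test battery.

Per-feature similarity between real and synthetic minority samples is
quantified by three complementary measures: the 1-D Wasserstein distance
(earth mover's distance, informative even for non-overlapping supports),
the Kullback-Leibler divergence KL(real || synthetic) on a shared-bin
histogram estimate (asymmetric; penalizes synthetic data that fails to
cover real mass), and the bounded, symmetric Jensen-Shannon divergence.
The per-feature distance vectors are the observations fed to the
cross-method Kruskal-Wallis test, with post-hoc pairwise Mann-Whitney U
tests under a Bonferroni-corrected significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import rel_entr

__all__ = [
    "DistanceProfile",
    "wasserstein_1d",
    "kl_divergence_hist",
    "js_divergence_hist",
    "per_feature_distances",
    "kruskal_wallis_test",
    "mann_whitney_u_test",
    "bonferroni_threshold",
]

DEFAULT_BINS = 50
DEFAULT_EPS = 1e-10


@dataclass
class DistanceProfile:
    """Per-feature distance vectors for one generation method."""

    method: str
    feature_names: list[str]
    wd: np.ndarray
    kld: np.ndarray
    jsd: np.ndarray
    bins: int = DEFAULT_BINS
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        lens = {len(self.feature_names), len(self.wd), len(self.kld),
                len(self.jsd)}
        if len(lens) != 1:
            raise ValueError("distance vectors must share a length")

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (feature, metric)."""
        rows = []
        for metric, vec in (("wasserstein", self.wd), ("kl", self.kld),
                            ("js", self.jsd)):
            for name, v in zip(self.feature_names, vec):
                rows.append({"method": self.method, "feature": name,
                             "metric": metric, "value": float(v)})
        return pd.DataFrame(rows)


def wasserstein_1d(a, b) -> float:
    """Empirical 1-D W1 distance (sorted-quantile integral)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return float(stats.wasserstein_distance(a, b))


def _hist_masses(real, synth, bins, eps):
    pooled = np.concatenate([real, synth])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        return None, None
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(real, bins=edges)[0].astype(float)
    q = np.histogram(synth, bins=edges)[0].astype(float)
    p = (p + eps) / (p + eps).sum()
    q = (q + eps) / (q + eps).sum()
    return p, q


def kl_divergence_hist(real, synth, bins: int = DEFAULT_BINS,
                       eps: float = DEFAULT_EPS) -> float:
    """KL(P_real || Q_synth) on eps-smoothed shared-bin histograms
    (natural log).  Degenerate pooled range returns 0 with a warning."""
    real, synth = np.asarray(real, float), np.asarray(synth, float)
    if real.size == 0 or synth.size == 0:
        raise ValueError("empty sample")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    p, q = _hist_masses(real, synth, bins, eps)
    if p is None:
        warnings.warn("degenerate pooled range; KL defined as 0")
        return 0.0
    return float(rel_entr(p, q).sum())


def js_divergence_hist(real, synth, bins: int = DEFAULT_BINS,
                       eps: float = DEFAULT_EPS) -> float:
    """Jensen-Shannon divergence, symmetric and bounded by ln 2."""
    real, synth = np.asarray(real, float), np.asarray(synth, float)
    if real.size == 0 or synth.size == 0:
        raise ValueError("empty sample")
    p, q = _hist_masses(real, synth, bins, eps)
    if p is None:
        warnings.warn("degenerate pooled range; JSD defined as 0")
        return 0.0
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def per_feature_distances(real: pd.DataFrame, synth: pd.DataFrame,
                          method: str = "",
                          bins: int = DEFAULT_BINS,
                          eps: float = DEFAULT_EPS) -> DistanceProfile:
    """All three distances feature-by-feature between matching tables."""
    if list(real.columns) != list(synth.columns):
        raise ValueError("real and synthetic feature sets differ")
    names = list(real.columns)
    wd = np.array([wasserstein_1d(real[c], synth[c]) for c in names])
    kld = np.array([kl_divergence_hist(real[c], synth[c], bins, eps)
                    for c in names])
    jsd = np.array([js_divergence_hist(real[c], synth[c], bins, eps)
                    for c in names])
    return DistanceProfile(method=method, feature_names=names,
                           wd=wd, kld=kld, jsd=jsd, bins=bins, eps=eps)


def kruskal_wallis_test(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; H undefined, returning 0")
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney_u_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; U = min(U_a, U_b).

    Exact enumeration when n_a * n_b <= 400 and there are no ties,
    otherwise the normal approximation with tie and continuity
    correction.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    u = min(float(res.statistic), a.size * b.size - float(res.statistic))
    return u, float(res.pvalue)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-comparison significance level alpha / m."""
    if m <= 0:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def compare_methods(profiles: list[DistanceProfile],
                    alpha: float = 0.05) -> dict:
    """Cross-method battery: per metric, Kruskal-Wallis across methods
    and Bonferroni-corrected pairwise Mann-Whitney U tests on the
    per-feature distance vectors."""
    from itertools import combinations

    metrics = {"wasserstein": "wd", "kl": "kld", "js": "jsd"}
    n_pairs = len(list(combinations(range(len(profiles)), 2)))
    corrected = bonferroni_threshold(alpha, n_pairs) if n_pairs else alpha
    report: dict = {"alpha": alpha, "corrected_alpha": corrected,
                    "kruskal_wallis": {}, "pairwise": {}}
    for metric, attr in metrics.items():
        groups = [getattr(p, attr) for p in profiles]
        if len(groups) >= 2:
            h, p = kruskal_wallis_test(groups)
            report["kruskal_wallis"][metric] = {"H": h, "p": p}
        rows = []
        for i, j in combinations(range(len(profiles)), 2):
            u, p = mann_whitney_u_test(groups[i], groups[j])
            rows.append({
                "pair": f"{profiles[i].method} vs {profiles[j].method}",
                "U": u, "p": p, "significant": bool(p < corrected),
            })
        report["pairwise"][metric] = rows
    return report
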