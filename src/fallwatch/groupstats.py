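"""Two-group comparison of the behavioral parameters.

Per parameter: a Student t-test when both groups pass a Shapiro-Wilk
normality check and a variance-ratio homogeneity check, otherwise a
Wilcoxon rank-sum test; p-values Holm-adjusted over the tested family;
relative difference between group means with a percentile-bootstrap CI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

STUDENT_T = "student_t"
WILCOXON = "wilcoxon_rank_sum"


@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    normality_alpha: float = 0.05
    variance_alpha: float = 0.05
    n_boot: int = 10000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 1000:
            raise ValueError("n_boot must be >= 1000")


@dataclass
class StatResult:
    parameter: str
    test_used: str
    p_raw: float
    p_adjusted: float
    significant: bool
    relative_difference_pct: float
    ci_low_pct: float
    ci_high_pct: float


def _variance_ratio_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test for equality of variances."""
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        return 0.0
    F = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    p = stats.f.sf(F, dfx, dfy)
    return float(2 * min(p, 1 - p))


def select_test(x, y, config: StatConfig = StatConfig()) -> str:
    """Student t iff Shapiro-Wilk passes in both groups AND the variance
    ratio test passes; otherwise Wilcoxon rank-sum."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if min(len(x), len(y)) < 3:
        warnings.warn("group too small for normality gating; using Wilcoxon",
                      stacklevel=2)
        return WILCOXON
    for g in (x, y):
        if np.ptp(g) == 0:  # shapiro undefined for constant data
            return WILCOXON
        if stats.shapiro(g).pvalue < config.normality_alpha:
            return WILCOXON
    if _variance_ratio_p(x, y) < config.variance_alpha:
        return WILCOXON
    return STUDENT_T


def run_test(x, y, test: str) -> float:
    """Two-sided p-value of the chosen two-group test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if test == STUDENT_T:
        return float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    if test == WILCOXON:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test {test!r}")


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order.

    adjusted_(i) = min(1, max_{j<=i} (m - j + 1) * p_(j)) over the ascending
    order statistics.
    """
    p = np.asarray(list(p_values), float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def relative_difference_ci(x, y, config: StatConfig = StatConfig()):
    """Relative difference of group means, (mean(y) - mean(x)) / mean(x) * 100,
    with a seeded percentile bootstrap CI over subjects."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx = x.mean()
    if mx == 0:
        raise ValueError("mean of the reference group is zero; relative "
                         "difference undefined")
    point = float((y.mean() - mx) / mx * 100.0)
    rng = np.random.default_rng(config.seed)
    bx = rng.choice(x, size=(config.n_boot, len(x)), replace=True).mean(axis=1)
    by = rng.choice(y, size=(config.n_boot, len(y)), replace=True).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = (by - bx) / bx * 100.0
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return point, float(lo), float(hi)


def compare_all(features: pd.DataFrame, labels: pd.Series,
                config: StatConfig = StatConfig()) -> pd.DataFrame:
    """Per-parameter two-group comparison with Holm adjustment.

    ``labels`` maps subject id to "low"/"high". Parameters missing for more
    than half of either group are excluded (logged). Returns one row per
    tested parameter.
    """
    labels = labels.loc[features.index]
    low_rows = features[labels == "low"]
    high_rows = features[labels == "high"]
    if low_rows.empty or high_rows.empty:
        raise ValueError("both groups must be non-empty")

    tested, pvals = [], []
    for name in features.columns:
        x = low_rows[name].dropna().to_numpy(float)
        y = high_rows[name].dropna().to_numpy(float)
        if (len(x) < 0.5 * len(low_rows)) or (len(y) < 0.5 * len(high_rows)):
            log.info("excluding %s: missing for >50%% of a group", name)
            continue
        test = select_test(x, y, config)
        p = run_test(x, y, test)
        point, lo, hi = relative_difference_ci(x, y, config)
        tested.append({"parameter": name, "test_used": test, "p_raw": p,
                       "relative_difference_pct": point, "ci_low_pct": lo,
                       "ci_high_pct": hi})
        pvals.append(p)
    adj = holm_adjust(pvals)
    for row, pa in zip(tested, adj):
        row["p_adjusted"] = float(pa)
        row["significant"] = bool(pa < config.alpha)
    cols = ["parameter", "test_used", "p_raw", "p_adjusted", "significant",
            "relative_difference_pct", "ci_low_pct", "ci_high_pct"]
    return pd.DataFrame(tested)[cols]
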