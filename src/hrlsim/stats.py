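"""Between-group comparison protocol.

The protocol is the standard one for simulation-replicate comparisons in
this model family:
Levene's test (classical, centred on the group means) decides between
Student's pooled-variance t-test and Welch's unequal-variance t-test; the
Wilcoxon rank-sum (Mann-Whitney) test is available for count-like metrics.
Implementations delegate to scipy.stats; this module fixes the protocol
choices (Levene centre, the variance-gate level, exact vs asymptotic
rank-sum p-values) and returns a uniform result record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "levene_test",
    "two_sample_t",
    "auto_t",
    "wilcoxon_rank_sum",
    "compare",
    "comparison_report",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one two-sample test."""

    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    direction: int   # sign of mean(x) - mean(y) (median difference for rank tests)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _clean(x, y, min_n: int = 2):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < min_n or len(y) < min_n:
        raise ValueError(f"need at least {min_n} observations per group")
    return x, y


def levene_test(x, y) -> StatResult:
    """Levene's test of equal variances, centred on the group means.

    Identical (including identical non-constant) samples give W = 0, p = 1.
    """
    x, y = _clean(x, y)
    if np.var(x) == 0 and np.var(y) == 0:
        w, p = 0.0, 1.0
    else:
        w, p = sps.levene(x, y, center="mean")
    return StatResult("levene", float(w), float(p), len(x), len(y),
                      int(np.sign(np.var(x, ddof=1) - np.var(y, ddof=1))))


def two_sample_t(x, y, equal_variance: bool = True) -> StatResult:
    """Student's (pooled) or Welch's two-sample t-test, two-sided."""
    x, y = _clean(x, y)
    t, p = sps.ttest_ind(x, y, equal_var=equal_variance)
    name = "student" if equal_variance else "welch"
    return StatResult(name, float(t), float(p), len(x), len(y),
                      int(np.sign(np.mean(x) - np.mean(y))))


def auto_t(x, y, variance_alpha: float = 0.05) -> StatResult:
    """Levene-gated t-test: Welch when Levene rejects equal variances,
    Student otherwise.  The chosen branch is recorded in ``test_name``."""
    gate = levene_test(x, y)
    return two_sample_t(x, y, equal_variance=gate.p_value >= variance_alpha)


def wilcoxon_rank_sum(x, y) -> StatResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test, two-sided.

    Exact enumeration for small tie-free samples (both n <= 20), otherwise
    the normal approximation with midranks and continuity correction.
    """
    x, y = _clean(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) <= 20 and len(y) <= 20) and not has_ties
    if np.array_equal(np.sort(x), np.sort(y)):
        # degenerate identical samples: no evidence of a shift
        u = len(x) * len(y) / 2.0
        return StatResult("wilcoxon_exact" if exact else "wilcoxon_normal",
                          u, 1.0, len(x), len(y), 0)
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided",
                            method="exact" if exact else "asymptotic",
                            use_continuity=True)
    name = "wilcoxon_exact" if exact else "wilcoxon_normal"
    return StatResult(name, float(u), float(min(p, 1.0)), len(x), len(y),
                      int(np.sign(np.median(x) - np.median(y))))


_TESTS = {
    "auto_t": auto_t,
    "student": lambda x, y: two_sample_t(x, y, equal_variance=True),
    "welch": lambda x, y: two_sample_t(x, y, equal_variance=False),
    "wilcoxon": wilcoxon_rank_sum,
}

# per-metric test assignments: trial-duration distributions are heavy
# tailed (occasional slow-learning trials), hence the rank test there
DEFAULT_METRIC_TESTS = {"total_timesteps": "wilcoxon"}


def compare(x, y, test: str = "auto_t") -> StatResult:
    """Run a named test from the protocol on two metric vectors."""
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {sorted(_TESTS)}")
    return _TESTS[test](x, y)


def comparison_report(result_a, result_b, metrics=None,
                      tests: dict | None = None,
                      alpha: float = 0.001) -> pd.DataFrame:
    """Compare two ConditionResults metric-by-metric.

    Missing values (e.g. zero-intake replicates for the reward-per-intake
    metric) are dropped per group before testing; the drop counts are
    reported.  Default test is the Levene-gated t; ``tests`` maps a metric
    name to one of 'auto_t', 'student', 'welch', 'wilcoxon'.
    """
    tests = {**DEFAULT_METRIC_TESTS, **(tests or {})}
    if metrics is None:
        metrics = [c for c in result_a.metrics.columns
                   if c not in ("replicate", "seed", "n_censored_episodes")]
    rows = []
    for metric in metrics:
        x = result_a.vector(metric)
        y = result_b.vector(metric)
        n_dropped = int(np.isnan(x).sum() + np.isnan(y).sum())
        res = compare(x[~np.isnan(x)], y[~np.isnan(y)], tests.get(metric, "auto_t"))
        rows.append({
            "metric": metric,
            "condition_A": result_a.condition.name,
            "condition_B": result_b.condition.name,
            "test_name": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "direction": res.direction,
            "n_dropped": n_dropped,
            f"significant_at_{alpha}": res.p_value < alpha,
        })
    return pd.DataFrame(rows)
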