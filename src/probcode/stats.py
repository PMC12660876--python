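"""Shared statistics: t-tests with effect sizes, and BH-FDR correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DomainError

__all__ = ["TestResult", "ttest", "fdr_bh"]


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    ci95: tuple[float, float]
    cohens_d: float
    kind: str


def _ci_from_t(effect: float, se: float, df: float) -> tuple[float, float]:
    crit = sps.t.ppf(0.975, df)
    return (effect - crit * se, effect + crit * se)


def ttest(data, kind: str = "one_sample", popmean: float = 0.0,
          other=None) -> TestResult:
    """Two-tailed t-test with 95% CI and Cohen's d.

    ``kind``: "one_sample" (against ``popmean``), "two_sample" (independent,
    pooled variance, against ``other``), or "paired" (against ``other``).
    """
    x = np.asarray(data, dtype=float)
    if kind == "one_sample":
        if x.size < 2:
            raise ConfigurationError("need n >= 2 observations")
        if x.std(ddof=1) == 0.0:
            # degenerate sample: t is defined (0) only when the mean sits
            # exactly at the reference
            if x.mean() != popmean:
                raise ConfigurationError("zero variance in sample")
            return TestResult(0.0, x.size - 1, 1.0, (0.0, 0.0), 0.0, kind)
        res = sps.ttest_1samp(x, popmean)
        df = x.size - 1
        se = x.std(ddof=1) / np.sqrt(x.size)
        effect = x.mean() - popmean
        d = effect / x.std(ddof=1)
        return TestResult(float(res.statistic), df, float(res.pvalue),
                          _ci_from_t(effect, se, df), float(d), kind)
    if other is None:
        raise ConfigurationError(f"{kind} test needs a second sample")
    y = np.asarray(other, dtype=float)
    if kind == "two_sample":
        if x.size < 2 or y.size < 2:
            raise ConfigurationError("need n >= 2 per group")
        s2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
            x.size + y.size - 2)
        if s2 == 0.0:
            if x.mean() != y.mean():
                raise ConfigurationError("zero pooled variance")
            return TestResult(0.0, x.size + y.size - 2, 1.0, (0.0, 0.0), 0.0, kind)
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
        se = np.sqrt(s2 * (1.0 / x.size + 1.0 / y.size))
        effect = x.mean() - y.mean()
        d = effect / np.sqrt(s2)
        return TestResult(float(res.statistic), df, float(res.pvalue),
                          _ci_from_t(effect, se, df), float(d), kind)
    if kind == "paired":
        if x.size != y.size or x.size < 2:
            raise ConfigurationError("paired test needs equal-length samples, n >= 2")
        diff = x - y
        if diff.std(ddof=1) == 0.0:
            # all differences identical; t undefined unless the mean is 0 too
            if diff.mean() != 0.0:
                raise ConfigurationError("zero variance in paired differences")
            return TestResult(0.0, x.size - 1, 1.0, (0.0, 0.0), 0.0, kind)
        res = sps.ttest_rel(x, y)
        df = x.size - 1
        se = diff.std(ddof=1) / np.sqrt(x.size)
        return TestResult(float(res.statistic), df, float(res.pvalue),
                          _ci_from_t(diff.mean(), se, df),
                          float(diff.mean() / diff.std(ddof=1)), kind)
    raise ConfigurationError(f"unknown test kind {kind!r}")


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up. Returns (rejection mask, adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise DomainError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
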