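"""Descriptive and nonparametric statistics used across the analyses.

Thin, validated wrappers over scipy/statsmodels with the conventions fixed:
Cohen's d uses the pooled SD with sign high-minus-low; the rank-sum test is
the two-sided Mann-Whitney (exact enumeration for tiny untied samples);
the signed-rank test drops zeros and uses the normal approximation with
continuity correction; the chi-square test is Pearson's without continuity
correction; FDR is Benjamini-Hochberg step-up at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class DStat:
    """Pooled-SD Cohen's d between two groups (group 2 = high)."""

    d: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int


def cohens_d_pooled(m1, s1, n1, m2, s2, n2) -> DStat:
    """Cohen's d = (m2 - m1) / pooled SD; by convention group 2 is 'high'."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ZeroDivisionError("pooled SD is zero; effect size undefined")
    return DStat(float((m2 - m1) / pooled), m1, s1, n1, m2, s2, n2)


def cohens_d_from_samples(low, high) -> DStat:
    low = np.asarray(low, float)
    high = np.asarray(high, float)
    return cohens_d_pooled(
        low.mean(), low.std(ddof=1), len(low), high.mean(), high.std(ddof=1), len(high)
    )


def ranksum_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Exact enumeration when the pooled sample is small (n_a + n_b <= 12)
    and untied, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    small = a.size + b.size <= 12 and np.unique(pooled).size == pooled.size
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def signedrank_test(paired_diffs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; the normal approximation with continuity
    correction is used throughout.
    """
    d = np.asarray(paired_diffs, float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise ValueError("all paired differences are zero")
    if nonzero.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=True, method="approx"
    )
    return float(res.statistic), float(res.pvalue)


def ks_2samp(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 8 or b.size < 8:
        raise ValueError("each sample needs at least 8 values")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    counts = np.asarray(counts, float)
    if counts.shape != (2, 2) or (counts < 0).any() or not np.allclose(
        counts, np.round(counts)
    ):
        raise ValueError("counts must be a 2x2 table of non-negative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), float(p)


def fdr_bh(p_values, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR.

    Returns the adjusted q-values (cumulative minimum of m * p_(i) / i on
    the sorted p-values) and the rejection flags at ``q_level``.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject
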