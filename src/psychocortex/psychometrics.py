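"""Scoring of the IRI and PCL-R, psychopathy grouping, and rank correlations.

The Interpersonal Reactivity Index (IRI) Perspective Taking and Empathic
Concern subscales are plain sums of 7 items scored 0-4 (subscale range
0-28; no prorating is defined for the IRI). The Psychopathy
Checklist-Revised (PCL-R) has 20 items scored 0-2; the total (0-40),
interpersonal/affective factor F1 (8 items, 0-16) and lifestyle/antisocial
factor F2 (10 items, 0-20) are prorated to the full item count when a
tolerable number of items was omitted, yielding possible decimals.
Psychopathy groups follow the conventional cutoffs: high >= 30, low <= 20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: 0-based PCL-R item indices per factor (two items load on neither factor)
DEFAULT_FACTOR_MAP = {"f1": tuple(range(0, 8)), "f2": tuple(range(8, 18))}

#: maximum omitted items tolerated before prorating is refused
DEFAULT_MAX_OMITTED = {"total": 5, "f1": 2, "f2": 2}

HIGH_CUTOFF = 30.0
LOW_CUTOFF = 20.0


class ProratingRefusedError(ValueError):
    """Raised when too many items were omitted on a PCL-R scale."""


class MissingItemError(ValueError):
    """Raised when an IRI item is missing (the IRI is never prorated)."""


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return True


def score_iri(items_pt, items_ec) -> tuple[int, int]:
    """Sum the 7 Perspective Taking and 7 Empathic Concern items.

    Each item must be an integer in 0..4; any missing item raises
    :class:`MissingItemError` because the IRI subscales are defined only as
    complete sums.
    """
    out = []
    for label, items in (("PT", items_pt), ("EC", items_ec)):
        if len(items) != 7:
            raise ValueError(f"IRI-{label} requires exactly 7 items")
        total = 0
        for v in items:
            if _is_missing(v):
                raise MissingItemError(f"IRI-{label} item missing; no prorating")
            v = int(v)
            if not 0 <= v <= 4:
                raise ValueError(f"IRI-{label} item {v} outside 0..4")
            total += v
        out.append(total)
    return tuple(out)


def _prorate_scale(items, idx, n_scale, max_omitted, label):
    vals = [items[i] for i in idx]
    scored = [float(v) for v in vals if not _is_missing(v)]
    n_omitted = len(vals) - len(scored)
    if n_omitted > max_omitted:
        raise ProratingRefusedError(
            f"{label}: {n_omitted} items omitted exceeds cap {max_omitted}"
        )
    if not scored:
        return float("nan")
    for v in scored:
        if v not in (0.0, 1.0, 2.0):
            raise ValueError(f"{label}: item score {v} outside {{0, 1, 2}}")
    return sum(scored) * n_scale / len(scored)


def prorate_pclr(
    items,
    factor_map: dict | None = None,
    max_omitted: dict | None = None,
) -> tuple[float, float, float]:
    """Prorate PCL-R total and factor scores under item omission.

    Each scale score is (sum of scored items) x (scale item count / scored
    item count), retaining decimals — equivalent to imputing each omitted
    item at the scale's observed mean. Scales whose omission count exceeds
    the cap raise :class:`ProratingRefusedError` naming the scale; a scale
    with zero scored items returns NaN.
    """
    if len(items) != 20:
        raise ValueError("PCL-R requires exactly 20 items")
    factor_map = factor_map or DEFAULT_FACTOR_MAP
    max_omitted = max_omitted or DEFAULT_MAX_OMITTED
    total = _prorate_scale(
        items, range(20), 20, max_omitted["total"], "PCL-R total"
    )
    f1 = _prorate_scale(
        items, factor_map["f1"], len(factor_map["f1"]), max_omitted["f1"], "PCL-R F1"
    )
    f2 = _prorate_scale(
        items, factor_map["f2"], len(factor_map["f2"]), max_omitted["f2"], "PCL-R F2"
    )
    return total, f1, f2


def assign_group(total: float) -> str:
    """Classify a PCL-R total into low (<=20), moderate, or high (>=30)."""
    if not 0.0 <= total <= 40.0:
        raise ValueError(f"PCL-R total {total} outside [0, 40]")
    if total >= HIGH_CUTOFF:
        return "high"
    if total <= LOW_CUTOFF:
        return "low"
    return "moderate"


@dataclass
class CorrelationMatrix:
    """Spearman rank-correlation matrix with Bonferroni significance flags."""

    variables: list
    rho: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    m_tests: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.variables, columns=self.variables)


def spearman_matrix(table: pd.DataFrame, m_tests: int | None = None) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations with Bonferroni flags.

    Ties receive average ranks; two-sided p-values use the t approximation.
    ``m_tests`` defaults to the number of off-diagonal pairs (28 for eight
    variables). A pair with fewer than 8 complete rows or a constant column
    yields NaN and is never flagged significant.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two variables")
    if len(table.dropna()) < 8:
        raise ValueError("need at least 8 complete rows")
    cols = list(table.columns)
    k = len(cols)
    if m_tests is None:
        m_tests = k * (k - 1) // 2
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if len(pair) < 8 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r_ij, p_ij = np.nan, np.nan
            else:
                r_ij, p_ij = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r_ij
            p[i, j] = p[j, i] = p_ij
    with np.errstate(invalid="ignore"):
        significant = (p * m_tests < 0.05) & ~np.isnan(p)
    np.fill_diagonal(significant, False)
    return CorrelationMatrix(cols, rho, p, significant, m_tests)
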