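"""Radiocarbon unit conversion and age-trend / distribution statistics.

Radiocarbon content of DOC is reported either as percent modern carbon
(pMC) or as Δ14C in per mille, the per-mille deviation from the 1950
oxalic-acid standard after correcting the measured activity for decay
between sample collection and 1950:

    Δ14C = (pMC/100 · exp(λ (1950 − collection_year)) − 1) × 1000,

with λ = 1/8267 yr⁻¹, the decay constant of the 5730-year *true* half-life.
δ13C fractionation normalisation is assumed already applied by the
reporting laboratory.

Trend statistics mirror common practice for small hydrochemical data sets:
Spearman rank correlations of sample metrics against Δ14C (exact
permutation p-values for n ≤ 9), two-sided Wilcoxon rank-sum tests for
median shifts between environments (exact for combined n ≤ 12 without
ties), and a two-sided variance-ratio F test.  No multiple-testing
correction is applied by default; a Benjamini–Hochberg helper is provided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LAMBDA_14C",
    "pmc_to_delta14c",
    "delta14c_to_pmc",
    "conventional_age_bp",
    "rank_correlation",
    "median_shift_test",
    "variance_ratio_test",
    "correlation_report",
    "benjamini_hochberg",
]

#: Radiocarbon decay constant, 1/8267 yr⁻¹ (5730-year true half-life).
LAMBDA_14C = 1.0 / 8267.0

#: Libby decay constant used for conventional radiocarbon ages, 1/8033 yr⁻¹.
_LAMBDA_LIBBY = 1.0 / 8033.0


def pmc_to_delta14c(pmc: float, collection_year: float) -> float:
    """Convert percent modern carbon to Δ14C (‰) at a collection year.

    Strictly increasing in pMC; Δ14C(100 pMC, 1950) = 0 exactly.

    Raises
    ------
    ValueError
        For negative pMC.
    """
    if pmc < 0:
        raise ValueError(f"pmc must be >= 0, got {pmc}")
    return (pmc / 100.0 * math.exp(LAMBDA_14C * (1950.0 - collection_year)) - 1.0) * 1000.0


def delta14c_to_pmc(delta14c: float, collection_year: float) -> float:
    """Inverse of :func:`pmc_to_delta14c`."""
    pmc = (delta14c / 1000.0 + 1.0) * 100.0 / math.exp(LAMBDA_14C * (1950.0 - collection_year))
    if pmc < 0:
        raise ValueError(f"delta14c {delta14c} implies negative pmc")
    return pmc


def conventional_age_bp(pmc: float) -> float:
    """Conventional radiocarbon age (years before 1950), Libby convention.

    ``age = −8033 · ln(pMC/100)``.  Reported alongside Δ14C only as a
    convenience; no calendar calibration or reservoir correction is applied.
    """
    if pmc <= 0:
        raise ValueError(f"pmc must be > 0 for an age, got {pmc}")
    return -math.log(pmc / 100.0) / _LAMBDA_LIBBY


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact" or "asymptotic"


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return math.nan
    return float((rx * ry).sum() / denom)


def rank_correlation(x, y, exact_threshold: int = 9) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    For n ≤ ``exact_threshold`` the p-value is computed by full permutation
    enumeration of one margin (exact even under ties); larger n uses the
    t-approximation.  Constant input yields an undefined correlation
    (NaN rho and p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 paired observations, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, n, "undefined")
    rho = _spearman_rho(x, y)
    if n <= exact_threshold:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        rxc = rx - rx.mean()
        sx = math.sqrt(float((rxc**2).sum()))
        perms = np.array(list(itertools.permutations(ry)))
        pc = perms - perms.mean(axis=1, keepdims=True)
        sy = np.sqrt((pc**2).sum(axis=1))
        rhos = pc @ rxc / (sx * sy)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, p, n, "exact")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho, float(res.pvalue), n, "asymptotic")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


def median_shift_test(a, b, exact_threshold: int = 12) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test for a median shift.

    Exact null distribution when the combined sample size is at most
    ``exact_threshold`` and there are no ties; otherwise the normal
    approximation with tie correction (no continuity correction, so
    identical samples give p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if a.size + b.size <= exact_threshold and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue), "exact")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return TestResult(float(res.statistic), float(res.pvalue), "asymptotic")


def variance_ratio_test(a, b) -> TestResult:
    """Two-sided variance-ratio F test, ``F = var(a)/var(b)`` (ddof 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if vb == 0:
        raise ValueError("zero variance in second group")
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    p = float(2.0 * min(cdf, 1.0 - cdf))
    return TestResult(f, min(p, 1.0), "f")


def correlation_report(metrics: pd.DataFrame, delta14c: pd.Series) -> pd.DataFrame:
    """Spearman correlations of each metric column against Δ14C.

    ``metrics`` is a sample × metric DataFrame; samples with missing Δ14C
    are rejected loudly.  Returns a tidy table ``metric, rho, p, n``.
    """
    delta14c = delta14c.reindex(metrics.index)
    if delta14c.isna().any():
        missing = delta14c.index[delta14c.isna()].tolist()
        raise ValueError(f"delta14c missing for samples {missing}")
    rows = []
    for metric in metrics.columns:
        res = rank_correlation(metrics[metric].to_numpy(float), delta14c.to_numpy(float))
        rows.append({"metric": metric, "rho": res.rho, "p": res.p_value, "n": res.n})
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional, off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
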