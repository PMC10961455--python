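"""Statistical primitives shared by every pipeline stage.

Two-sample and paired t-tests, rank tests (Mann-Whitney U, Kruskal-Wallis)
and the Benjamini-Hochberg / Benjamini-Yekutieli false-discovery-rate
step-up procedures.  All tests are two-sided.  Distributional machinery is
delegated to :mod:`scipy.stats`; the FDR step-up is implemented here because
it is applied per seed map over large voxel sets and is the thresholding
primitive of the connectivity pipeline.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "TestResult",
    "p_from_t",
    "two_sample_t",
    "paired_t",
    "mann_whitney_u",
    "kruskal_wallis",
    "fdr_adjust",
    "FdrResult",
]

#: total-sample-size limit below which Mann-Whitney uses exact enumeration
MWU_EXACT_LIMIT = 12


@dataclasses.dataclass(frozen=True)
class TestResult:
    """A scalar test statistic with its two-sided p-value.

    ``df`` is ``None`` for rank statistics whose null is not a t
    distribution (U) or is chi-square (H, where df = groups - 1 is stored).
    """

    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def p_from_t(t_value: float, df: float) -> float:
    """Two-sided p-value for a Student t statistic.

    Uses the survival function of the t distribution (regularised
    incomplete beta under the hood).
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(2.0 * _st.t.sf(abs(t_value), df))


def _check_group(x: np.ndarray, min_n: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise ValueError(f"{name} must be 1-D with at least {min_n} values")
    return x


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> TestResult:
    """Two-sample t-test; homoscedastic (pooled variance) by default.

    The pooled test has df = n_x + n_y - 2.  Raises on zero pooled
    variance (degenerate data).
    """
    x = _check_group(np.asarray(x), 2, "x")
    y = _check_group(np.asarray(y), 2, "y")
    nx, ny = x.size, y.size
    if equal_var:
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        if sp2 <= 0.0:
            raise ValueError("zero pooled variance: t statistic undefined")
        df = float(nx + ny - 2)
    else:
        if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
            raise ValueError("zero variance in both groups")
        df = None
    res = _st.ttest_ind(x, y, equal_var=equal_var)
    if df is None:
        df = float(res.df)
    return TestResult(float(res.statistic), float(res.pvalue), df)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired t-test: one-sample t on the element-wise differences."""
    x = _check_group(np.asarray(x), 2, "x")
    y = _check_group(np.asarray(y), 2, "y")
    if x.size != y.size:
        raise ValueError("paired test needs equal-length samples")
    d = x - y
    if d.var(ddof=1) == 0.0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = _st.ttest_rel(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), float(x.size - 1))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U test, two-sided.

    Exact enumeration of the permutation null when the combined sample
    size is at most :data:`MWU_EXACT_LIMIT` (posthoc group sizes here are
    small, so exact is feasible and removes approximation ambiguity);
    otherwise the tie-corrected normal approximation.
    """
    x = _check_group(np.asarray(x), 1, "x")
    y = _check_group(np.asarray(y), 1, "y")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size + y.size <= MWU_EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = _st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), None)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction; chi-square p, df = g-1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if sum(g.size for g in groups) < 2:
        raise ValueError("need at least two observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical: H undefined")
    h, p = _st.kruskal(*groups)
    return TestResult(float(h), float(p), float(len(groups) - 1))


@dataclasses.dataclass(frozen=True)
class FdrResult:
    rejected: np.ndarray  # boolean mask, same shape as input
    adjusted_p: np.ndarray
    threshold: float  # largest raw p rejected (0.0 if none)


def fdr_adjust(
    p_values: Sequence[float],
    method: Literal["BH", "BY"] = "BH",
    q: float = 0.05,
) -> FdrResult:
    """FDR step-up procedure of Benjamini-Hochberg or Benjamini-Yekutieli.

    Sorted p-values ``p_(i)`` are compared against ``(i/m) * q`` (BH) or
    ``(i/m) * q / c(m)`` with ``c(m) = sum_{j<=m} 1/j`` (BY, valid under
    arbitrary dependence); the largest qualifying rank and every smaller
    rank are rejected.  Adjusted p-values are the usual monotone step-up
    transform, so ``adjusted_p <= q`` reproduces the rejection mask.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    shape = p.shape
    p = p.ravel()
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    cm = float(np.sum(1.0 / np.arange(1, m + 1))) if method == "BY" else 1.0
    if method not in ("BH", "BY"):
        raise ValueError(f"unknown FDR method {method!r}")
    crit = (np.arange(1, m + 1) / m) * (q / cm)
    passing = np.nonzero(ranked <= crit)[0]
    rejected = np.zeros(m, dtype=bool)
    threshold = 0.0
    if passing.size:
        kmax = passing[-1]
        rejected[order[: kmax + 1]] = True
        threshold = float(ranked[kmax])
    adj = ranked * m * cm / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adj, 0.0, 1.0)
    return FdrResult(rejected.reshape(shape), adjusted.reshape(shape), threshold)
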