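"""Agreement and comparison statistics for the convergence analysis.

Three pieces make up the statistical layer:

* **Through-origin regression** of the partial entropy on the full-test
  entropy across participants, ``SampEn10I = k * SampEn50``.  The slope is
  the closed form ``k = sum(x*y) / sum(x^2)``; the coefficient of
  determination uses the uncentered total sum of squares ``sum(y^2)``, the
  standard convention for no-intercept fits (the centered variant can leave
  [0, 1] and is kept behind a flag for sensitivity checks).  Pearson's r and
  its two-sided p accompany each fit.

* **Optimal-duration selection**: the smallest window end I whose regression
  reaches R^2 above 0.99 with slope k above 0.95 — a better-than-95% linkage
  between the short test and the full 50-cycle test.

* **Bland-Altman limits of agreement**: bias = mean of paired differences,
  limits = bias +/- 1.96 * SD(differences) (sample SD, divisor n - 1); 95% of
  differences are expected to fall between the limits.

Condition contrasts (box vs stool) use the two-sided Wilcoxon signed-rank
test (exact null for n <= 25 without ties, normal approximation with tie
correction otherwise) for durations, SDs and entropies, and the paired
t-test for amplitudes, at a 5% significance level with no multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "DurationSelection",
    "regress_through_origin",
    "select_duration",
    "bland_altman",
    "compare_conditions",
    "cross_condition_correlation",
]

LOA_MULTIPLIER = 1.96  # normal 95% limits of agreement


@dataclass(frozen=True)
class RegressionResult:
    """Through-origin fit y = k x with its goodness-of-fit summaries."""

    k: float
    se_k: float
    r_squared: float
    pearson_r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement of paired differences d = a - b."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray  # per-pair (a + b) / 2, for the agreement plot
    diffs: np.ndarray  # per-pair a - b


@dataclass(frozen=True)
class DurationSelection:
    """Smallest window end I meeting both convergence thresholds."""

    optimal_I: int | None  # seconds; None when no window qualifies
    r2_threshold: float
    slope_threshold: float
    table: dict[int, RegressionResult]


def _paired(a, b, min_n: int):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {a.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs contain non-finite values")
    return a, b


def regress_through_origin(y, x, *, r2_convention: str = "uncentered") -> RegressionResult:
    """Fit y = k x with no intercept: k = sum(x y) / sum(x^2)."""
    y, x = _paired(y, x, 3)
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("x is identically zero; slope undefined")
    k = float(np.sum(x * y)) / sxx
    resid = y - k * x
    ss_res = float(np.sum(resid**2))
    if r2_convention == "uncentered":
        ss_tot = float(np.sum(y**2))
    elif r2_convention == "centered":
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        raise ValueError(f"unknown r2_convention {r2_convention!r}")
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    se_k = float(np.sqrt(ss_res / (y.size - 1) / sxx))
    pr = stats.pearsonr(x, y)
    return RegressionResult(
        k=k,
        se_k=se_k,
        r_squared=r_squared,
        pearson_r=float(pr.statistic),
        p_value=float(pr.pvalue),
        n=int(y.size),
    )


def select_duration(
    table: dict[int, RegressionResult],
    *,
    r2_threshold: float = 0.99,
    slope_threshold: float = 0.95,
) -> DurationSelection:
    """Smallest tabulated I with R^2 above ``r2_threshold`` and k above
    ``slope_threshold``; ``optimal_I=None`` when none qualifies."""
    if not table:
        raise ValueError("empty regression table")
    optimal = None
    for i in sorted(table):
        res = table[i]
        if res.r_squared > r2_threshold and res.k > slope_threshold:
            optimal = int(i)
            break
    return DurationSelection(
        optimal_I=optimal,
        r2_threshold=r2_threshold,
        slope_threshold=slope_threshold,
        table=dict(table),
    )


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements: differences a - b."""
    a, b = _paired(a, b, 3)
    diffs = a - b
    bias = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - LOA_MULTIPLIER * sd_diff,
        loa_high=bias + LOA_MULTIPLIER * sd_diff,
        n=int(a.size),
        means=(a + b) / 2.0,
        diffs=diffs,
    )


def compare_conditions(box, stool, test: str = "wilcoxon") -> tuple[float, float]:
    """Paired two-sided comparison of the two test conditions.

    ``test="wilcoxon"`` uses the signed-rank test (exact null for n <= 25
    when no zero differences or tied absolute differences occur, otherwise
    the tie-corrected normal approximation); ``test="paired_t"`` the paired
    t-test.  Returns (statistic, p).
    """
    box, stool = _paired(box, stool, 5)
    d = box - stool
    if test == "paired_t":
        if np.all(d == 0):
            return 0.0, 1.0  # identical samples: no evidence of any difference
        res = stats.ttest_rel(box, stool)
        return float(res.statistic), float(res.pvalue)
    if test != "wilcoxon":
        raise ValueError(f"unknown test {test!r}")
    if np.all(d == 0):
        raise ValueError("degenerate pairs: all differences are zero")
    nonzero = d[d != 0]
    exact_ok = (
        box.size <= 25
        and nonzero.size == d.size
        and np.unique(np.abs(nonzero)).size == nonzero.size
    )
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(box, stool, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cross_condition_correlation(sampen_box, sampen_stool) -> tuple[float, float]:
    """Pearson correlation of per-participant values across the two
    conditions; returns (r, p)."""
    a, b = _paired(sampen_box, sampen_stool, 3)
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
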