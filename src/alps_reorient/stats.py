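"""Reliability and agreement statistics for repeated ALPS measurements.

Implements, from the standard ANOVA / contingency formulas: intraclass
correlation coefficients (one-way random; two-way random absolute agreement,
the default for inter-rater reliability of a measurement; two-way mixed
consistency) with the conventional classification bands; the variance-ratio
F test; the paired t test; Bland-Altman limits of agreement; weighted kappa
for ordinal head-rotation grades; and ordinary-least-squares slope testing
for age associations.  All p-values are two sided, alpha = 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

ALPHA = 0.05

ICC_BANDS = (  # upper edge, label
    (0.5, "poor"),
    (0.75, "moderate"),
    (0.9, "good"),
    (np.inf, "excellent"),
)
KAPPA_BANDS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "good"),
    (np.inf, "very good"),
)


def _classify(value: float, bands) -> str:
    for upper, label in bands:
        if value <= upper:
            return label
    return bands[-1][1]


@dataclass(frozen=True)
class IccResult:
    icc: float
    model: str
    variance_components: dict[str, float]
    classification: str


@dataclass(frozen=True)
class VarianceTestResult:
    f_statistic: float
    df: tuple[int, int]
    p_value: float


@dataclass(frozen=True)
class PairedTResult:
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray = field(repr=False, default=None)
    differences: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weights: str
    classification: str


@dataclass(frozen=True)
class OlsResult:
    slope: float
    intercept: float
    p_value: float  # two-sided, for the slope
    r_squared: float


def _validate_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("rating table must be 2-D with >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(table)):
        raise ValueError("rating table must have no missing cells")
    return table


def icc(table, model: str = "twoway_agreement") -> IccResult:
    """Single-measurement ICC from the two-way ANOVA decomposition.

    Rows are subjects, columns raters/sessions.  Models:

    - ``oneway``: one-way random, ICC(1,1)
    - ``twoway_agreement``: two-way random effects, absolute agreement,
      ICC(2,1) — the default for inter-rater reliability of a measurement
    - ``twoway_consistency``: two-way mixed, consistency, ICC(3,1)
    """
    table = _validate_table(table)
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_total = np.sum((table - grand) ** 2)
    if ss_total == 0:
        raise ValueError("ICC undefined: the table has zero total variance")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # between subjects
    msc = ss_cols / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual
    msw = (ss_cols + ss_err) / (n * (k - 1))  # within subjects (one-way)
    if model == "oneway":
        denom = msr + (k - 1) * msw
        value = (msr - msw) / denom if denom != 0 else np.nan
    elif model == "twoway_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom if denom != 0 else np.nan
    elif model == "twoway_consistency":
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom if denom != 0 else np.nan
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    if not np.isfinite(value):
        raise ValueError("ICC undefined for this table (zero denominator)")
    comps = {"ms_rows": msr, "ms_cols": msc, "ms_error": mse, "ms_within": msw}
    return IccResult(float(value), model, comps, _classify(float(value), ICC_BANDS))


def f_test_equal_variance(sample_a, sample_b) -> VarianceTestResult:
    """Two-sided variance-ratio F test, F = s_a^2 / s_b^2 (ddof 1)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("denominator sample has zero variance")
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return VarianceTestResult(float(f), (dfa, dfb), float(min(p, 1.0)))


def paired_t(pairs_a, pairs_b=None) -> PairedTResult:
    """Paired t test: one-sample t on the differences.

    Accepts either two equal-length samples or a single array of differences.
    """
    if pairs_b is None:
        d = np.asarray(pairs_a, dtype=float)
    else:
        a = np.asarray(pairs_a, dtype=float)
        b = np.asarray(pairs_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
    if d.size < 2:
        raise ValueError("paired t test needs n >= 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired t undefined: differences have zero variance")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(float(t), n - 1, float(p), float(d.mean()))


def bland_altman(a, b) -> BlandAltmanResult:
    """Bias and 95% limits of agreement, bias +/- 1.96 sd of the differences.

    Plot coordinates follow the convention mean vs difference: x = (a+b)/2,
    y = a-b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("Bland-Altman needs two equal-length samples with n >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, means=(a + b) / 2.0, differences=d
    )


def weighted_kappa(rater1, rater2, weights: str = "linear", n_categories: int | None = None) -> KappaResult:
    """Weighted kappa on ordinal grades (0..k-1).

    kappa_w = 1 - sum(w_ij o_ij) / sum(w_ij e_ij) with disagreement weights
    w_ij = |i-j|/(k-1) (linear, default) or (|i-j|/(k-1))^2 (quadratic).
    """
    r1 = np.asarray(rater1, dtype=int)
    r2 = np.asarray(rater2, dtype=int)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size == 0:
        raise ValueError("raters must supply equal-length 1-D grade vectors")
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("grades must be non-negative integers")
    k = n_categories or int(max(r1.max(), r2.max())) + 1
    if k < 2:
        raise ValueError("need at least two grade categories")
    obs = np.zeros((k, k))
    for i, j in zip(r1, r2):
        obs[i, j] += 1
    obs /= obs.sum()
    p1 = obs.sum(axis=1)
    p2 = obs.sum(axis=0)
    expected = np.outer(p1, p2)
    dist = np.abs(np.arange(k)[:, None] - np.arange(k)[None, :]) / (k - 1)
    w = dist if weights == "linear" else dist**2 if weights == "quadratic" else None
    if w is None:
        raise ValueError(f"unknown weight scheme {weights!r}")
    expected_disagreement = np.sum(w * expected)
    if expected_disagreement == 0:
        raise ValueError("kappa undefined: no chance-expected disagreement (constant raters)")
    value = 1.0 - np.sum(w * obs) / expected_disagreement
    return KappaResult(float(value), weights, _classify(float(value), KAPPA_BANDS))


def ols_slope(x, y) -> OlsResult:
    """OLS fit y = a + b x via the normal equations, with a t test on b."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("OLS slope needs n >= 3 paired observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("x is constant: slope undefined")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    n = x.size
    sigma2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = 2.0 * sps.t.sf(abs(slope) / se, n - 2)
    syy = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / syy if syy > 0 else 0.0
    return OlsResult(float(slope), float(intercept), float(p), float(r2))
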