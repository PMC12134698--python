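"""Accuracy and reliability statistics for matched bout pairs.

Accuracy follows the method-comparison convention: with device value ``d_i``
and reference value ``r_i`` over n matched bouts,

* ME   = mean(d_i - r_i)                      (mean error)
* MRE  = mean((d_i - r_i) / r_i) * 100        (mean relative error, %)
* MAE  = mean(|d_i - r_i|)                    (mean absolute error)
* MARE = mean(|d_i - r_i| / r_i) * 100        (mean absolute relative error, %)

with Bland-Altman 95% limits of agreement mean +/- 1.96 x SD (n-1 SD) around
ME and MRE.  Reliability is the two-way random-effects, absolute-agreement,
single-measures intraclass correlation ICC(2,1), computed from the two-way
ANOVA mean squares with a 95% CI by the F-based (McGraw-Wong) method, and
banded qualitatively: poor (<0.5), moderate (0.5 to <0.75), good (0.75 to
0.9), excellent (>0.9).

Distribution summaries use mean with 5%/95% quantiles; quantiles are linear
interpolation between order statistics by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .bout_matcher import MatchedPair
from .dmo_engine import SPATIAL_DMOS

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class ErrorMetrics:
    n: int
    me: float
    mre_pct: float
    mae: float
    mare_pct: float


def error_metrics(device_values: Sequence[float], reference_values: Sequence[float]) -> ErrorMetrics | None:
    """The four error statistics; ``None`` for empty input, not zeros."""
    d = np.asarray(device_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if d.shape != r.shape:
        raise ValueError("device and reference value vectors must have equal length")
    n = d.size
    if n == 0:
        return None
    if np.any(r <= 0):
        raise ValueError("reference values must be strictly positive for relative errors")
    err = d - r
    rel = err / r * 100.0
    return ErrorMetrics(
        n=n,
        me=float(np.mean(err)),
        mre_pct=float(np.mean(rel)),
        mae=float(np.mean(np.abs(err))),
        mare_pct=float(np.mean(np.abs(rel))),
    )


def limits_of_agreement(errors: Sequence[float]) -> tuple[float, float] | None:
    """Bland-Altman 95% limits: mean(errors) +/- 1.96 x SD (n-1 denominator)."""
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        return None
    m = float(np.mean(e))
    sd = float(np.std(e, ddof=1))
    return (m - LOA_MULTIPLIER * sd, m + LOA_MULTIPLIER * sd)


def quantile_summary(
    values: Sequence[float], probs: tuple[float, float] = (0.05, 0.95), method: str = "linear"
) -> tuple[float, float]:
    """Quantiles by linear interpolation between order statistics (configurable)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("quantile_summary requires at least one value")
    q = np.quantile(v, probs, method=method)
    return (float(q[0]), float(q[1]))


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    warning: str | None = None


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares for an n-subjects x k-raters table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1) if k > 1 else 0.0
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(
    device_values: Sequence[float],
    reference_values: Sequence[float],
    alpha: float = 0.05,
) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    With k = 2 raters (device, reference) and the row/column/error mean
    squares MSR, MSC, MSE,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The 95% CI uses the F-distribution bounds with Satterthwaite degrees of
    freedom.  Fewer than 5 pairs attaches a warning; zero between-subject
    variance returns a zero-or-negative ICC with a warning, not a failure.
    """
    x = np.column_stack(
        [np.asarray(device_values, dtype=float), np.asarray(reference_values, dtype=float)]
    )
    n, k = x.shape
    if n < 2:
        raise ValueError("ICC requires at least 2 pairs")
    warning = None
    if n < 5:
        warning = f"only {n} pairs; ICC is unstable below 5"

    # Perfect agreement (identical columns) short-circuits to exactly 1.0:
    # the ANOVA route would only blur it with float cancellation error.
    if np.array_equal(x[:, 0], x[:, 1]):
        if np.all(x[:, 0] == x[0, 0]):
            return ICCResult(0.0, 0.0, 0.0, n, warning="degenerate: constant table")
        return ICCResult(1.0, 1.0, 1.0, n, warning)

    msr, msc, mse = _mean_squares(x)

    # Perfect agreement: both rater and residual variation vanish.
    if mse <= 1e-30 and msc <= 1e-30:
        if msr <= 1e-30:
            return ICCResult(0.0, 0.0, 0.0, n, warning="degenerate: constant table")
        return ICCResult(1.0, 1.0, 1.0, n, warning)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom
    if msr <= mse:
        warning = (warning + "; " if warning else "") + "zero or negative between-subject variance"

    ci_low, ci_high = _icc_ci_f(icc, msr, msc, mse, n, k, alpha)
    return ICCResult(float(icc), ci_low, ci_high, n, warning)


def _icc_ci_f(
    icc: float, msr: float, msc: float, mse: float, n: int, k: int, alpha: float
) -> tuple[float, float]:
    if icc >= 1.0 - 1e-12:
        return (1.0, 1.0)
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1)
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return (float(lower), float(upper))


def icc_level(icc: float) -> str:
    """Qualitative reliability band; 0.5 is moderate, 0.75 and 0.9 are good."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Per-DMO summaries over matched pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementSummary:
    """One row of the agreement tables: one DMO over one pair stratum."""

    dmo: str
    n: int
    ref_mean: float
    ref_q05: float
    ref_q95: float
    dev_mean: float
    dev_q05: float
    dev_q95: float
    me: float
    me_loa: tuple[float, float] | None
    mre_pct: float
    mre_loa: tuple[float, float] | None
    mae: float
    mae_q05: float
    mae_q95: float
    mare_pct: float
    mare_q05: float
    mare_q95: float
    icc: float | None
    icc_ci: tuple[float, float] | None
    icc_level: str | None
    icc_warning: str | None = None


def pair_values(pairs: Sequence[MatchedPair], dmo: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract (device, reference) value vectors, skipping pairs where a
    spatial DMO is unavailable on either side."""
    dev, ref = [], []
    for p in pairs:
        d = p.device_dmos.value(dmo)
        r = p.reference_dmos.value(dmo)
        if d is None or r is None:
            if dmo not in SPATIAL_DMOS:
                raise ValueError(f"unexpected missing value for non-spatial DMO {dmo}")
            continue
        dev.append(float(d))
        ref.append(float(r))
    return np.asarray(dev), np.asarray(ref)


def summarize_pairs(
    pairs: Sequence[MatchedPair], dmo: str, quantile_method: str = "linear"
) -> AgreementSummary | None:
    """Full agreement summary for one DMO over a set of matched pairs."""
    dev, ref = pair_values(pairs, dmo)
    metrics = error_metrics(dev, ref)
    if metrics is None:
        return None
    err = dev - ref
    rel = err / ref * 100.0
    abs_err = np.abs(err)
    abs_rel = np.abs(rel)
    q = lambda v: quantile_summary(v, method=quantile_method)

    if metrics.n >= 2:
        icc_res = icc_2_1(dev, ref)
        icc, ci, level, warn = icc_res.icc, (icc_res.ci_low, icc_res.ci_high), icc_level(icc_res.icc), icc_res.warning
    else:
        icc = ci = level = warn = None

    rq, dq, maeq, mareq = q(ref), q(dev), q(abs_err), q(abs_rel)
    return AgreementSummary(
        dmo=dmo,
        n=metrics.n,
        ref_mean=float(np.mean(ref)),
        ref_q05=rq[0],
        ref_q95=rq[1],
        dev_mean=float(np.mean(dev)),
        dev_q05=dq[0],
        dev_q95=dq[1],
        me=metrics.me,
        me_loa=limits_of_agreement(err),
        mre_pct=metrics.mre_pct,
        mre_loa=limits_of_agreement(rel),
        mae=metrics.mae,
        mae_q05=maeq[0],
        mae_q95=maeq[1],
        mare_pct=metrics.mare_pct,
        mare_q05=mareq[0],
        mare_q95=mareq[1],
        icc=icc,
        icc_ci=ci,
        icc_level=level,
        icc_warning=warn,
    )
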