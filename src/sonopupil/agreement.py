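"""Paired method-comparison and observer-reliability statistics.

Implements the battery used to compare two pupillometry modalities on
eye-level averages: Bland-Altman bias and 95% limits of agreement, simple
ordinary-least-squares regression of modality A on modality B with Pearson's
r and Fisher-z confidence intervals, proportional-bias testing (regression
of paired differences on pair means), single-measure intraclass correlation
coefficients ICC(2,1) (two-way random effects, absolute agreement) and
ICC(3,1) (two-way mixed effects, consistency) from the two-way ANOVA mean
squares, and Shapiro-Wilk normality p-values.

Conventions: differences are A - B throughout, SDs use n-1 denominators, and
the limits of agreement use the fixed 1.96 multiplier (no small-sample t
correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "AgreementResult",
    "ReliabilityTable",
    "ICCResult",
    "bland_altman",
    "ols_and_pearson",
    "proportional_bias",
    "icc",
    "normality_pvalue",
    "compare_modalities",
    "agreement_table",
]

NAN = math.nan


@dataclass(frozen=True)
class PairedSample:
    """One eye's value under both modalities (A = index method, B = reference)."""

    eye_id: str
    metric_name: str
    value_a: float
    value_b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value_a) and math.isfinite(self.value_b)):
            raise ValueError(f"non-finite paired value for eye {self.eye_id}")


@dataclass
class AgreementResult:
    """Method-comparison statistics for one metric (Table-style row)."""

    metric_name: str = ""
    n: int = 0
    mean_a: float = NAN
    sd_a: float = NAN
    mean_b: float = NAN
    sd_b: float = NAN
    bias: float = NAN          # mean(a - b)
    sd_diff: float = NAN
    loa_low: float = NAN       # bias - 1.96 sd_diff
    loa_high: float = NAN      # bias + 1.96 sd_diff
    slope: float = NAN         # OLS a on b
    intercept: float = NAN
    r_squared: float = NAN
    pearson_r: float = NAN
    r_ci_low: float = NAN
    r_ci_high: float = NAN
    prop_bias_slope: float = NAN
    prop_bias_p: float = NAN


def _ab_arrays(pairs: Sequence[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([p.value_a for p in pairs], dtype=float)
    b = np.array([p.value_b for p in pairs], dtype=float)
    return a, b


def bland_altman(pairs: Sequence[PairedSample]) -> AgreementResult:
    """Bland-Altman bias and 95% limits of agreement for A - B.

    bias = mean(a - b); sd_diff uses the n-1 denominator; limits are
    bias +/- 1.96 * sd_diff.  Requires n >= 2.
    """
    if len(pairs) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    a, b = _ab_arrays(pairs)
    d = a - b
    bias = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return AgreementResult(
        metric_name=pairs[0].metric_name,
        n=len(pairs),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        bias=bias, sd_diff=sd_diff,
        loa_low=bias - 1.96 * sd_diff,
        loa_high=bias + 1.96 * sd_diff,
    )


def ols_and_pearson(pairs: Sequence[PairedSample], alpha: float = 0.05) -> AgreementResult:
    """Simple OLS of A on B plus Pearson's r with a Fisher-z CI.

    The confidence interval is tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n-3));
    |r| = 1 gives the degenerate interval [r, r].  Requires n >= 4 and
    non-zero variance in both coordinates.
    """
    if len(pairs) < 4:
        raise ValueError("regression/correlation needs at least 4 pairs")
    a, b = _ab_arrays(pairs)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one coordinate")
    sxx = np.sum((b - b.mean()) ** 2)
    sxy = np.sum((b - b.mean()) * (a - a.mean()))
    slope = float(sxy / sxx)
    intercept = float(a.mean() - slope * b.mean())
    r = float(sxy / math.sqrt(sxx * np.sum((a - a.mean()) ** 2)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        lo = hi = r
    else:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(len(pairs) - 3)
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo, hi = math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
    return AgreementResult(
        metric_name=pairs[0].metric_name, n=len(pairs),
        slope=slope, intercept=intercept,
        r_squared=r * r, pearson_r=r, r_ci_low=lo, r_ci_high=hi,
    )


def proportional_bias(pairs: Sequence[PairedSample]) -> tuple[float, float]:
    """Regress paired differences on pair means; two-sided t test on the slope.

    Returns (slope beta, p value) with n-2 degrees of freedom.  A slope of
    exactly zero reports p = 1 even when residuals vanish.
    """
    if len(pairs) < 4:
        raise ValueError("proportional-bias test needs at least 4 pairs")
    a, b = _ab_arrays(pairs)
    d, m = a - b, (a + b) / 2.0
    sxx = float(np.sum((m - m.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in pair means")
    beta = float(np.sum((m - m.mean()) * (d - d.mean())) / sxx)
    resid = d - (d.mean() + beta * (m - m.mean()))
    dof = len(pairs) - 2
    sse = float(np.sum(resid**2))
    if beta == 0.0:
        return 0.0, 1.0
    if sse == 0.0:
        return beta, 0.0
    se = math.sqrt(sse / dof / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return beta, float(p)


@dataclass
class ReliabilityTable:
    """Subjects x raters (or repeats) matrix for one metric, no missing cells."""

    metric_name: str
    values: np.ndarray
    design: str = "inter_observer"   # or "intra_observer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need >= 2 subjects and >= 2 columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing cells are not allowed (no imputation)")


@dataclass
class ICCResult:
    icc: float
    form: str                 # "icc_2_1" | "icc_3_1"
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc(table: ReliabilityTable, form: str) -> ICCResult:
    """Single-measure intraclass correlation from two-way ANOVA mean squares.

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

    where MSR/MSC/MSE are the subject, column and residual mean squares of
    the complete n x k matrix.
    """
    if form not in ("icc_2_1", "icc_3_1"):
        raise ValueError("form must be 'icc_2_1' or 'icc_3_1'")
    x = table.values
    n, k = x.shape
    gm = x.mean()
    ss_rows = k * float(np.sum((x.mean(axis=1) - gm) ** 2))
    ss_cols = n * float(np.sum((x.mean(axis=0) - gm) ** 2))
    ss_tot = float(np.sum((x - gm) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "icc_2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    value = (msr - mse) / denom if denom != 0 else NAN
    return ICCResult(icc=float(value), form=form, ms_rows=msr, ms_cols=msc, ms_error=mse)


def normality_pvalue(values: Sequence[float]) -> float:
    """Shapiro-Wilk p-value (the statistic is delegated to scipy).

    Requires 3 <= n <= 5000.  A zero-variance sample has no defined p-value
    and returns NaN.  By the reporting convention used alongside, p > 0.05
    labels a metric "approximately normal".
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return NAN
    return float(stats.shapiro(x).pvalue)


# ---------------------------------------------------------------------------
# assembly over per-eye session-averaged metric tables

def pairs_from_table(metrics_table: pd.DataFrame, metric_name: str) -> list[PairedSample]:
    """Build PairedSamples for one metric from a long-format table.

    The table needs columns ``eye_id``, ``modality`` (``auto_upa`` /
    ``ipa``) and one column per metric.  Every eye must appear under both
    modalities; offenders are listed in the error.
    """
    df = metrics_table
    col = metric_name
    if col not in df.columns:
        raise KeyError(f"metric column {col!r} not in table")
    piv = df.pivot_table(index="eye_id", columns="modality", values=col, aggfunc="first")
    for mod in ("auto_upa", "ipa"):
        if mod not in piv.columns:
            raise ValueError(f"table has no rows for modality {mod!r}")
    missing = piv.index[piv[["auto_upa", "ipa"]].isna().any(axis=1)].tolist()
    if missing:
        raise ValueError(f"eyes missing a modality for {metric_name}: {missing}")
    return [
        PairedSample(eye_id=str(i), metric_name=metric_name,
                     value_a=float(row["auto_upa"]), value_b=float(row["ipa"]))
        for i, row in piv.iterrows()
    ]


def compare_modalities(
    metrics_table: pd.DataFrame, metric_name: str, alpha: float = 0.05
) -> AgreementResult:
    """Full method comparison for one metric: Bland-Altman + OLS/Pearson +
    proportional bias, merged into a single table-style row."""
    pairs = pairs_from_table(metrics_table, metric_name)
    ba = bland_altman(pairs)
    reg = ols_and_pearson(pairs, alpha=alpha)
    beta, p = proportional_bias(pairs)
    return replace(
        ba,
        slope=reg.slope, intercept=reg.intercept, r_squared=reg.r_squared,
        pearson_r=reg.pearson_r, r_ci_low=reg.r_ci_low, r_ci_high=reg.r_ci_high,
        prop_bias_slope=beta, prop_bias_p=p,
    )


def agreement_table(
    metrics_table: pd.DataFrame, metric_names: Iterable[str], alpha: float = 0.05
) -> pd.DataFrame:
    """One comparison row per metric (means +/- SD, bias, LoA, r, ...)."""
    rows = []
    for name in metric_names:
        res = compare_modalities(metrics_table, name, alpha=alpha)
        rows.append(vars(res))
    return pd.DataFrame(rows)
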