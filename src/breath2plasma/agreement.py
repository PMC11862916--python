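"""Correlation, log-log regression, prediction and agreement statistics.

The breath-plasma link is a power law, fitted as OLS of LN(plasma, ng/mL) on
LN(breath, pptv).  Agreement of predicted vs measured plasma uses a two-way
absolute-agreement single-measure ICC plus Bland-Altman bias and limits of
agreement.  Group contrasts use one-way ANOVA and t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import (
    RefusedComparisonError,
    RegressionError,
    UndefinedStatisticError,
)
from .preprocessing import MatchedPair


@dataclass(frozen=True)
class LogLogModel:
    """LN(cp) = slope * LN(ce) + intercept, ce in pptv, cp in ng/mL."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    ce_unit: str = "pptv"
    cp_unit: str = "ng/mL"


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    icc_ci: Tuple[float, float]
    p_value: float
    bias: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    df: Tuple[float, float] | float
    groups: Tuple[str, ...]
    test: str


def _pairs_to_arrays(pairs: Sequence[MatchedPair]) -> Tuple[np.ndarray, np.ndarray]:
    ce = np.array([p.ce for p in pairs], dtype=float)
    cp = np.array([p.cp for p in pairs], dtype=float)
    return ce, cp


def spearman_correlation(pairs: Sequence[MatchedPair]) -> Tuple[float, float]:
    """Spearman rank correlation (ties averaged) with t-approximation p-value."""
    if len(pairs) < 3:
        raise UndefinedStatisticError("need at least 3 pairs for correlation")
    ce, cp = _pairs_to_arrays(pairs)
    if np.all(ce == ce[0]) or np.all(cp == cp[0]):
        raise UndefinedStatisticError("correlation undefined for constant input")
    res = stats.spearmanr(ce, cp)
    return float(res.statistic), float(res.pvalue)


def fit_loglog(pairs: Sequence[MatchedPair]) -> LogLogModel:
    """OLS of LN(cp) on LN(ce) over positive matched pairs."""
    if len(pairs) < 3:
        raise RegressionError("need at least 3 pairs for regression")
    ce, cp = _pairs_to_arrays(pairs)
    x, y = np.log(ce), np.log(cp)
    if np.ptp(x) == 0:
        raise RegressionError("zero variance in LN(ce)")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid ** 2)) / sst
    return LogLogModel(
        slope=float(slope), intercept=float(intercept), r_squared=r2, n_pairs=len(pairs)
    )


def predict_plasma(model: LogLogModel, ce):
    """Predicted plasma concentration (ng/mL) for breath concentration (pptv)."""
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr <= 0):
        raise ValueError("breath concentration must be positive")
    out = np.exp(model.slope * np.log(ce_arr) + model.intercept)
    return float(out) if out.ndim == 0 else out


def _icc_mean_squares(table: np.ndarray):
    """Two-way ANOVA mean squares for an n x k (targets x raters) table."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((table - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_agreement(
    actual: Sequence[float],
    predicted: Sequence[float],
    confidence: float = 0.95,
    log_scale_bland_altman: bool = False,
) -> AgreementResult:
    """ICC(2,1) absolute agreement of predicted vs actual, plus Bland-Altman.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) with k = 2; the
    p-value is from F = MSR/MSE and the confidence interval follows the
    standard two-way random-effects construction.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("actual and predicted must be equal-length 1-D, n >= 3")
    table = np.column_stack([a, p])
    n, k = table.shape
    if np.ptp(table) == 0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    msr, msc, mse = _icc_mean_squares(table)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedStatisticError("ICC undefined: zero denominator")
    icc = (msr - mse) / denom

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        p_value = 0.0
        ci = (icc, icc)
    else:
        f_obs = msr / mse
        p_value = float(stats.f.sf(f_obs, df1, df2))
        ci = _icc_ci(icc, msr, msc, mse, n, k, confidence)

    if log_scale_bland_altman:
        if np.any(a <= 0) or np.any(p <= 0):
            raise ValueError("log-scale Bland-Altman requires positive values")
        diffs = np.log(p) - np.log(a)
    else:
        diffs = p - a
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        icc=float(icc),
        icc_ci=ci,
        p_value=p_value,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def _icc_ci(icc, msr, msc, mse, n, k, confidence):
    # Satterthwaite df for the ICC(A,1) interval (McGraw & Wong construction)
    alpha = 1.0 - confidence
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc))
    fc = msc / mse
    v_num = (a * fc + b) ** 2
    v_den = (a * a * fc * fc) / (k - 1.0) + (b * b) / ((n - 1.0) * (k - 1.0))
    v = v_num / v_den if v_den > 0 else (n - 1.0) * (k - 1.0)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return (float(lower), float(upper))


def one_way_anova(groups: Sequence[Sequence[float]], names: Optional[Sequence[str]] = None) -> GroupComparison:
    """Classical one-way ANOVA computed from between/within mean squares."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(arrays)
    ssb = float(sum(g.size * (g.mean() - grand) ** 2 for g in arrays))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in arrays))
    df_b, df_w = k - 1, n_total - k
    if ssw == 0 and ssb == 0:
        raise UndefinedStatisticError("ANOVA degenerate: zero variance everywhere")
    if ssw == 0:
        f, p = math.inf, 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    if names is None:
        names = tuple(f"group{i+1}" for i in range(k))
    return GroupComparison(
        statistic=float(f), p_value=p, df=(float(df_b), float(df_w)),
        groups=tuple(names), test="one_way_anova",
    )


# parameters never compared across matrices: the concentration unit differs
# between breath and plasma, making V1/CL/AUC incommensurable
_REFUSED_PARAMETERS = {"v1", "cl", "auc", "auc_0_120", "auc_inf", "auc_0_t"}

_PARAM_GETTERS = {
    "k10": lambda f: f.micro.K10,
    "k12": lambda f: f.micro.K12,
    "k21": lambda f: f.micro.K21,
    "t_half_alpha": lambda f: f.derived.t_half_alpha,
    "t_half_beta": lambda f: f.derived.t_half_beta,
}


def compare_parameters(
    ce_fits: Sequence,
    cp_fits: Sequence,
    parameter: str,
    paired: bool = True,
) -> GroupComparison:
    """t-test of a PK parameter between breath and plasma fits.

    Paired by subject by default (both matrices come from the same animals);
    ``paired=False`` runs Welch's unequal-variance test.  Comparisons of V1,
    CL and AUC are refused: their units differ between matrices.
    """
    key = parameter.strip().lower()
    if key in _REFUSED_PARAMETERS:
        raise RefusedComparisonError(
            f"{parameter} is unit-incommensurable between matrices; comparison refused"
        )
    if key not in _PARAM_GETTERS:
        raise KeyError(f"unknown parameter {parameter!r}")
    getter = _PARAM_GETTERS[key]
    x = np.array([getter(f) for f in ce_fits], dtype=float)
    y = np.array([getter(f) for f in cp_fits], dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired comparison needs equal-length fit lists")
        diffs = x - y
        if np.all(diffs == 0):
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(x, y)
            t, p = float(res.statistic), float(res.pvalue)
        df = float(x.size - 1)
        test = "paired_t"
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
        test = "welch_t"
    if not math.isfinite(t):
        raise UndefinedStatisticError("t statistic undefined (zero variance)")
    return GroupComparison(
        statistic=t, p_value=p, df=df, groups=("breath", "plasma"), test=test
    )
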