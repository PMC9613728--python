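"""Method-agreement statistics for comparing AnWC/AnC models.

Pairwise agreement between two models measured on the same athletes is
summarised by the Bland-Altman mean difference with 95% limits of agreement
(mean +/- 1.96 SD of the differences), the typical error TE = SD(diff)/sqrt(2)
in absolute units and as a percentage of the pair's grand mean, a paired
t-test, and the standardized mean difference Hedges' g_av (Cohen's d_av with
a small-sample correction). Across all models a one-way repeated-measures
ANOVA is run with Mauchly's sphericity test, Greenhouse-Geisser correction
of the degrees of freedom when epsilon <= 0.75, eta-squared effect size,
Bonferroni-adjusted pairwise tests, and the standard error of measurement
taken as the square root of the within-groups mean-square error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "PairedComparison",
    "RmAnovaResult",
    "bland_altman",
    "typical_error",
    "hedges_g_av",
    "rm_anova",
    "compare_models",
]

#: GG correction is applied only for clearly violated sphericity.
GG_EPSILON_THRESHOLD = 0.75


@dataclass(frozen=True)
class PairedComparison:
    """Agreement summary for one model pair measured on the same athletes."""

    labels: tuple[str, str]
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    te: float
    te_pct: float
    t_stat: float
    p_value: float
    g_av: float


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way repeated-measures ANOVA with sphericity handling."""

    f_stat: float
    df: tuple[float, float]
    df_uncorrected: tuple[int, int]
    p_value: float
    p_uncorrected: float
    eta_squared: float
    sem: float
    epsilon_gg: float
    gg_applied: bool
    mauchly_w: float
    mauchly_p: float
    pairwise: pd.DataFrame = field(repr=False)


def _paired(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    return a, b


def bland_altman(a, b, labels: tuple[str, str] = ("A", "B")) -> PairedComparison:
    """Full pairwise agreement summary between models ``a`` and ``b``.

    Differences are ``a - b``; limits of agreement use the sample SD (n-1).
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    d = a - b
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    te, te_pct = typical_error(a, b)
    if sd_diff > 0:
        t_res = stats.ttest_rel(a, b)
        t_stat, p = float(t_res.statistic), float(t_res.pvalue)
    else:
        t_stat, p = 0.0, 1.0
    return PairedComparison(
        labels=labels,
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        te=te,
        te_pct=te_pct,
        t_stat=t_stat,
        p_value=p,
        g_av=hedges_g_av(a, b),
    )


def typical_error(a, b) -> tuple[float, float]:
    """TE = SD(a-b)/sqrt(2), absolute and as % of the pair's grand mean."""
    a, b = _paired(a, b)
    te = float(np.std(a - b, ddof=1) / np.sqrt(2.0))
    grand = float(np.mean(np.concatenate([a, b])))
    if grand == 0:
        raise ValueError("grand mean is zero; percentage TE undefined")
    return te, 100.0 * te / grand


def hedges_g_av(a, b, exact: bool = False) -> float:
    """Hedges' g_av: Cohen's d_av with a small-sample bias correction.

    d_av divides the mean paired difference by the average of the two
    standard deviations. The default correction is the approximation
    ``1 - 3/(4*df - 1)`` with df = n - 1; ``exact`` uses the gamma-function
    factor instead.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    sd_av = (np.std(a, ddof=1) + np.std(b, ddof=1)) / 2.0
    if sd_av == 0:
        if np.mean(a - b) == 0:
            return 0.0
        raise ValueError("zero pooled SD with non-zero mean difference")
    d_av = float(np.mean(a - b) / sd_av)
    df = n - 1
    if exact:
        j = float(np.exp(gammaln(df / 2.0) - gammaln((df - 1) / 2.0)) / np.sqrt(df / 2.0))
    else:
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return d_av * j


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance matrix."""
    k = data.shape[1]
    s = np.cov(data, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    sc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(sc) ** 2
    den = (k - 1) * np.sum(sc**2)
    if den == 0:  # identical conditions: sphericity trivially perfect
        return 1.0
    return float(num / den)


def _mauchly(data: np.ndarray) -> tuple[float, float]:
    """Mauchly's W and its chi-square p-value for sphericity."""
    n, k = data.shape
    d = k - 1
    s = np.atleast_2d(np.cov(data, rowvar=False, ddof=1))
    sc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    eig = np.linalg.eigvalsh(sc)
    eig = np.sort(eig)[::-1][:d]  # the d non-trivial eigenvalues
    eig = np.clip(eig, 0.0, None)
    mean_eig = eig.sum() / d
    if mean_eig <= 0 or np.any(eig <= 0):
        return 0.0, 0.0
    w = float(np.prod(eig / mean_eig))
    f_corr = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1.0))
    chi2 = -(n - 1.0) * f_corr * np.log(w)
    dof = d * (d + 1) / 2.0 - 1.0
    if dof <= 0:  # two conditions: sphericity holds trivially
        return 1.0, 1.0
    return w, float(stats.chi2.sf(chi2, dof))


def rm_anova(data, bonferroni: bool = True) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an athletes x conditions table.

    ``data`` is a 2-D array or DataFrame with one row per athlete and one
    column per condition (model), complete cases only. SEM is the square
    root of the within-groups mean-square error; eta-squared is
    SS_condition / SS_total. Degrees of freedom are GG-corrected only when
    epsilon <= 0.75.
    """
    if isinstance(data, pd.DataFrame):
        cols = [str(c) for c in data.columns]
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        cols = [f"C{i + 1}" for i in range(x.shape[1])]
    if x.ndim != 2 or np.isnan(x).any():
        raise ValueError("need a complete 2-D athletes x conditions table")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 athletes and >= 2 conditions")

    grand = x.mean()
    ss_total = float(np.sum((x - grand) ** 2))
    ss_subj = float(k * np.sum((x.mean(axis=1) - grand) ** 2))
    ss_cond = float(n * np.sum((x.mean(axis=0) - grand) ** 2))
    ss_err = ss_total - ss_subj - ss_cond
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    f_stat = ms_cond / ms_err if ms_err > 0 else (np.inf if ms_cond > 0 else 0.0)
    p_unc = float(stats.f.sf(f_stat, df_cond, df_err)) if np.isfinite(f_stat) else 0.0

    eps = _gg_epsilon(x)
    w, mauchly_p = _mauchly(x)
    gg = eps <= GG_EPSILON_THRESHOLD
    if gg:
        df_used = (df_cond * eps, df_err * eps)
        p_value = float(stats.f.sf(f_stat, *df_used)) if np.isfinite(f_stat) else 0.0
    else:
        df_used = (float(df_cond), float(df_err))
        p_value = p_unc

    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        cmp_ = bland_altman(x[:, i], x[:, j], labels=(cols[i], cols[j]))
        rows.append(
            {
                "a": cols[i],
                "b": cols[j],
                "mean_diff": cmp_.mean_diff,
                "loa_low": cmp_.loa_low,
                "loa_high": cmp_.loa_high,
                "te": cmp_.te,
                "te_pct": cmp_.te_pct,
                "t_stat": cmp_.t_stat,
                "p_value": cmp_.p_value,
                "p_bonferroni": min(1.0, cmp_.p_value * m) if bonferroni else cmp_.p_value,
                "g_av": cmp_.g_av,
            }
        )
    return RmAnovaResult(
        f_stat=float(f_stat),
        df=df_used,
        df_uncorrected=(df_cond, df_err),
        p_value=p_value,
        p_uncorrected=p_unc,
        eta_squared=ss_cond / ss_total if ss_total > 0 else 0.0,
        sem=float(np.sqrt(max(ms_err, 0.0))),
        epsilon_gg=eps,
        gg_applied=gg,
        mauchly_w=w,
        mauchly_p=mauchly_p,
        pairwise=pd.DataFrame(rows),
    )


def compare_models(wide: pd.DataFrame) -> tuple[pd.DataFrame, RmAnovaResult]:
    """Pairwise agreement table and RM-ANOVA for an athletes x models table."""
    anova = rm_anova(wide)
    return anova.pairwise.copy(), anova
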