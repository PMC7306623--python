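"""Group-level statistics: t-tests, JZS Bayes factors, 2x2 mixed ANOVA,
Greenhouse-Geisser epsilon, Pearson correlation, simple regression.

The independent t is the pooled-variance Student test (matching the degrees
of freedom convention n1+n2-2 used in the study's reports); Welch's variant
is available behind a flag.  The Bayes factor is the default JZS form: the
likelihood ratio obtained by integrating the standardized effect size over
a zero-centered Cauchy prior (scale 0.707 by default), evaluated by
adaptive quadrature on the noncentral-t density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats as sps

__all__ = [
    "TTestResult",
    "BayesFactor",
    "MixedAnovaResult",
    "t_independent",
    "t_paired",
    "jzs_bf_ttest",
    "mixed_anova_2x2",
    "gg_epsilon",
    "pearson",
    "simple_regression",
    "RegressionResult",
    "bonferroni",
]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    design: str               # independent | paired
    n1: int
    n2: int | None = None
    degenerate: bool = False  # zero-variance input with unequal means


@dataclass
class BayesFactor:
    bf10: float
    rscale: float
    design: str

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass
class MixedAnovaResult:
    """F tests for a 2 (group, between) x 2 (condition, within) design."""

    f_group: float
    f_within: float
    f_interaction: float
    df_num: int
    df_den: int
    p_group: float
    p_within: float
    p_interaction: float
    gg_epsilon: float = 1.0   # exactly 1 with two within-levels


def t_independent(x, y, welch: bool = False) -> TTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per sample")
    if welch:
        t, p = sps.ttest_ind(x, y, equal_var=False)
        df = sps.ttest_ind(x, y, equal_var=False).df
        return TTestResult(float(t), float(df), float(p), "independent", n1, n2)
    sp2 = (((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    df = n1 + n2 - 2
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, "independent", n1, n2)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0,
                           "independent", n1, n2, degenerate=True)
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), "independent", n1, n2)


def t_paired(x, y) -> TTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TTestResult(0.0, n - 1, 1.0, "paired", n)
        return TTestResult(math.copysign(math.inf, d.mean()), n - 1, 0.0,
                           "paired", n, degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p), "paired", n)


def jzs_bf_ttest(t: float, n1: int, n2: int | None = None,
                 rscale: float = 0.707) -> BayesFactor:
    """Default JZS Bayes factor for a t statistic.

    Two-sample when ``n2`` is given (effective N = n1 n2/(n1+n2),
    df = n1+n2-2); one-sample/paired otherwise (N = n1, df = n1-1).
    BF10 = integral over delta ~ Cauchy(0, rscale) of the noncentral-t
    likelihood, divided by the central-t likelihood.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if n2 is None:
        if n1 < 2:
            raise ValueError("need n >= 2")
        N, df, design = float(n1), n1 - 1, "paired"
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("need >= 2 per group")
        N, df, design = n1 * n2 / (n1 + n2), n1 + n2 - 2, "independent"
    sqrtN = math.sqrt(N)

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, df, delta * sqrtN) * sps.cauchy.pdf(delta, scale=rscale)

    # split at the likelihood peak so quad resolves sharp posteriors
    cut = sorted({0.0, t / sqrtN})
    num = integrate.quad(integrand, -np.inf, cut[0])[0]
    for a, b in zip(cut[:-1], cut[1:]):
        num += integrate.quad(integrand, a, b)[0]
    num += integrate.quad(integrand, cut[-1], np.inf)[0]
    bf10 = num / sps.t.pdf(t, df)
    return BayesFactor(float(bf10), rscale, design)


def mixed_anova_2x2(values: np.ndarray, group: np.ndarray) -> MixedAnovaResult:
    """Classical mixed ANOVA: between factor (2 groups) x within factor (2 levels).

    ``values`` is subjects x 2 (one column per within-level); ``group`` a
    per-subject label array with exactly two distinct values.  The between
    effect is tested against subjects-within-groups, the within and
    interaction effects against the subject x condition residual.  With two
    within-levels the interaction F equals the squared independent t on
    per-subject difference scores, and the group F equals the squared
    independent t on subject means.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("values must be subjects x 2 (within-levels)")
    if not np.isfinite(values).all():
        raise ValueError("missing cell in the design")
    gs = np.unique(group)
    if len(gs) != 2:
        raise ValueError("need exactly two groups")
    n = np.array([(group == g).sum() for g in gs])
    if n.min() < 2:
        raise ValueError("need >= 2 subjects per group")
    N = int(n.sum())

    # between-subjects part, on subject means
    M = values.mean(axis=1)
    grand = float(M.mean())
    gmeans = np.array([M[group == g].mean() for g in gs])
    ss_group = 2.0 * float(np.sum(n * (gmeans - grand) ** 2))
    ss_subj = 2.0 * float(sum(np.sum((M[group == g] - gm) ** 2)
                              for g, gm in zip(gs, gmeans)))
    df_between_err = N - 2
    ms_group = ss_group / 1.0
    ms_subj = ss_subj / df_between_err
    f_group = ms_group / ms_subj if ms_subj > 0 else (0.0 if ms_group == 0 else math.inf)

    # within-subjects part, on difference scores
    d = values[:, 1] - values[:, 0]
    dmeans = np.array([d[group == g].mean() for g in gs])
    dgrand = float(np.sum(d) / N)
    ss_within = N * dgrand ** 2 / 2.0
    ss_inter = float(np.sum(n * (dmeans - dgrand) ** 2)) / 2.0
    ss_err = float(sum(np.sum((d[group == g] - dm) ** 2)
                       for g, dm in zip(gs, dmeans))) / 2.0
    ms_err = ss_err / df_between_err
    f_within = ss_within / ms_err if ms_err > 0 else (0.0 if ss_within == 0 else math.inf)
    f_inter = ss_inter / ms_err if ms_err > 0 else (0.0 if ss_inter == 0 else math.inf)

    def pf(f):
        return float(sps.f.sf(f, 1, df_between_err)) if math.isfinite(f) else 0.0

    return MixedAnovaResult(float(f_group), float(f_within), float(f_inter),
                            1, df_between_err,
                            pf(f_group), pf(f_within), pf(f_inter))


def gg_epsilon(covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-level covariance matrix.

    epsilon = (sum lambda)^2 / ((k-1) sum lambda^2), lambda the eigenvalues
    of the double-centered covariance; equals 1 under sphericity (always,
    for k = 2) and is bounded below by 1/(k-1).
    """
    S = np.asarray(covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need >= 2 within-levels")
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    lam = np.linalg.eigvalsh(Sc)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * float(np.sum(lam ** 2))
    if denom == 0:
        return 1.0
    return float(np.sum(lam) ** 2 / denom)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment r with two-sided p (NaN, NaN for zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        return math.nan, math.nan
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f: float
    df: int
    p: float


def simple_regression(x, y) -> RegressionResult:
    """Least-squares simple regression; F is the squared slope t."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0.0:
        raise ValueError("zero predictor variance")
    res = sps.linregress(x, y)
    df = len(x) - 2
    if res.stderr == 0.0:
        f = math.inf
        p = 0.0
    else:
        tstat = res.slope / res.stderr
        f = tstat ** 2
        p = float(res.pvalue)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), float(f), df, p)


def bonferroni(alpha: float, m: int) -> float:
    """Per-comparison alpha for m comparisons (0.05/40 = 0.00125)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
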