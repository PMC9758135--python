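"""Inferential utilities: t-tests, repeated-measures ANOVA, JZS Bayes factors,
Benjamini-Hochberg FDR, and Cousineau within-subject error bars.

The repeated-measures ANOVAs use the standard within-subject sums-of-squares
partitioning with each effect tested against its own effect x subject
interaction, and report uncorrected degrees of freedom by default (a
Greenhouse-Geisser option is available).  The paired Bayes factor is the
default two-sided JZS test: a Cauchy prior (scale 0.707 = sqrt(2)/2, the
common software default) on the standardized effect size, integrated
numerically against the noncentral-t likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._exceptions import BalancedDesignError, DegenerateDataError, ParameterError

__all__ = ["TTestResult", "AnovaResult", "BayesFactorResult", "FDRResult",
           "paired_t", "one_sample_t", "rm_anova_oneway", "rm_anova_twoway",
           "jzs_bf01_paired", "jzs_bf01_from_t", "bh_fdr", "cousineau_sem"]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float


@dataclass
class AnovaResult:
    """List of effects, each ``(name, F, df_num, df_den, p)``."""
    effects: list

    def effect(self, name: str):
        for e in self.effects:
            if e[0] == name:
                return e
        raise KeyError(name)


@dataclass
class BayesFactorResult:
    bf01: float
    prior_scale: float

    @property
    def bf10(self) -> float:
        return 1.0 / self.bf01


@dataclass
class FDRResult:
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray
    q: float


def one_sample_t(x, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test of ``mean(x)`` against ``mu0`` (two-sided)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateDataError(f"need at least 2 observations, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance data; t undefined")
    mean_diff = float(x.mean() - mu0)
    t = mean_diff / (sd / np.sqrt(n))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p, mean_diff=mean_diff)


def paired_t(a, b) -> TTestResult:
    """Paired t-test; identical to a one-sample t on the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def _ss_tolerance(data: np.ndarray) -> float:
    """Sum-of-squares scale below which an effect is numerically zero."""
    scale = float(np.abs(data).max())
    return data.size * (np.finfo(float).eps * max(scale, 1.0)) ** 2 * 1e4


def _f_ratio(ms_eff: float, ms_err: float, tol: float) -> float:
    """F with degenerate cases pinned: zero effect -> 0, zero error -> inf."""
    if ms_eff <= tol:
        return 0.0
    if ms_err <= tol:
        return float("inf")
    return float(ms_eff / ms_err)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    S = np.cov(data.T, ddof=1)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((S ** 2).sum() - 2 * k * (row_means ** 2).sum()
                     + k ** 2 * grand ** 2)
    return float(num / den) if den > 0 else 1.0


def rm_anova_oneway(data, *, gg_correction: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x levels matrix.

    ``F = MS_levels / MS_(levels x subjects)`` with df ``(L-1, (L-1)(S-1))``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise BalancedDesignError("need a 2-D matrix with >= 2 subjects and levels")
    if not np.isfinite(data).all():
        raise BalancedDesignError("missing cells are not supported")
    S, L = data.shape
    grand = data.mean()
    ss_levels = S * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = L * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_levels - ss_subj
    df1, df2 = L - 1, (L - 1) * (S - 1)
    ms_levels = ss_levels / df1
    ms_err = ss_err / df2
    tol = _ss_tolerance(data)
    F = _f_ratio(ms_levels, ms_err, tol)
    if gg_correction:
        eps = _gg_epsilon(data)
        df1, df2 = df1 * eps, df2 * eps
    p = float(sps.f.sf(F, df1, df2)) if F > 0 else 1.0
    return AnovaResult(effects=[("levels", float(F), df1, df2, p)])


def rm_anova_twoway(data) -> AnovaResult:
    """Two-way fully-crossed repeated-measures ANOVA on subjects x A x B data.

    Main effects and the interaction are each tested against their own
    effect x subject error term.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise BalancedDesignError("need a subjects x A x B array")
    if not np.isfinite(data).all():
        raise BalancedDesignError("missing cells are not supported")
    S, A, B = data.shape
    if S < 2 or A < 2 or B < 2:
        raise BalancedDesignError("need >= 2 subjects and >= 2 levels per factor")
    grand = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    ss_a = S * B * ((m_a - grand) ** 2).sum()
    ss_b = S * A * ((m_b - grand) ** 2).sum()
    ss_ab = S * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = B * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = A * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_s = A * B * ((m_s - grand) ** 2).sum()
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    effects = []
    tol = _ss_tolerance(data)
    for name, ss_eff, df_eff, ss_err, df_err in [
            ("A", ss_a, A - 1, ss_as, (A - 1) * (S - 1)),
            ("B", ss_b, B - 1, ss_bs, (B - 1) * (S - 1)),
            ("A*B", ss_ab, (A - 1) * (B - 1), ss_abs, (A - 1) * (B - 1) * (S - 1))]:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = _f_ratio(ms_eff, ms_err, tol)
        p = float(sps.f.sf(F, df_eff, df_err)) if F > 0 else 1.0
        effects.append((name, float(F), df_eff, df_err, p))
    return AnovaResult(effects=effects)


def jzs_bf01_from_t(t: float, n: int, prior_scale: float = 0.707) -> float:
    """JZS Bayes factor in favor of the null, from a one-sample/paired t value.

    BF01 = f(t | delta = 0) / integral f(t | delta) Cauchy(delta; 0, r) d delta,
    where f is the (non)central-t density with df = n - 1 and noncentrality
    sqrt(n) * delta.
    """
    if n < 2:
        raise DegenerateDataError("need n >= 2")
    if prior_scale <= 0:
        raise ParameterError("prior_scale must be positive")
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        return (sps.nct.pdf(t, df, sqrt_n * delta)
                * sps.cauchy.pdf(delta, loc=0.0, scale=prior_scale))

    lower, err_lo = integrate.quad(integrand, -np.inf, 0.0, limit=200)
    upper, err_hi = integrate.quad(integrand, 0.0, np.inf, limit=200)
    m1, err = lower + upper, err_lo + err_hi
    if not np.isfinite(m1) or m1 <= 0 or err > 1e-6 * max(m1, 1e-12):
        raise DegenerateDataError(
            f"marginal-likelihood quadrature did not converge (m1={m1}, err={err})")
    m0 = sps.t.pdf(t, df)
    return float(m0 / m1)


def jzs_bf01_paired(a, b, prior_scale: float = 0.707) -> BayesFactorResult:
    """Default Bayesian paired t-test; returns evidence for the null (BF01)."""
    res = paired_t(a, b)
    bf01 = jzs_bf01_from_t(res.t, res.df + 1, prior_scale)
    return BayesFactorResult(bf01=bf01, prior_scale=prior_scale)


def bh_fdr(p, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up adjusted p-values and rejections at level q."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ParameterError("q must be in (0, 1)")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRResult(p_raw=p, p_adjusted=p_adj, rejected=rejected, q=q)


def cousineau_sem(data, *, morey_correction: bool = False) -> np.ndarray:
    """Within-subject standard errors for a subjects x conditions matrix.

    Each cell is first recentered, ``cell - subject_mean + grand_mean``,
    removing between-subject offsets; per-condition SEMs of the normalized
    values follow.  The optional Morey factor ``sqrt(C / (C - 1))``
    corrects the systematic underestimate of the normalized variance.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise DegenerateDataError("need >= 2 subjects (rows)")
    S, C = data.shape
    normalized = data - data.mean(axis=1, keepdims=True) + data.mean()
    sem = normalized.std(axis=0, ddof=1) / np.sqrt(S)
    if morey_correction:
        if C < 2:
            raise DegenerateDataError("Morey correction needs >= 2 conditions")
        sem = sem * np.sqrt(C / (C - 1))
    return sem
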