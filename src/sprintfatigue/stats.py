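"""Model-comparison and group-difference statistics, implemented from formulas.

All tests are two-sided at the conventional alpha = 0.05.  Effect sizes follow
the usual small-sample conventions: Hedges' g (bias-corrected standardised
mean difference) for independent contrasts, Cohen's d on the paired
differences for within-subject contrasts, and partial eta squared for the
repeated-measures ANOVA.  Only p-value lookups use scipy's distributions; the
statistics themselves are computed directly from sums of squares so they can
be validated against independent brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "independent_t",
    "hedges_g",
    "paired_t",
    "pitman_morgan",
    "rm_anova_gg",
    "bonferroni",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: size, mean and (ddof=1) SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("GroupSummary requires n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, float)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom (possibly fractional), p-value and effect size."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect_size: float | None = None
    effect_size_kind: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    df = g1.n + g2.n - 2
    return float(np.sqrt(((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df))


def independent_t(g1: GroupSummary, g2: GroupSummary, welch: bool = False) -> TestResult:
    """Two-sample t-test from group summaries, pooled-variance or Welch.

    Pooled: ``t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2))`` with
    ``df = n1 + n2 - 2``.  Welch uses per-group variances with
    Welch-Satterthwaite df.  Hedges' g is attached as the effect size.
    """
    if g1.sd == 0 and g2.sd == 0:
        raise ValueError("both groups have zero variance")
    diff = g1.mean - g2.mean
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    if welch:
        t = diff / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    else:
        sp = _pooled_sd(g1, g2)
        t = diff / (sp * np.sqrt(1.0 / g1.n + 1.0 / g2.n))
        df = g1.n + g2.n - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t),
        df=float(df),
        p_value=float(p),
        effect_size=hedges_g(g1, g2),
        effect_size_kind="hedges_g",
    )


def hedges_g(g1: GroupSummary, g2: GroupSummary) -> float:
    """Bias-corrected standardised mean difference.

    ``g = J * (m1 - m2) / s_pooled`` with ``J = 1 - 3/(4 df - 1)``,
    ``df = n1 + n2 - 2``.
    """
    sp = _pooled_sd(g1, g2)
    if sp == 0:
        raise ValueError("zero pooled SD")
    df = g1.n + g2.n - 2
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(j * (g1.mean - g2.mean) / sp)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired t-test on the differences, with Cohen's d = mean(diff)/sd(diff)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs two equal-length samples of size >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of the paired differences")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(
        statistic=float(t),
        df=float(n - 1),
        p_value=float(p),
        effect_size=float(d.mean() / sd),
        effect_size_kind="cohens_d",
    )


def pitman_morgan(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pitman-Morgan test for equal variances of two correlated (paired) samples.

    ``t = (s_x^2 - s_y^2) * sqrt(n - 2) / (2 s_x s_y sqrt(1 - r^2))`` with
    ``r`` the sample correlation and ``df = n - 2``.  The sign convention is
    ``s_x^2 - s_y^2`` (negative when the second sample varies more).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pitman_morgan needs two equal-length samples of size >= 3")
    n = x.size
    sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance sample")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        raise ValueError("|r| = 1: samples are perfectly correlated")
    t = (sx2 - sy2) * np.sqrt(n - 2) / (2.0 * np.sqrt(sx2 * sy2) * np.sqrt(1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestResult(statistic=float(t), df=float(n - 2), p_value=float(p))


def rm_anova_gg(data: np.ndarray) -> TestResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` is a complete subjects x conditions matrix (>= 3 subjects,
    >= 2 conditions).  Returns the F statistic with GG-adjusted degrees of
    freedom ``(eps*(k-1), eps*(k-1)(n-1))``, the GG-adjusted p-value, and
    partial eta squared ``SS_cond / (SS_cond + SS_err)``.

    The GG epsilon is computed from the double-centered condition covariance
    matrix:  ``eps = tr(S~)^2 / ((k-1) * sum(S~^2))``; with two conditions
    sphericity holds trivially and eps = 1.
    """
    y = np.asarray(data, float)
    if y.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions matrix")
    if np.any(~np.isfinite(y)):
        raise ValueError("data matrix must be complete (no NaN/inf)")
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError("rm_anova_gg needs >= 3 subjects and >= 2 conditions")

    grand = y.mean()
    cond_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj

    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    tol = 1e-12 * max(float(ss_total), 1e-300)
    ss_cond = 0.0 if ss_cond < tol else float(ss_cond)
    ss_err = max(float(ss_err), 0.0)
    if ss_err < tol:  # degenerate: no within-subject residual variation
        f = 0.0 if ss_cond == 0.0 else np.inf
    else:
        f = (ss_cond / df_cond) / (ss_err / df_err)

    s = np.cov(y, rowvar=False, ddof=1)
    centered = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    denom = df_cond * np.sum(centered**2)
    eps = 1.0 if denom == 0 else float(np.trace(centered) ** 2 / denom)
    eps = min(1.0, max(eps, 1.0 / df_cond))

    df1, df2 = eps * df_cond, eps * df_err
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    eta = 0.0 if ss_cond == 0 else float(ss_cond / (ss_cond + ss_err))
    return TestResult(
        statistic=float(f),
        df=(float(df1), float(df2)),
        p_value=p,
        effect_size=eta,
        effect_size_kind="partial_eta_sq",
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, p*m)``; ``m`` defaults to the list length."""
    p = np.asarray(p_values, float)
    m = p.size if m is None else m
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, p * m)
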