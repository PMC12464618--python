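"""Inverse-variance meta-analysis primitives.

Fixed-effect and DerSimonian-Laird random-effects pooling of log odds
ratios, Cochran's Q / I-squared / tau-squared heterogeneity statistics,
Egger's regression test for small-study effects, and recovery of a
two-sided p-value from a pooled OR and its upper confidence limit (the
usual fallback when a meta-analysis prints an OR with CI but no p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

#: Normal quantile used for 95% intervals throughout.  Kept at the rounded
#: 1.96 (rather than the exact 1.95996...) because published tables derive
#: their intervals and standard errors with this constant.
CI_Z = 1.96


@dataclass(frozen=True)
class StudyEffect:
    """One primary study's effect on the log-OR scale.

    Parameters
    ----------
    label : str
        Study identifier.
    log_or : float
        Natural-log odds ratio.
    se : float
        Standard error of ``log_or``; must be positive.
    counts : tuple of int, optional
        The originating 2x2 table ``(a, b, c, d)`` = (cases exposed,
        cases unexposed, controls exposed, controls unexposed), if known.
    """

    label: str
    log_or: float
    se: float
    counts: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"study {self.label!r}: se must be positive, got {self.se}")
        if not math.isfinite(self.log_or):
            raise ValueError(f"study {self.label!r}: non-finite log_or")

    @property
    def p_value(self) -> float:
        """Two-sided Wald p-value of this study's effect."""
        return 2.0 * stats.norm.sf(abs(self.log_or) / self.se)


@dataclass(frozen=True)
class PooledResult:
    """A pooled meta-analytic estimate with heterogeneity statistics.

    ``theta`` and ``se`` are on the log-OR scale; ``ci_low``/``ci_high``
    are the 95% limits on the OR scale.  ``q`` is Cochran's Q computed
    with fixed-effect weights (also under the random-effects model, as is
    conventional), ``i2`` is in percent, and ``tau2`` is the DL
    between-study variance (0 for the fixed model).
    """

    model: str            # "fixed" | "random"
    theta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    q: float
    df: int
    q_p: float
    i2: float
    tau2: float

    @property
    def or_point(self) -> float:
        return math.exp(self.theta)


@dataclass(frozen=True)
class EggerResult:
    """Egger regression test of funnel-plot asymmetry.

    ``p_value`` is ``None`` when fewer than three studies are available
    (the test is not calculable), mirroring how published tables report
    "NC" in that case.
    """

    intercept: float
    intercept_se: float
    p_value: float | None
    n_studies: int


def log_or_from_counts(
    a: int, b: int, c: int, d: int, label: str = ""
) -> StudyEffect:
    """Log odds ratio and SE from a 2x2 table, with zero-cell handling.

    If any cell is zero, 0.5 is added to all four cells
    (Haldane-Anscombe) before computing ``ln(ad/bc)`` and the usual
    Woolf SE ``sqrt(1/a + 1/b + 1/c + 1/d)``.

    Raises
    ------
    ValueError
        If any count is negative, or all four counts are zero
        (degenerate table).
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"negative cell count in {counts}")
    if all(x == 0 for x in counts):
        raise ValueError("degenerate table: all four cells are zero")
    if any(x == 0 for x in counts):
        ap, bp, cp, dp = (x + 0.5 for x in counts)
    else:
        ap, bp, cp, dp = counts
    log_or = math.log((ap * dp) / (bp * cp))
    se = math.sqrt(1 / ap + 1 / bp + 1 / cp + 1 / dp)
    return StudyEffect(label=label, log_or=log_or, se=se, counts=counts)


def _heterogeneity(theta: np.ndarray, w: np.ndarray) -> tuple[float, int, float, float]:
    """Q, df, upper-tail chi-square p of Q, and I^2 (%) with weights w."""
    theta_f = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_f) ** 2))
    df = len(theta) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, q_p, i2


def _assemble(model: str, theta: float, se: float,
              q: float, df: int, q_p: float, i2: float, tau2: float) -> PooledResult:
    z = theta / se
    return PooledResult(
        model=model,
        theta=theta,
        se=se,
        ci_low=math.exp(theta - CI_Z * se),
        ci_high=math.exp(theta + CI_Z * se),
        p_value=2.0 * float(stats.norm.sf(abs(z))),
        q=q, df=df, q_p=q_p, i2=i2, tau2=tau2,
    )


def pool_fixed(studies: Sequence[StudyEffect]) -> PooledResult:
    """Inverse-variance fixed-effect pooling."""
    if len(studies) == 0:
        raise ValueError("cannot pool an empty list of studies")
    theta = np.array([s.log_or for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    q, df, q_p, i2 = _heterogeneity(theta, w)
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return _assemble("fixed", pooled, se, q, df, q_p, i2, tau2=0.0)


def pool_random_dl(studies: Sequence[StudyEffect]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    The moment estimator ``tau2 = max(0, (Q - df) / C)`` with
    ``C = sum(w) - sum(w^2)/sum(w)`` uses fixed-effect weights; studies
    are then re-weighted by ``1/(se^2 + tau2)``.  With a single study,
    or whenever ``Q <= df``, the result coincides with :func:`pool_fixed`.
    """
    if len(studies) == 0:
        raise ValueError("cannot pool an empty list of studies")
    theta = np.array([s.log_or for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    q, df, q_p, i2 = _heterogeneity(theta, w)
    if df == 0:
        tau2 = 0.0
    else:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (np.array([s.se**2 for s in studies]) + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    return _assemble("random", pooled, se, q, df, q_p, i2, tau2=tau2)


def egger_test(studies: Sequence[StudyEffect]) -> EggerResult:
    """Classic Egger test: standardized effect regressed on precision.

    Ordinary least squares of ``theta_i / se_i`` on ``1 / se_i``; the
    intercept estimates funnel asymmetry and is tested two-sided against
    a t distribution with ``n - 2`` degrees of freedom.  Returns a
    ``p_value`` of ``None`` for fewer than three studies.
    """
    n = len(studies)
    if n < 3:
        return EggerResult(intercept=math.nan, intercept_se=math.nan,
                           p_value=None, n_studies=n)
    y = np.array([s.log_or / s.se for s in studies])
    x = sm.add_constant(np.array([1.0 / s.se for s in studies]))
    fit = sm.OLS(y, x).fit()
    return EggerResult(
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        p_value=float(fit.pvalues[0]),
        n_studies=n,
    )


def p_from_estimate(or_point: float, ci_high: float) -> float:
    """Recover a two-sided p-value from a pooled OR and its upper 95% limit.

    Uses ``SE = (ln ci_high - ln or_point) / 1.96`` and the normal
    ``Z = ln(or_point) / SE``.  The magnitude of Z is what matters, so
    protective ORs (< 1) are handled symmetrically.
    """
    if or_point <= 0 or ci_high <= 0:
        raise ValueError("odds ratios must be positive")
    if ci_high <= or_point:
        raise ValueError(
            f"inverted interval: upper limit {ci_high} <= point estimate {or_point}"
        )
    se = (math.log(ci_high) - math.log(or_point)) / CI_Z
    z = math.log(or_point) / se
    return 2.0 * float(stats.norm.sf(abs(z)))
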