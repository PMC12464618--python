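"""Bayesian false-positive metrics for pooled genetic associations.

Two complementary metrics, both computed from nothing more than a pooled
odds ratio with its 95% confidence interval and a prior probability that
the association is real:

* **FPRP** (false positive report probability, Wacholder): the posterior
  probability that a significant finding is a false positive, given the
  observed significance level alpha, the power to detect a specified
  target OR at that level, and the prior pi:

      FPRP = alpha (1 - pi) / (alpha (1 - pi) + (1 - beta) pi)

* **BFDP** (Bayesian false discovery probability, Wakefield): the
  posterior probability of the null under a normal approximate Bayes
  factor with prior variance W on the log-OR,

      ABF  = sqrt((V + W) / V) * exp(-Z^2 W / (2 (V + W)))
      BFDP = ABF * PO / (ABF * PO + 1),   PO = (1 - pi) / pi

Conventions that matter for reproducing published spreadsheets: the SE
is taken from the *upper* confidence limit only, (ln UCI - ln OR)/1.96
(the full-width alternative is behind ``se_convention``); the observed
alpha is recomputed from Z rather than read from possibly truncated
printed p-values; and all computations run on |ln OR| so that a
protective OR and its reciprocal give identical results, with target
ORs always stated above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from scipy import stats

from .meta_core import CI_Z

__all__ = [
    "EffectEstimate", "PriorSpec", "FprpResult", "BfdpResult",
    "CredibilityResult", "effect_from_ci", "power_at_or", "fprp",
    "bfdp", "assess",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A pooled OR with 95% CI and its derived log-scale quantities.

    ``theta`` is ln(OR) (signed); ``se`` the log-scale standard error
    under the chosen CI convention; ``z = theta / se``; ``alpha`` the
    two-sided normal p recomputed from ``z``.
    """

    or_point: float
    ci_low: float
    ci_high: float
    reported_p: float | None = None
    theta: float = field(init=False)
    se: float = field(init=False)
    z: float = field(init=False)
    alpha: float = field(init=False)
    se_convention: str = "upper_ci"

    def __post_init__(self) -> None:
        if not (0 < self.ci_low < self.or_point < self.ci_high):
            raise ValueError(
                f"interval ({self.ci_low}, {self.ci_high}) does not contain "
                f"the point estimate {self.or_point}"
            )
        theta = math.log(self.or_point)
        if self.se_convention == "upper_ci":
            se = (math.log(self.ci_high) - theta) / CI_Z
        elif self.se_convention == "full_width":
            se = (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * CI_Z)
        else:
            raise ValueError(f"unknown se_convention {self.se_convention!r}")
        z = theta / se
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "se", se)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "alpha", 2.0 * float(stats.norm.sf(abs(z))))


def effect_from_ci(
    or_point: float,
    ci_low: float,
    ci_high: float,
    reported_p: float | None = None,
    se_convention: str = "upper_ci",
) -> EffectEstimate:
    """Build an :class:`EffectEstimate` from a printed OR and 95% CI."""
    return EffectEstimate(or_point, ci_low, ci_high,
                          reported_p=reported_p, se_convention=se_convention)


@dataclass(frozen=True)
class PriorSpec:
    """Priors, detectable target ORs and noteworthiness thresholds.

    ``priors`` are prior probabilities pi of a true association (the
    conventional medium 0.05 and low 0.001 candidate-gene expectations);
    ``target_ors`` the detectable ORs at which FPRP power is evaluated
    (reciprocals implied for protective effects); ``bfdp_prior_or975``
    the 97.5th percentile of the prior OR distribution anchoring the
    BFDP prior variance W.  ``fprp_rule`` decides whether a comparison
    is FPRP-noteworthy when *all* target ORs fall below the threshold
    (default) or *any* of them.
    """

    priors: tuple[float, ...] = (0.05, 0.001)
    target_ors: tuple[float, ...] = (1.5, 2.0)
    bfdp_prior_or975: float = 1.5
    fprp_threshold: float = 0.2
    bfdp_threshold: float = 0.8
    se_convention: str = "upper_ci"
    fprp_rule: str = "all"

    def __post_init__(self) -> None:
        if not all(0 < p < 1 for p in self.priors):
            raise ValueError("priors must lie in (0, 1)")
        if not all(t > 1 for t in self.target_ors):
            raise ValueError("target ORs must exceed 1 (reciprocals implied)")
        if self.bfdp_prior_or975 <= 1:
            raise ValueError("bfdp_prior_or975 must exceed 1")
        if not (0 < self.fprp_threshold < 1 and 0 < self.bfdp_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.fprp_rule not in ("all", "any"):
            raise ValueError("fprp_rule must be 'all' or 'any'")

    @property
    def w(self) -> float:
        """Prior variance W of the log OR implied by ``bfdp_prior_or975``."""
        return (math.log(self.bfdp_prior_or975) / CI_Z) ** 2


@dataclass(frozen=True)
class FprpResult:
    """FPRP grid over (prior, target OR), with power and noteworthiness."""

    power: Mapping[float, float]                      # target_or -> 1 - beta
    fprp: Mapping[tuple[float, float], float]         # (prior, target_or) -> FPRP
    noteworthy: Mapping[tuple[float, float], bool]

    def noteworthy_at(self, prior: float, rule: str = "all") -> bool:
        cells = [self.noteworthy[(p, t)] for (p, t) in self.noteworthy if p == prior]
        if not cells:
            raise KeyError(f"prior {prior} not in FPRP grid")
        return all(cells) if rule == "all" else any(cells)


@dataclass(frozen=True)
class BfdpResult:
    """BFDP per prior, with the shared V, W and approximate Bayes factor."""

    v: float
    w: float
    abf: float
    bfdp: Mapping[float, float]                       # prior -> BFDP
    noteworthy: Mapping[float, bool]


@dataclass(frozen=True)
class CredibilityResult:
    """FPRP and BFDP for one estimate, plus comparison-level flags."""

    effect: EffectEstimate
    spec: PriorSpec
    fprp: FprpResult
    bfdp: BfdpResult

    def noteworthy_at(self, prior: float) -> bool:
        """Noteworthy at ``prior``: FPRP below threshold (per the
        configured rule across target ORs) or BFDP below threshold."""
        return (self.fprp.noteworthy_at(prior, self.spec.fprp_rule)
                or self.bfdp.noteworthy[prior])


def power_at_or(target_or: float, se: float, alpha: float) -> float:
    """Power to detect ``target_or`` at two-sided level ``alpha``.

    With critical value ``z_c = Phi^-1(1 - alpha/2)`` and noncentrality
    ``mu = ln(target_or)/se``:  ``1 - Phi(z_c - mu) + Phi(-z_c - mu)``.
    As se grows (mu -> 0) this tends to alpha, the size of the test.
    """
    if target_or <= 1:
        raise ValueError("target_or must exceed 1; reciprocals are implied")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if se <= 0:
        raise ValueError("se must be positive")
    z_c = float(stats.norm.isf(alpha / 2.0))
    mu = math.log(target_or) / se
    return float(stats.norm.sf(z_c - mu) + stats.norm.cdf(-z_c - mu))


def fprp(alpha: float, power: float, prior: float) -> float:
    """Wacholder's false positive report probability.

    ``alpha (1-pi) / (alpha (1-pi) + power * pi)``; returns 1.0 in the
    limit of zero power rather than dividing by zero.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if not (0 <= power <= 1):
        raise ValueError("power must lie in [0, 1]")
    if not (0 < prior < 1):
        raise ValueError("prior must lie in (0, 1)")
    num = alpha * (1.0 - prior)
    den = num + power * prior
    if den == 0.0:
        return 1.0
    return num / den


def bfdp(theta: float, se: float, prior: float,
         prior_or975: float = 1.5) -> tuple[float, float, float, float]:
    """Wakefield's Bayesian false discovery probability.

    Returns ``(v, w, abf, bfdp)`` where ``v = se**2`` and
    ``w = (ln(prior_or975)/1.96)**2``.  The sign of ``theta`` is
    irrelevant (only Z^2 enters the Bayes factor).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not (0 < prior < 1):
        raise ValueError("prior must lie in (0, 1)")
    v = se * se
    w = (math.log(prior_or975) / CI_Z) ** 2
    z = theta / se
    abf = math.sqrt((v + w) / v) * math.exp(-z * z * w / (2.0 * (v + w)))
    po = (1.0 - prior) / prior
    return v, w, abf, abf * po / (abf * po + 1.0)


def assess(effect: EffectEstimate, spec: PriorSpec | None = None) -> CredibilityResult:
    """Full credibility grid for one pooled estimate.

    Computes power at every target OR, the FPRP over priors x target
    ORs, BFDP per prior, and per-cell noteworthiness flags.  All on
    |ln OR| magnitudes, so reciprocal estimates assess identically.
    """
    if spec is None:
        spec = PriorSpec()
    theta_mag = abs(effect.theta)
    power = {t: power_at_or(t, effect.se, effect.alpha) for t in spec.target_ors}
    grid = {}
    flags = {}
    for pi in spec.priors:
        for t in spec.target_ors:
            val = fprp(effect.alpha, power[t], pi)
            grid[(pi, t)] = val
            flags[(pi, t)] = val < spec.fprp_threshold
    fprp_res = FprpResult(power=power, fprp=grid, noteworthy=flags)

    bmap = {}
    bflags = {}
    v = w = abf = math.nan
    for pi in spec.priors:
        v, w, abf, b = bfdp(theta_mag, effect.se, pi, spec.bfdp_prior_or975)
        bmap[pi] = b
        bflags[pi] = b < spec.bfdp_threshold
    bfdp_res = BfdpResult(v=v, w=w, abf=abf, bfdp=bmap, noteworthy=bflags)
    return CredibilityResult(effect=effect, spec=spec, fprp=fprp_res, bfdp=bfdp_res)
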