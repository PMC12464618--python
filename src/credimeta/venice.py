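"""Venice-criteria grading of cumulative epidemiological evidence.

Three domains are graded A/B/C and combined into an overall label:

* **Amount of evidence** — total sample size (subjects or alleles):
  A > 1000, B in (100, 1000], C <= 100.
* **Consistency** — heterogeneity I^2 (%): A < 25, B in [25, 50], C > 50.
* **Protection from bias** — Egger test p-value, with a small-effect
  rule: grade C when Egger p <= 0.05 or when the pooled OR is small
  enough (within [0.87, 1.15] by default) to be explicable by modest
  bias; grade B when the analyst flags potential concerns despite a
  non-significant Egger test; otherwise A.  When the Egger p is not
  calculable (fewer than three studies) the domain, and the overall
  label, are not applicable.

Overall: Strong only for "AAA"; Weak when any domain is C; Moderate
otherwise.  Boundary conventions are frozen here and in the tests:
amount B is the half-open (100, 1000], consistency B the closed
[25, 50], and the Egger cut is p <= 0.05 (published gradings place
p = 0.05 in grade C).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "VeniceConfig", "VeniceGrade", "grade_amount", "grade_consistency",
    "grade_bias", "overall", "grade_evidence", "NA",
]

#: Domain marker for "not applicable" (shown as "-" in grade codes).
NA = "-"

_OVERALL_LABELS = {"Strong": "S", "Moderate": "M", "Weak": "W", "N/A": "N/A"}


@dataclass(frozen=True)
class VeniceConfig:
    """Tunable grading rules.

    ``small_effect_rule`` enables the bias-susceptibility grade C for
    pooled ORs inside ``small_or_band``; ``concern_band`` optionally
    auto-flags "potential concerns" (grade B) for Egger p-values inside
    a half-open interval, e.g. ``(0.05, 0.10)`` — off by default, since
    the concern judgement is the analyst's.
    """

    small_effect_rule: bool = True
    small_or_band: tuple[float, float] = (0.87, 1.15)
    egger_alpha: float = 0.05
    concern_band: tuple[float, float] | None = None


@dataclass(frozen=True)
class VeniceGrade:
    """Per-domain grades and the derived overall credibility."""

    amount: str
    consistency: str
    bias: str
    overall: str       # Strong | Moderate | Weak | N/A

    @property
    def code(self) -> str:
        """Three-character code such as ``"AAC"`` or ``"BA-"``."""
        return self.amount + self.consistency + self.bias

    @property
    def label(self) -> str:
        """Short report label: S, M, W or N/A."""
        return _OVERALL_LABELS[self.overall]


def grade_amount(total_n: int) -> str:
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    if total_n > 1000:
        return "A"
    if total_n > 100:
        return "B"
    return "C"


def grade_consistency(i2: float | None) -> str:
    if i2 is None:
        return NA
    if not (0 <= i2 <= 100):
        raise ValueError(f"I^2 must be a percentage in [0, 100], got {i2}")
    if i2 < 25:
        return "A"
    if i2 <= 50:
        return "B"
    return "C"


def grade_bias(
    egger_p: float | None,
    or_point: float,
    concern: bool = False,
    config: VeniceConfig | None = None,
) -> str:
    if config is None:
        config = VeniceConfig()
    if egger_p is None:
        return NA
    if egger_p <= config.egger_alpha:
        return "C"
    lo, hi = config.small_or_band
    if config.small_effect_rule and lo <= or_point <= hi:
        return "C"
    if concern:
        return "B"
    if config.concern_band is not None:
        lo, hi = config.concern_band
        if lo <= egger_p < hi:
            return "B"
    return "A"


def overall(amount: str, consistency: str, bias: str) -> str:
    grades = (amount, consistency, bias)
    for g in grades:
        if g not in ("A", "B", "C", NA):
            raise ValueError(f"invalid grade {g!r}")
    if NA in grades:
        return "N/A"
    if all(g == "A" for g in grades):
        return "Strong"
    if any(g == "C" for g in grades):
        return "Weak"
    return "Moderate"


def grade_evidence(
    total_n: int,
    i2: float | None,
    egger_p: float | None,
    or_point: float,
    concern: bool = False,
    config: VeniceConfig | None = None,
) -> VeniceGrade:
    """Grade all three domains and derive the overall label."""
    a = grade_amount(total_n)
    c = grade_consistency(i2)
    b = grade_bias(egger_p, or_point, concern=concern, config=config)
    return VeniceGrade(amount=a, consistency=c, bias=b, overall=overall(a, c, b))
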