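"""End-to-end credibility reappraisal of pooled genetic comparisons.

Reads a table of meta-analysed comparisons (one row per study x variant
x genetic contrast x subgroup, with pooled OR, 95% CI, p-values,
heterogeneity and Egger statistics), deduplicates overlapping
meta-analyses by keeping the largest study per (variant, contrast,
subgroup), computes the FPRP/BFDP grid and Venice grades for every
record, and writes a rounded report plus a full-precision sidecar.

Input cells may carry annotations commonly found in published tables:
values in parentheses were estimated (e.g. recovered from a forest
plot) and are flagged ``*_estimated``; "<x" values are upper bounds and
only their bound is retained (alpha is always recomputed from the CI,
never from a truncated p); "NA", "NC" or an empty cell mean not
available/not calculable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .credibility import (CredibilityResult, EffectEstimate, PriorSpec,
                          assess, effect_from_ci)
from .venice import VeniceConfig, VeniceGrade, grade_evidence

__all__ = [
    "ComparisonRecord", "ReappraisalRow", "ReappraisalReport",
    "read_comparisons", "dedupe_largest", "run", "write_report",
]

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "NA", "NC", "N/A", "NAN", "NONE"}

REQUIRED_COLUMNS = [
    "study", "drug", "gene", "variant", "contrast", "subgroup", "model",
    "n_total", "or_point", "ci_low", "ci_high", "p_value", "het_p", "i2",
    "egger_p",
]


@dataclass(frozen=True)
class ParsedCell:
    """A numeric table cell with its annotation flags."""

    value: float | None
    estimated: bool = False   # printed in parentheses
    bound: bool = False       # printed as "<x": value is an upper bound


def parse_cell(token) -> ParsedCell:
    """Parse one p-value-like cell: plain number, "(x)", "<x", "(<x)" or NA."""
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return ParsedCell(None)
    s = str(token).strip()
    if s.upper() in _NA_TOKENS:
        return ParsedCell(None)
    estimated = s.startswith("(") and s.endswith(")")
    if estimated:
        s = s[1:-1].strip()
    bound = s.startswith("<")
    if bound:
        s = s[1:].strip()
    try:
        value = float(s)
    except ValueError as exc:
        raise ValueError(f"unparseable cell {token!r}") from exc
    return ParsedCell(value, estimated=estimated, bound=bound)


@dataclass(frozen=True)
class ComparisonRecord:
    """One pooled genetic comparison as printed in a summary table."""

    study: str
    drug: str
    gene: str
    variant: str
    contrast: str
    subgroup: str
    pooling_model: str            # "F" | "R"
    n_total: int
    effect: EffectEstimate
    n_studies: int | None = None
    i2: float | None = None
    het_p: ParsedCell = field(default_factory=lambda: ParsedCell(None))
    egger_p: ParsedCell = field(default_factory=lambda: ParsedCell(None))
    p_cell: ParsedCell = field(default_factory=lambda: ParsedCell(None))
    bias_concern: bool = False

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(f"{self.key}: n_total must be positive")
        if self.pooling_model not in ("F", "R"):
            raise ValueError(f"{self.key}: pooling model must be F or R")

    @property
    def key(self) -> tuple[str, str, str]:
        """Deduplication identity: (variant, contrast, subgroup)."""
        return (self.variant, self.contrast, self.subgroup)

    @property
    def p_estimated(self) -> bool:
        return self.p_cell.estimated

    @property
    def egger_estimated(self) -> bool:
        return self.egger_p.estimated


def _parse_float(token, allow_na: bool = True) -> float | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    s = str(token).strip().replace(" ", "").replace(" ", "")
    if s.upper() in _NA_TOKENS:
        if allow_na:
            return None
        raise ValueError(f"missing value {token!r}")
    return float(s)


def read_comparisons(path: str | Path,
                     se_convention: str = "upper_ci") -> list[ComparisonRecord]:
    """Read and validate a comparisons TSV.

    Required columns: study, drug, gene, variant, contrast, subgroup,
    model, n_total, or_point, ci_low, ci_high, p_value, het_p, i2,
    egger_p.  Optional: n_studies, bias_concern (0/1 analyst flag for
    the Venice "potential concerns" grade).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no comparison records")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for idx, row in df.iterrows():
        where = f"{path} row {idx + 2}"  # 1-based with header line
        try:
            p_cell = parse_cell(row["p_value"])
            effect = effect_from_ci(
                _parse_float(row["or_point"], allow_na=False),
                _parse_float(row["ci_low"], allow_na=False),
                _parse_float(row["ci_high"], allow_na=False),
                reported_p=p_cell.value,
                se_convention=se_convention,
            )
            n_studies = row.get("n_studies")
            n_studies = None if _parse_float(n_studies) is None else int(float(n_studies))
            concern = row.get("bias_concern")
            concern = (str(concern).strip() in {"1", "true", "True"}) if concern is not None else False
            records.append(ComparisonRecord(
                study=row["study"].strip(),
                drug=row["drug"].strip(),
                gene=row["gene"].strip(),
                variant=row["variant"].strip(),
                contrast=row["contrast"].strip(),
                subgroup=row["subgroup"].strip(),
                pooling_model=row["model"].strip().upper(),
                n_total=int(_parse_float(row["n_total"], allow_na=False)),
                effect=effect,
                n_studies=n_studies,
                i2=_parse_float(row["i2"]),
                het_p=parse_cell(row["het_p"]),
                egger_p=parse_cell(row["egger_p"]),
                p_cell=p_cell,
                bias_concern=concern,
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{where} ({row.get('variant', '?')}): {exc}") from exc
    return records


def dedupe_largest(records: Sequence[ComparisonRecord]) -> list[ComparisonRecord]:
    """Keep, per (variant, contrast, subgroup), the record with the
    largest total sample; subgroups are never merged.  Ties are all
    retained, with a warning."""
    by_key: dict[tuple, list[ComparisonRecord]] = {}
    for rec in records:
        by_key.setdefault(rec.key, []).append(rec)
    kept: list[ComparisonRecord] = []
    for key, group in by_key.items():
        n_max = max(r.n_total for r in group)
        winners = [r for r in group if r.n_total == n_max]
        if len(winners) > 1:
            logger.warning("tie on n_total=%d for %s: keeping all %d records",
                           n_max, key, len(winners))
        kept.extend(winners)
    # preserve input order
    kept_ids = {id(r) for r in kept}
    return [r for r in records if id(r) in kept_ids]


@dataclass(frozen=True)
class ReappraisalRow:
    """One record with its credibility metrics and Venice grades."""

    record: ComparisonRecord
    credibility: CredibilityResult
    venice: VeniceGrade
    noteworthy: dict[float, bool]     # prior -> noteworthy flag
    credible_noteworthy: bool         # noteworthy at strictest prior AND Venice not Weak


@dataclass(frozen=True)
class ReappraisalReport:
    rows: tuple[ReappraisalRow, ...]
    prior_spec: PriorSpec
    venice_config: VeniceConfig
    metadata: dict


def _config_hash(prior_spec: PriorSpec, venice_config: VeniceConfig) -> str:
    blob = repr((prior_spec, venice_config)).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run(
    records: Sequence[ComparisonRecord],
    prior_spec: PriorSpec | None = None,
    venice_config: VeniceConfig | None = None,
) -> ReappraisalReport:
    """Assess every record: FPRP/BFDP grid, Venice grades, flags.

    A comparison is ``credible_noteworthy`` only when it is noteworthy
    at the strictest (smallest) prior *and* its Venice overall label is
    not Weak — the joint reading under which a statistically robust
    signal still fails if the cumulative evidence is biased.
    """
    if prior_spec is None:
        prior_spec = PriorSpec()
    if venice_config is None:
        venice_config = VeniceConfig()
    strict_prior = min(prior_spec.priors)
    rows = []
    for rec in records:
        try:
            cred = assess(rec.effect, prior_spec)
            grade = grade_evidence(
                total_n=rec.n_total,
                i2=rec.i2,
                egger_p=rec.egger_p.value,
                or_point=rec.effect.or_point,
                concern=rec.bias_concern,
                config=venice_config,
            )
        except ValueError as exc:
            raise ValueError(f"record {rec.key}: {exc}") from exc
        noteworthy = {pi: cred.noteworthy_at(pi) for pi in prior_spec.priors}
        rows.append(ReappraisalRow(
            record=rec,
            credibility=cred,
            venice=grade,
            noteworthy=noteworthy,
            credible_noteworthy=noteworthy[strict_prior] and grade.overall != "Weak",
        ))
    metadata = {
        "n_records": len(rows),
        "config_hash": _config_hash(prior_spec, venice_config),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return ReappraisalReport(rows=tuple(rows), prior_spec=prior_spec,
                             venice_config=venice_config, metadata=metadata)


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def report_frame(report: ReappraisalReport, ndigits: int | None = 3) -> pd.DataFrame:
    """Tabular view of a report; ``ndigits=None`` keeps full precision."""
    spec = report.prior_spec
    rows = []
    for row in report.rows:
        rec = row.record
        d = {
            "study": rec.study, "drug": rec.drug, "gene": rec.gene,
            "variant": rec.variant, "contrast": rec.contrast,
            "subgroup": rec.subgroup, "model": rec.pooling_model,
            "n_total": rec.n_total,
            "or_point": rec.effect.or_point,
            "ci_low": rec.effect.ci_low, "ci_high": rec.effect.ci_high,
            "p_recovered": rec.effect.alpha,
        }
        for t in spec.target_ors:
            for pi in spec.priors:
                d[f"fprp_or{t:g}_pi{pi:g}"] = row.credibility.fprp.fprp[(pi, t)]
        for pi in spec.priors:
            d[f"bfdp_pi{pi:g}"] = row.credibility.bfdp.bfdp[pi]
        d["venice_code"] = row.venice.code
        d["venice_label"] = row.venice.label
        for pi in spec.priors:
            d[f"noteworthy_pi{pi:g}"] = row.noteworthy[pi]
        d["credible_noteworthy"] = row.credible_noteworthy
        rows.append(d)
    df = pd.DataFrame(rows)
    if ndigits is not None:
        metric_cols = [c for c in df.columns
                       if c.startswith(("fprp_", "bfdp_", "p_recovered"))]
        df[metric_cols] = df[metric_cols].map(lambda v: _round_half_up(v, ndigits))
    return df


def write_report(report: ReappraisalReport, path: str | Path,
                 ndigits: int = 3) -> None:
    """Write the rounded TSV report and a full-precision JSON sidecar.

    Probabilities are rounded half-up to ``ndigits`` in the TSV (so a
    tiny FPRP prints as 0.000); the sidecar ``<path>.meta.json`` keeps
    full precision together with the run metadata.
    """
    path = Path(path)
    report_frame(report, ndigits=ndigits).to_csv(path, sep="\t", index=False)
    sidecar = {
        "metadata": report.metadata,
        "prior_spec": {
            "priors": list(report.prior_spec.priors),
            "target_ors": list(report.prior_spec.target_ors),
            "bfdp_prior_or975": report.prior_spec.bfdp_prior_or975,
            "fprp_threshold": report.prior_spec.fprp_threshold,
            "bfdp_threshold": report.prior_spec.bfdp_threshold,
            "se_convention": report.prior_spec.se_convention,
            "fprp_rule": report.prior_spec.fprp_rule,
        },
        "rows": report_frame(report, ndigits=None).to_dict(orient="records"),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))
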