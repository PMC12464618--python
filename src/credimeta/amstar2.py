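"""AMSTAR-2 appraisal of systematic reviews.

Derives the overall confidence rating (High / Moderate / Low /
Critically low) from the 16 item responses (Y / PY / N) of the AMSTAR-2
checklist.  A response of N on one of the seven critical domains
(items 2, 4, 7, 9, 11, 13 and 15 by default) is a critical flaw; PY is
treated as partial adherence — a non-critical weakness — unless
explicitly configured as a flaw for particular items.

Rating rule: more than one critical flaw -> Critically low; exactly
one -> Low; no critical flaw but more than one non-critical weakness ->
Moderate; otherwise High.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CRITICAL_ITEMS", "RATINGS", "AmstarRecord", "rate", "summarize",
    "read_amstar_tsv", "write_amstar_tsv",
]

CRITICAL_ITEMS: frozenset[int] = frozenset({2, 4, 7, 9, 11, 13, 15})
RATINGS = ("High", "Moderate", "Low", "Critically low")
_VALID = {"Y", "PY", "N"}


def rate(
    responses: Sequence[str],
    critical_items: Iterable[int] = CRITICAL_ITEMS,
    py_is_flaw_on: Iterable[int] = (),
) -> str:
    """Overall confidence from 16 item responses.

    ``py_is_flaw_on`` lists item numbers (1-based) on which a PY answer
    should count as a flaw rather than partial adherence.
    """
    responses = [str(r).strip().upper() for r in responses]
    if len(responses) != 16:
        raise ValueError(f"expected 16 item responses, got {len(responses)}")
    bad = [r for r in responses if r not in _VALID]
    if bad:
        raise ValueError(f"invalid responses {bad}; expected Y, PY or N")
    critical = set(critical_items)
    py_flaw = set(py_is_flaw_on)

    critical_flaws = 0
    weaknesses = 0
    for item, resp in enumerate(responses, start=1):
        is_flaw = resp == "N" or (resp == "PY" and item in py_flaw)
        if item in critical:
            if is_flaw:
                critical_flaws += 1
        elif is_flaw:
            weaknesses += 1
        if resp == "PY" and not is_flaw:
            weaknesses += 1

    if critical_flaws > 1:
        return "Critically low"
    if critical_flaws == 1:
        return "Low"
    if weaknesses > 1:
        return "Moderate"
    return "High"


@dataclass(frozen=True)
class AmstarRecord:
    """One review's 16 responses and its derived overall confidence."""

    study: str
    responses: tuple[str, ...]
    critical_items: frozenset[int] = CRITICAL_ITEMS
    overall: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses",
                           tuple(str(r).strip().upper() for r in self.responses))
        object.__setattr__(self, "overall",
                           rate(self.responses, self.critical_items))


def summarize(records: Sequence[AmstarRecord]) -> tuple[pd.DataFrame, pd.Series]:
    """Per-item compliance and the overall rating distribution.

    Returns ``(item_table, overall_pct)``: ``item_table`` has one row
    per item Q1..Q16 with the percentage of Y, PY and N responses;
    ``overall_pct`` the percentage of reviews in each rating category.
    """
    if not records:
        raise ValueError("no records to summarize")
    resp = pd.DataFrame([r.responses for r in records],
                        index=[r.study for r in records],
                        columns=[f"Q{i}" for i in range(1, 17)])
    n = len(records)
    item_table = pd.DataFrame(
        {cat: (resp == cat).sum(axis=0) * 100.0 / n for cat in ("Y", "PY", "N")}
    ).T[resp.columns].T
    overall = pd.Series([r.overall for r in records])
    overall_pct = (overall.value_counts() * 100.0 / n).reindex(RATINGS, fill_value=0.0)
    return item_table, overall_pct


def read_amstar_tsv(path: str | Path) -> list[AmstarRecord]:
    """Read an item-response table: one row per review, columns
    ``study`` and ``Q1`` .. ``Q16``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["study"] + [f"Q{i}" for i in range(1, 17)]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        AmstarRecord(study=row["study"],
                     responses=tuple(row[f"Q{i}"] for i in range(1, 17)))
        for _, row in df.iterrows()
    ]


def write_amstar_tsv(records: Sequence[AmstarRecord], path: str | Path) -> None:
    """Write reviews with their derived overall rating."""
    rows = [
        {"study": r.study,
         **{f"Q{i}": resp for i, resp in enumerate(r.responses, start=1)},
         "overall": r.overall}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
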