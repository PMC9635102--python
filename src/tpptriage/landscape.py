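"""Descriptive pipeline-landscape summaries and preclinical taxonomy.

Counts and percentages by activity, development phase, product type and
archetype over a registry, plus the preclinical-only breakdown by medicine
subclass and indication membership. Percentages are rounded half-up to one
decimal place, matching the conventional presentation style (e.g. 43.1%,
17.5%). Dual-indication candidates are counted once in unique-candidate
denominators and once per indication in membership tallies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyInputError, ScopeError
from .registry import (
    Activity,
    Archetype,
    Indication,
    Phase,
    PreclinicalSubclass,
    ProductType,
    Registry,
    classify_activity,
)

__all__ = [
    "CategoryCount",
    "PipelineSummary",
    "PreclinicalTaxonomy",
    "categorize_preclinical",
    "round_percent",
    "summarize_pipeline",
    "summary_to_json",
    "summary_to_tidy_csv",
    "unique_candidate_count",
]


def round_percent(count: int, denominator: int) -> float:
    """Percentage of ``denominator``, rounded half-up to one decimal."""
    if denominator == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategoryCount:
    count: int
    percent: float


@dataclass(frozen=True)
class PipelineSummary:
    """Counts and percentages by activity, phase, product type, archetype."""

    denominator: int
    breakdowns: Mapping[str, Mapping[str, CategoryCount]]


@dataclass(frozen=True)
class PreclinicalTaxonomy:
    """Preclinical accounting over unique candidates.

    Dual-indication candidates appear once in ``subclass_counts``,
    ``archetype_counts`` and the denominator, and once in the ``both``
    bucket of ``indication_membership``.
    """

    denominator: int
    subclass_counts: Mapping[str, int]
    indication_membership: Mapping[str, int]  # prevention_only / treatment_only / both
    archetype_counts: Mapping[str, int]


_AXES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("activity", tuple(a.value for a in Activity)),
    ("phase", tuple(p.value for p in Phase)),
    ("product_type", tuple(t.value for t in ProductType)),
    ("archetype", tuple(a.value for a in Archetype)),
)


def summarize_pipeline(registry: Registry, reference_year: int) -> PipelineSummary:
    """Count-and-percentage breakdown of a registry along the four axes."""
    if not registry:
        raise EmptyInputError("cannot summarize an empty registry")
    raw: dict[str, dict[str, int]] = {
        axis: {cat: 0 for cat in cats} for axis, cats in _AXES
    }
    for cand in registry:
        raw["activity"][classify_activity(cand, reference_year).value] += 1
        raw["phase"][cand.phase.value] += 1
        raw["product_type"][cand.product_type.value] += 1
        raw["archetype"][cand.archetype.value] += 1
    n = len(registry)
    breakdowns = {
        axis: {
            cat: CategoryCount(count, round_percent(count, n))
            for cat, count in counts.items()
        }
        for axis, counts in raw.items()
    }
    return PipelineSummary(n, breakdowns)


def categorize_preclinical(registry: Registry) -> PreclinicalTaxonomy:
    """Taxonomy of a preclinical registry by subclass, indication, archetype.

    The registry must contain preclinical candidates only; any other row
    raises :class:`ScopeError`.
    """
    for cand in registry:
        if cand.phase is not Phase.PRECLINICAL:
            raise ScopeError(
                f"{cand.candidate_id}: phase {cand.phase.value} candidate in a "
                "preclinical-only taxonomy"
            )
    subclass = {sc.value: 0 for sc in PreclinicalSubclass}
    membership = {"prevention_only": 0, "treatment_only": 0, "both": 0}
    archetype = {a.value: 0 for a in Archetype}
    for cand in registry:
        subclass[cand.preclinical_subclass.value] += 1  # type: ignore[union-attr]
        archetype[cand.archetype.value] += 1
        if cand.indications == {Indication.PREVENTION, Indication.TREATMENT}:
            membership["both"] += 1
        elif Indication.PREVENTION in cand.indications:
            membership["prevention_only"] += 1
        else:
            membership["treatment_only"] += 1
    return PreclinicalTaxonomy(len(registry), subclass, membership, archetype)


def unique_candidate_count(name_lists: Iterable[Iterable[str]]) -> int:
    """Number of unique candidate names across per-indication lists.

    Names are compared case-insensitively after whitespace trimming; no
    fuzzy matching (distinct-but-similar names stay distinct).
    """
    return len({name.strip().casefold() for lst in name_lists for name in lst})


def summary_to_json(summary: PipelineSummary, path: str | Path | None = None) -> str:
    payload = {
        "denominator": summary.denominator,
        "breakdowns": {
            axis: {
                cat: {"count": cc.count, "percent": cc.percent}
                for cat, cc in counts.items()
            }
            for axis, counts in summary.breakdowns.items()
        },
    }
    text = json.dumps(payload, indent=2) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def summary_to_tidy_csv(summary: PipelineSummary, path: str | Path) -> None:
    rows = [
        {"axis": axis, "category": cat, "count": cc.count, "percent": cc.percent}
        for axis, counts in summary.breakdowns.items()
        for cat, cc in counts.items()
    ]
    pd.DataFrame(rows, columns=["axis", "category", "count", "percent"]).to_csv(
        path, index=False
    )
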