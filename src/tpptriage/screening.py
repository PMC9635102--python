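"""Eligibility screening: partition a registry by six exclusion rules.

Candidates are excluded when they are (1) approved and already on the
market for the indication; (2) recommended by WHO or otherwise in routine
clinical use; (3) already recommended or widely used for a subgroup only;
(4) inactive following negative trial outcomes; (5) targeted at one symptom
rather than the underlying pathology; or (6) indicated as inferior to
current treatments. These are curator judgments carried as boolean registry
attributes, not literature lookups.

A candidate triggering several rules is counted once, under the
lowest-numbered rule; all triggered rules are retained in a secondary list
so flowchart accounting stays single-counted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

from .registry import Candidate, Registry

__all__ = [
    "EXCLUSION_RULES",
    "RULESET_VERSION",
    "Exclusion",
    "ScreeningResult",
    "apply_exclusions",
    "screening_flowchart",
    "write_flowchart_json",
    "write_screening_csv",
]

RULESET_VERSION = "exclusion-rules-2021"

#: (rule code, candidate attribute, short description), in precedence order.
EXCLUSION_RULES: tuple[tuple[int, str, str], ...] = (
    (1, "approved_for_indication", "approved and already available on the market"),
    (2, "recommended_or_routine_use", "recommended by WHO or in routine clinical use"),
    (3, "recommended_for_subgroup_only", "already recommended or widely used for a subgroup"),
    (4, "inactive_negative_outcome", "inactive due to negative trial outcomes"),
    (5, "targets_symptom_only", "targets one symptom rather than the underlying pathology"),
    (6, "inferior_to_current", "indicated as inferior to current treatments"),
)


@dataclass(frozen=True)
class Exclusion:
    candidate: Candidate
    reason_code: int  # lowest-numbered triggered rule
    all_reasons: tuple[int, ...]  # every triggered rule, ascending


@dataclass(frozen=True)
class ScreeningResult:
    retained: tuple[Candidate, ...]
    excluded: tuple[Exclusion, ...]
    ruleset_version: str = RULESET_VERSION


def _triggered_rules(candidate: Candidate) -> tuple[int, ...]:
    return tuple(code for code, attr, _ in EXCLUSION_RULES if getattr(candidate, attr))


def apply_exclusions(registry: Registry) -> ScreeningResult:
    """Partition a registry into retained and excluded candidates.

    A candidate is excluded iff any of the six flags is true; the primary
    reason code is the lowest-numbered triggered rule. Registry order is
    preserved on both sides of the partition.
    """
    retained: list[Candidate] = []
    excluded: list[Exclusion] = []
    for cand in registry:
        rules = _triggered_rules(cand)
        if rules:
            excluded.append(Exclusion(cand, rules[0], rules))
        else:
            retained.append(cand)
    return ScreeningResult(tuple(retained), tuple(excluded))


def screening_flowchart(result: ScreeningResult) -> dict:
    """Flowchart-style count table: input, per-rule exclusions, retained.

    Each excluded candidate is counted once, under its primary reason, so
    ``retained + sum(excluded_by_reason) == input``.
    """
    by_reason = {code: 0 for code, _, _ in EXCLUSION_RULES}
    for exc in result.excluded:
        by_reason[exc.reason_code] += 1
    return {
        "input": len(result.retained) + len(result.excluded),
        "excluded_total": len(result.excluded),
        "excluded_by_reason": by_reason,
        "retained": len(result.retained),
        "ruleset_version": result.ruleset_version,
    }


def write_screening_csv(result: ScreeningResult, path: str | Path) -> None:
    """Per-candidate screening report (candidate_id, decision, reasons)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["candidate_id", "decision", "primary_reason", "all_reasons"])
        for cand in result.retained:
            writer.writerow([cand.candidate_id, "retained", "", ""])
        for exc in result.excluded:
            writer.writerow(
                [
                    exc.candidate.candidate_id,
                    "excluded",
                    exc.reason_code,
                    ";".join(str(r) for r in exc.all_reasons),
                ]
            )


def write_flowchart_json(result: ScreeningResult, path: str | Path) -> None:
    counts = screening_flowchart(result)
    counts["excluded_by_reason"] = {str(k): v for k, v in counts["excluded_by_reason"].items()}
    Path(path).write_text(json.dumps(counts, indent=2) + "\n", encoding="utf-8")
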