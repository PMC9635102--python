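"""Candidate registry data model, validation and CSV/JSON I/O.

A registry is an ordered list of :class:`Candidate` rows describing drug,
biological and dietary-supplement candidates for the prevention and/or
treatment of a condition, at any stage from preclinical to phase IV.
Reviewer assessments record, per candidate-indication pair and reviewer,
the level at which the candidate matches each target-product-profile (TPP)
criterion.

CSV dialect: UTF-8, comma-separated, one header row; multi-valued fields
(indications, trial_settings) are semicolon-joined; absent values are the
empty string (``null`` in JSON); booleans are ``true``/``false`` (empty
means false); the tri-state cold-chain field uses explicit tokens
``yes``/``no``/``unknown``. Loading rejects, rather than coerces, any token
outside a field's vocabulary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import (
    DuplicateIdError,
    ReferentialError,
    SchemaError,
    ValueTokenError,
)

__all__ = [
    "Activity",
    "Archetype",
    "Candidate",
    "ColdChain",
    "Indication",
    "MatchLevel",
    "INFORMATIVE_LEVELS",
    "Phase",
    "PHASE_ORDER",
    "CLINICAL_PHASES",
    "PreclinicalSubclass",
    "ProductType",
    "Registry",
    "ReviewerAssessment",
    "ReviewerId",
    "TrialSetting",
    "ValidationDefect",
    "ValidationReport",
    "classify_activity",
    "load_assessments",
    "load_registry",
    "validate_assessments",
    "write_assessments",
    "write_registry",
]


class Indication(str, Enum):
    PREVENTION = "prevention"
    TREATMENT = "treatment"


class ProductType(str, Enum):
    DRUG = "drug"
    DIETARY = "dietary"
    BIOLOGICAL = "biological"


class Archetype(str, Enum):
    NEW = "new"
    REPURPOSED = "repurposed"


class Phase(str, Enum):
    PRECLINICAL = "preclinical"
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


#: Development-stage ordering, earliest first.
PHASE_ORDER: dict[Phase, int] = {
    Phase.PRECLINICAL: 0,
    Phase.I: 1,
    Phase.II: 2,
    Phase.III: 3,
    Phase.IV: 4,
}

#: Phases whose candidates have entered human trials.
CLINICAL_PHASES: tuple[Phase, ...] = (Phase.I, Phase.II, Phase.III, Phase.IV)


class TrialSetting(str, Enum):
    HIC = "HIC"
    LMIC = "LMIC"


class ColdChain(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class PreclinicalSubclass(str, Enum):
    AMINO_ACID_PEPTIDE = "amino acid-peptide"
    ANTIOXIDANT = "antioxidant"
    STATIN = "enzyme inhibitors (statins)"
    H2S_DONOR = "hydrogen sulphide donors"
    MACRONUTRIENT = "macronutrients"
    POLYPHENOL = "polyphenol"
    NUCLEIC_ACID = "DNA/siRNA/mRNA"
    SMALL_MOLECULE = "small molecule"
    CELL_THERAPY = "cell therapy"
    HERBAL = "herbal"
    VASCULAR = "vascular agents"


class MatchLevel(str, Enum):
    """Degree to which a candidate satisfies one TPP criterion.

    The four informative levels carry a total order
    ``NOT_MET < PARTIALLY_MET < MET_MINIMUM < MET_PREFERRED``; ``UNKNOWN``
    ("not yet known", grey in the traffic-light figures) sits outside it.
    """

    MET_PREFERRED = "met_preferred"
    MET_MINIMUM = "met_minimum"
    PARTIALLY_MET = "partially_met"
    NOT_MET = "not_met"
    UNKNOWN = "unknown"

    @property
    def is_informative(self) -> bool:
        return self is not MatchLevel.UNKNOWN


#: The informative levels in ascending order of match quality.
INFORMATIVE_LEVELS: tuple[MatchLevel, ...] = (
    MatchLevel.NOT_MET,
    MatchLevel.PARTIALLY_MET,
    MatchLevel.MET_MINIMUM,
    MatchLevel.MET_PREFERRED,
)


class Activity(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"


class ReviewerId(str, Enum):
    A = "A"
    B = "B"
    ADJUDICATOR = "adjudicator"


class Candidate(BaseModel):
    """One registry row: identity, classification and screening attributes.

    The six boolean exclusion attributes are curator judgments recorded in
    the registry, not computed from literature.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    candidate_id: str
    name: str
    indications: frozenset[Indication]
    product_type: ProductType
    archetype: Archetype
    phase: Phase
    last_activity_year: Optional[int] = None
    approved_for_indication: bool = False
    recommended_or_routine_use: bool = False
    recommended_for_subgroup_only: bool = False
    inactive_negative_outcome: bool = False
    targets_symptom_only: bool = False
    inferior_to_current: bool = False
    trial_settings: Optional[frozenset[TrialSetting]] = None
    requires_cold_chain: ColdChain = ColdChain.UNKNOWN
    on_who_eml: bool = False
    preclinical_subclass: Optional[PreclinicalSubclass] = None
    evidence_concerns: str = ""

    @field_validator("candidate_id", "name")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("must be a non-empty string")
        return v

    @field_validator("indications")
    @classmethod
    def _indications_non_empty(cls, v: frozenset[Indication]) -> frozenset[Indication]:
        if not v:
            raise ValueError("indications must be non-empty")
        return v

    @model_validator(mode="after")
    def _subclass_iff_preclinical(self) -> "Candidate":
        if (self.phase is Phase.PRECLINICAL) != (self.preclinical_subclass is not None):
            raise ValueError(
                "preclinical_subclass must be present if and only if phase is preclinical"
            )
        return self

    @property
    def is_clinical(self) -> bool:
        return self.phase in CLINICAL_PHASES


Registry = list[Candidate]


class ReviewerAssessment(BaseModel):
    """One reviewer's TPP match levels for one candidate-indication pair."""

    model_config = ConfigDict(frozen=True)

    candidate_id: str
    indication: Indication
    reviewer_id: ReviewerId
    levels: Mapping[str, MatchLevel]


def classify_activity(candidate: Candidate, reference_year: int) -> Activity:
    """Classify R&D activity: active iff published activity within the last
    three calendar years (inclusive boundary), inactive when no activity
    year is recorded."""
    year = candidate.last_activity_year
    if year is None:
        return Activity.INACTIVE
    return Activity.ACTIVE if year >= reference_year - 3 else Activity.INACTIVE


# --------------------------------------------------------------------------
# Registry I/O

REGISTRY_COLUMNS: tuple[str, ...] = (
    "candidate_id",
    "name",
    "indications",
    "product_type",
    "archetype",
    "phase",
    "last_activity_year",
    "approved_for_indication",
    "recommended_or_routine_use",
    "recommended_for_subgroup_only",
    "inactive_negative_outcome",
    "targets_symptom_only",
    "inferior_to_current",
    "trial_settings",
    "requires_cold_chain",
    "on_who_eml",
    "preclinical_subclass",
    "evidence_concerns",
)

_BOOL_COLUMNS = (
    "approved_for_indication",
    "recommended_or_routine_use",
    "recommended_for_subgroup_only",
    "inactive_negative_outcome",
    "targets_symptom_only",
    "inferior_to_current",
    "on_who_eml",
)


def _parse_bool(token: str, column: str, row: int) -> bool:
    token = token.strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no", ""):
        return False
    raise ValueTokenError(f"row {row}: column {column!r}: invalid boolean token {token!r}")


def _row_to_candidate(raw: Mapping[str, str], row: int) -> Candidate:
    data: dict[str, object] = {}
    data["candidate_id"] = raw["candidate_id"].strip()
    data["name"] = raw["name"].strip()
    data["indications"] = frozenset(
        tok.strip() for tok in raw["indications"].split(";") if tok.strip()
    )
    data["product_type"] = raw["product_type"].strip()
    data["archetype"] = raw["archetype"].strip()
    data["phase"] = raw["phase"].strip()
    year = raw["last_activity_year"].strip()
    data["last_activity_year"] = int(year) if year else None
    for col in _BOOL_COLUMNS:
        data[col] = _parse_bool(raw[col], col, row)
    settings = raw["trial_settings"].strip()
    data["trial_settings"] = (
        frozenset(tok.strip() for tok in settings.split(";") if tok.strip())
        if settings
        else None
    )
    cold = raw["requires_cold_chain"].strip()
    if cold not in (c.value for c in ColdChain):
        raise ValueTokenError(
            f"row {row}: column 'requires_cold_chain': invalid token {cold!r} "
            "(expected yes/no/unknown)"
        )
    data["requires_cold_chain"] = cold
    sub = raw["preclinical_subclass"].strip()
    data["preclinical_subclass"] = sub if sub else None
    data["evidence_concerns"] = raw["evidence_concerns"].strip()
    try:
        return Candidate(**data)  # type: ignore[arg-type]
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<row>"
        raise ValueTokenError(f"row {row}: field {loc!r}: {first['msg']}") from exc


def _check_header(found: Sequence[str] | None, where: str) -> None:
    if found is None:
        raise SchemaError(f"{where}: empty file, no header row")
    missing = [c for c in REGISTRY_COLUMNS if c not in found]
    extra = [c for c in found if c not in REGISTRY_COLUMNS]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns {missing}")
        if extra:
            parts.append(f"unknown columns {extra}")
        raise SchemaError(f"{where}: {'; '.join(parts)}")


def _check_unique_ids(registry: Registry) -> None:
    seen: set[str] = set()
    for cand in registry:
        if cand.candidate_id in seen:
            raise DuplicateIdError(f"duplicate candidate_id {cand.candidate_id!r}")
        seen.add(cand.candidate_id)


def load_registry(path: str | Path, format: str | None = None) -> Registry:
    """Load and validate a candidate registry from CSV or JSON.

    The format is inferred from the file suffix when not given. Input order
    is preserved; invalid enum tokens raise rather than coerce.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            _check_header(reader.fieldnames, str(path))
            registry = [_row_to_candidate(raw, i) for i, raw in enumerate(reader, start=2)]
    elif fmt == "json":
        with path.open(encoding="utf-8") as fh:
            records = json.load(fh)
        if not isinstance(records, list):
            raise SchemaError(f"{path}: JSON registry must be an array of objects")
        registry = []
        for i, rec in enumerate(records):
            keys = set(rec)
            missing = set(REGISTRY_COLUMNS) - keys
            extra = keys - set(REGISTRY_COLUMNS)
            if missing or extra:
                raise SchemaError(
                    f"{path} record {i}: missing keys {sorted(missing)}; unknown keys {sorted(extra)}"
                )
            try:
                registry.append(
                    Candidate(
                        **{
                            **rec,
                            "indications": frozenset(rec["indications"] or []),
                            "trial_settings": (
                                frozenset(rec["trial_settings"])
                                if rec["trial_settings"] is not None
                                else None
                            ),
                            "evidence_concerns": rec["evidence_concerns"] or "",
                        }
                    )
                )
            except ValidationError as exc:
                first = exc.errors()[0]
                loc = ".".join(str(p) for p in first["loc"]) or "<record>"
                raise ValueTokenError(f"record {i}: field {loc!r}: {first['msg']}") from exc
    else:
        raise ValueError(f"unsupported registry format {fmt!r}")
    _check_unique_ids(registry)
    return registry


def _candidate_to_row(cand: Candidate) -> dict[str, str]:
    return {
        "candidate_id": cand.candidate_id,
        "name": cand.name,
        "indications": ";".join(sorted(i.value for i in cand.indications)),
        "product_type": cand.product_type.value,
        "archetype": cand.archetype.value,
        "phase": cand.phase.value,
        "last_activity_year": "" if cand.last_activity_year is None else str(cand.last_activity_year),
        **{col: ("true" if getattr(cand, col) else "false") for col in _BOOL_COLUMNS},
        "trial_settings": (
            "" if cand.trial_settings is None else ";".join(sorted(s.value for s in cand.trial_settings))
        ),
        "requires_cold_chain": cand.requires_cold_chain.value,
        "preclinical_subclass": (
            "" if cand.preclinical_subclass is None else cand.preclinical_subclass.value
        ),
        "evidence_concerns": cand.evidence_concerns,
    }


def write_registry(registry: Registry, path: str | Path, format: str | None = None) -> None:
    """Serialize a registry to CSV or JSON (see module docstring for dialect)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=REGISTRY_COLUMNS)
            writer.writeheader()
            for cand in registry:
                writer.writerow(_candidate_to_row(cand))
    elif fmt == "json":
        records = []
        for cand in registry:
            rec = _candidate_to_row(cand)
            records.append(
                {
                    **rec,
                    "indications": sorted(i.value for i in cand.indications),
                    "last_activity_year": cand.last_activity_year,
                    **{col: getattr(cand, col) for col in _BOOL_COLUMNS},
                    "trial_settings": (
                        None
                        if cand.trial_settings is None
                        else sorted(s.value for s in cand.trial_settings)
                    ),
                    "preclinical_subclass": (
                        None if cand.preclinical_subclass is None else cand.preclinical_subclass.value
                    ),
                }
            )
        path.write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unsupported registry format {fmt!r}")


# --------------------------------------------------------------------------
# Assessment I/O (long format: one row per candidate/indication/reviewer/criterion)

ASSESSMENT_COLUMNS: tuple[str, ...] = (
    "candidate_id",
    "indication",
    "reviewer_id",
    "criterion_id",
    "level",
)


def load_assessments(path: str | Path) -> list[ReviewerAssessment]:
    """Load long-format reviewer assessments from CSV.

    Rows sharing (candidate, indication, reviewer) are grouped into one
    :class:`ReviewerAssessment`; a repeated criterion within a group is an
    error.
    """
    path = Path(path)
    grouped: dict[tuple[str, str, str], dict[str, MatchLevel]] = {}
    order: list[tuple[str, str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != set(ASSESSMENT_COLUMNS):
            raise SchemaError(
                f"{path}: assessment header must be exactly {list(ASSESSMENT_COLUMNS)}"
            )
        for i, raw in enumerate(reader, start=2):
            key = (
                raw["candidate_id"].strip(),
                raw["indication"].strip(),
                raw["reviewer_id"].strip(),
            )
            level = raw["level"].strip()
            if level not in (lv.value for lv in MatchLevel):
                raise ValueTokenError(f"row {i}: invalid match level token {level!r}")
            crit = raw["criterion_id"].strip()
            if key not in grouped:
                order.append(key)
            bucket = grouped.setdefault(key, {})
            if crit in bucket:
                raise ValueTokenError(
                    f"row {i}: duplicate criterion {crit!r} for {key}"
                )
            bucket[crit] = MatchLevel(level)
    out: list[ReviewerAssessment] = []
    for key in order:
        cid, ind, rev = key
        try:
            out.append(
                ReviewerAssessment(
                    candidate_id=cid,
                    indication=ind,  # type: ignore[arg-type]
                    reviewer_id=rev,  # type: ignore[arg-type]
                    levels=grouped[key],
                )
            )
        except ValidationError as exc:
            first = exc.errors()[0]
            raise ValueTokenError(f"assessment {key}: {first['msg']}") from exc
    return out


def write_assessments(assessments: Iterable[ReviewerAssessment], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=ASSESSMENT_COLUMNS)
        writer.writeheader()
        for rec in assessments:
            for crit, level in rec.levels.items():
                writer.writerow(
                    {
                        "candidate_id": rec.candidate_id,
                        "indication": rec.indication.value,
                        "reviewer_id": rec.reviewer_id.value,
                        "criterion_id": crit,
                        "level": level.value,
                    }
                )


# --------------------------------------------------------------------------
# Assessment validation


@dataclass(frozen=True)
class ValidationDefect:
    candidate_id: str
    indication: str
    kind: str  # missing_reviewer | missing_criterion | unknown_criterion | duplicate_record | foreign_indication
    detail: str


@dataclass
class ValidationReport:
    """Coverage report of reviewer assessments against a registry.

    ``defects`` lists problems within the assessed pairs; ``unassessed``
    lists clinical candidate-indication pairs with no assessment at all
    (informational — screening may exclude them before ranking).
    """

    defects: list[ValidationDefect] = field(default_factory=list)
    unassessed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.defects


def validate_assessments(
    registry: Registry,
    assessments: Sequence[ReviewerAssessment],
    criteria: Sequence[str],
) -> ValidationReport:
    """Report, per assessed candidate-indication pair, which reviewers are
    present and which criteria are missing. Never mutates its inputs.

    Raises :class:`ReferentialError` for an assessment whose candidate_id is
    not in the registry.
    """
    by_id = {c.candidate_id: c for c in registry}
    report = ValidationReport()
    pairs: dict[tuple[str, str], dict[ReviewerId, ReviewerAssessment]] = {}
    crit_set = set(criteria)
    for rec in assessments:
        cand = by_id.get(rec.candidate_id)
        if cand is None:
            raise ReferentialError(
                f"assessment references unknown candidate_id {rec.candidate_id!r}"
            )
        key = (rec.candidate_id, rec.indication.value)
        bucket = pairs.setdefault(key, {})
        if rec.reviewer_id in bucket:
            report.defects.append(
                ValidationDefect(*key, "duplicate_record", f"reviewer {rec.reviewer_id.value}")
            )
        bucket[rec.reviewer_id] = rec
        if rec.indication not in cand.indications:
            report.defects.append(
                ValidationDefect(
                    *key,
                    "foreign_indication",
                    f"candidate is not registered for {rec.indication.value}",
                )
            )
        for crit in rec.levels:
            if crit not in crit_set:
                report.defects.append(
                    ValidationDefect(
                        *key, "unknown_criterion", f"{rec.reviewer_id.value}: {crit}"
                    )
                )
    for (cid, ind), bucket in pairs.items():
        for reviewer in (ReviewerId.A, ReviewerId.B):
            rec = bucket.get(reviewer)
            if rec is None:
                report.defects.append(
                    ValidationDefect(cid, ind, "missing_reviewer", reviewer.value)
                )
                continue
            for crit in criteria:
                if crit not in rec.levels:
                    report.defects.append(
                        ValidationDefect(cid, ind, "missing_criterion", f"{reviewer.value}: {crit}")
                    )
    assessed = set(pairs)
    for cand in registry:
        if not cand.is_clinical:
            continue
        for ind in sorted(i.value for i in cand.indications):
            if (cand.candidate_id, ind) not in assessed:
                report.unassessed.append((cand.candidate_id, ind))
    return report
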