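"""TPP match engine: reconciliation, weighted scoring and phase ranking.

Candidates in clinical development are assessed against nine critical
target-product-profile criteria — trial setting, efficacy, need for a
companion diagnostic, need for clinical monitoring, safety, mode of
administration, treatment adherence, stability (cold chain) and presence on
the WHO Essential Medicines List. Two reviewers assess each
candidate-indication pair independently; a third reviewer adjudicates
disagreements. Each reconciled level maps to a numeric score, criteria are
weighted (efficacy and safety above the rest), and the normalized score
``r = total / max_attainable`` is compared against per-phase cutoffs to
assign a high / medium / low potential rank. Preclinical candidates are
described, never ranked.

The numeric coding, weights and cutoffs are a replaceable configuration
(:class:`ScoringScheme`); the shipped default uses level scores 0/1/2/3
(UNKNOWN scoring 0 but tracked through the completeness fraction), weight 2
for efficacy and safety versus 1 elsewhere, and cutoffs high >= 0.60,
medium >= 0.40 at every phase. Both cutoff comparisons are inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import (
    ConfigError,
    CoverageError,
    MissingAssessmentError,
    NotRankableError,
    UnresolvedConflictError,
)
from .registry import (
    CLINICAL_PHASES,
    INFORMATIVE_LEVELS,
    Candidate,
    Indication,
    MatchLevel,
    Phase,
    Registry,
    ReviewerAssessment,
    ReviewerId,
)
from .screening import ScreeningResult, apply_exclusions

__all__ = [
    "CRITERION_IDS",
    "Criterion",
    "MatchProfile",
    "PhaseThresholds",
    "PipelineRun",
    "Rank",
    "RankedCandidate",
    "ScoreBreakdown",
    "ScoringScheme",
    "assign_rank",
    "default_scheme",
    "derive_categorical_levels",
    "load_scheme",
    "rank_registry",
    "reconcile",
    "score_profile",
    "write_ranked_csv",
]


class Rank(str, Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


class Criterion(BaseModel):
    model_config = ConfigDict(frozen=True)

    criterion_id: str
    display_name: str
    weight: float

    @field_validator("weight")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("criterion weight must be positive")
        return v


#: The nine default criteria, in presentation order.
CRITERION_IDS: tuple[str, ...] = (
    "setting",
    "efficacy",
    "companion_diagnostic",
    "clinical_monitoring",
    "safety",
    "mode_of_administration",
    "treatment_adherence",
    "stability",
    "who_eml",
)

_DEFAULT_CRITERIA: tuple[tuple[str, str, float], ...] = (
    ("setting", "Setting", 1.0),
    ("efficacy", "Efficacy", 2.0),
    ("companion_diagnostic", "Need for a companion diagnostic test", 1.0),
    ("clinical_monitoring", "Need for clinical monitoring", 1.0),
    ("safety", "Safety", 2.0),
    ("mode_of_administration", "Mode of administration", 1.0),
    ("treatment_adherence", "Treatment adherence", 1.0),
    ("stability", "Stability", 1.0),
    ("who_eml", "WHO Essential Medicines List", 1.0),
)

#: Criteria whose weight must strictly exceed every other criterion's weight.
_UPWEIGHTED = ("efficacy", "safety")


class PhaseThresholds(BaseModel):
    model_config = ConfigDict(frozen=True)

    high: float
    medium: float

    @model_validator(mode="after")
    def _ordered(self) -> "PhaseThresholds":
        if not (0.0 <= self.medium < self.high <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= medium < high <= 1")
        return self


class ScoringScheme(BaseModel):
    """Match-level score map, per-criterion weights and per-phase cutoffs."""

    model_config = ConfigDict(frozen=True)

    criteria: tuple[Criterion, ...]
    level_scores: Mapping[MatchLevel, float]
    thresholds: Mapping[Phase, PhaseThresholds]

    @model_validator(mode="after")
    def _validate(self) -> "ScoringScheme":
        ids = [c.criterion_id for c in self.criteria]
        if len(ids) != len(set(ids)):
            raise ValueError("criterion ids must be unique")
        if not self.criteria:
            raise ValueError("criterion set must be non-empty")
        missing = [lv.value for lv in MatchLevel if lv not in self.level_scores]
        if missing:
            raise ValueError(f"level_scores missing levels {missing}")
        scores = [self.level_scores[lv] for lv in INFORMATIVE_LEVELS]
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ValueError(
                "level_scores must be monotone over not_met < partially_met "
                "< met_minimum < met_preferred"
            )
        weights = {c.criterion_id: c.weight for c in self.criteria}
        up = [weights[c] for c in _UPWEIGHTED if c in weights]
        rest = [w for cid, w in weights.items() if cid not in _UPWEIGHTED]
        if len(up) == len(_UPWEIGHTED) and rest and min(up) <= max(rest):
            raise ValueError(
                "efficacy and safety must carry strictly greater weight than the other criteria"
            )
        missing_phases = [p.value for p in CLINICAL_PHASES if p not in self.thresholds]
        if missing_phases:
            raise ValueError(f"thresholds missing phases {missing_phases}")
        if Phase.PRECLINICAL in self.thresholds:
            raise ValueError("preclinical candidates are described, not ranked")
        return self

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.criterion_id for c in self.criteria)

    def weight(self, criterion_id: str) -> float:
        for c in self.criteria:
            if c.criterion_id == criterion_id:
                return c.weight
        raise KeyError(criterion_id)


def default_scheme() -> ScoringScheme:
    """The documented default scheme (see module docstring)."""
    return ScoringScheme(
        criteria=tuple(
            Criterion(criterion_id=cid, display_name=name, weight=w)
            for cid, name, w in _DEFAULT_CRITERIA
        ),
        level_scores={
            MatchLevel.NOT_MET: 0.0,
            MatchLevel.PARTIALLY_MET: 1.0,
            MatchLevel.MET_MINIMUM: 2.0,
            MatchLevel.MET_PREFERRED: 3.0,
            MatchLevel.UNKNOWN: 0.0,
        },
        thresholds={
            phase: PhaseThresholds(high=0.60, medium=0.40) for phase in CLINICAL_PHASES
        },
    )


def load_scheme(path: str | Path) -> ScoringScheme:
    """Load a scoring scheme from YAML or JSON with explicit error messages.

    Expected layout::

        criteria:            # ordered
          - {id: efficacy, name: Efficacy, weight: 2}
        level_scores:        # all five levels
          met_preferred: 3
          ...
        thresholds:          # phases I..IV, fractions of max attainable
          I: {high: 0.6, medium: 0.4}
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse scheme file: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: scheme file must hold a mapping")
    for key in ("criteria", "level_scores", "thresholds"):
        if key not in raw:
            raise ConfigError(f"{path}: scheme is missing section {key!r}")
    try:
        criteria = tuple(
            Criterion(
                criterion_id=c["id"],
                display_name=c.get("name", c["id"]),
                weight=float(c["weight"]),
            )
            for c in raw["criteria"]
        )
        return ScoringScheme(
            criteria=criteria,
            level_scores={MatchLevel(k): float(v) for k, v in raw["level_scores"].items()},
            thresholds={
                Phase(p): PhaseThresholds(**t) for p, t in raw["thresholds"].items()
            },
        )
    except (KeyError, TypeError, ValueError, ValidationError) as exc:
        raise ConfigError(f"{path}: invalid scheme: {exc}") from exc


# --------------------------------------------------------------------------
# Reconciliation


@dataclass(frozen=True)
class MatchProfile:
    """Reconciled match levels for one candidate-indication pair.

    ``provenance`` records, per criterion, how the level was determined:
    ``agreement``, ``adjudicated``, ``derived`` (from registry attributes)
    or ``unassessed`` (filled as UNKNOWN).
    """

    candidate_id: str
    indication: Indication
    levels: Mapping[str, MatchLevel]
    provenance: Mapping[str, str] = field(default_factory=dict)


def reconcile(
    a: ReviewerAssessment,
    b: ReviewerAssessment,
    adjudicator: Optional[ReviewerAssessment] = None,
    criteria: Sequence[str] = CRITERION_IDS,
) -> MatchProfile:
    """Merge two independent reviewer assessments, adjudicating disagreements.

    Per criterion: if both reviewers agree, their common level stands; if
    they differ (including when only one of them assessed it), the
    adjudicator's level is taken. A disagreement with no adjudicator level
    raises :class:`UnresolvedConflictError` naming the criterion. Criteria
    assessed by neither reviewer are omitted from the profile (gaps, to be
    filled downstream from registry attributes or as UNKNOWN).

    Symmetric in ``a`` and ``b``.
    """
    if (a.candidate_id, a.indication) != (b.candidate_id, b.indication):
        raise ValueError(
            "assessments must reference the same candidate-indication pair, got "
            f"{(a.candidate_id, a.indication.value)} vs {(b.candidate_id, b.indication.value)}"
        )
    levels: dict[str, MatchLevel] = {}
    provenance: dict[str, str] = {}
    for crit in criteria:
        la = a.levels.get(crit)
        lb = b.levels.get(crit)
        if la is None and lb is None:
            continue
        if la == lb:
            levels[crit] = la  # type: ignore[assignment]
            provenance[crit] = "agreement"
            continue
        adj_level = adjudicator.levels.get(crit) if adjudicator is not None else None
        if adj_level is None:
            raise UnresolvedConflictError(
                f"{a.candidate_id}/{a.indication.value}: reviewers disagree on "
                f"{crit!r} ({la and la.value} vs {lb and lb.value}) with no adjudicator level"
            )
        levels[crit] = adj_level
        provenance[crit] = "adjudicated"
    return MatchProfile(a.candidate_id, a.indication, levels, provenance)


def derive_categorical_levels(candidate: Candidate) -> dict[str, MatchLevel]:
    """Match levels derivable directly from registry attributes.

    Setting: trials in both HIC and LMIC meet the preferred criterion;
    HIC-only or LMIC-only partially meet it; no stated setting is unknown.
    Stability: no cold-chain requirement meets preferred, a cold-chain
    requirement fails, unsure is unknown. WHO EML: listed meets preferred,
    unlisted fails.
    """
    out: dict[str, MatchLevel] = {}
    settings = candidate.trial_settings
    if settings is None:
        out["setting"] = MatchLevel.UNKNOWN
    elif len(settings) == 2:
        out["setting"] = MatchLevel.MET_PREFERRED
    elif len(settings) == 1:
        out["setting"] = MatchLevel.PARTIALLY_MET
    else:
        out["setting"] = MatchLevel.UNKNOWN
    cold = candidate.requires_cold_chain
    out["stability"] = {
        "no": MatchLevel.MET_PREFERRED,
        "yes": MatchLevel.NOT_MET,
        "unknown": MatchLevel.UNKNOWN,
    }[cold.value]
    out["who_eml"] = MatchLevel.MET_PREFERRED if candidate.on_who_eml else MatchLevel.NOT_MET
    return out


# --------------------------------------------------------------------------
# Scoring and ranking


@dataclass(frozen=True)
class ScoreBreakdown:
    total_score: float
    max_attainable: float
    completeness: float  # fraction of criteria with informative levels


def score_profile(profile: MatchProfile, scheme: ScoringScheme) -> ScoreBreakdown:
    """Weighted sum of level scores over the configured criterion set.

    ``total = sum_c weight(c) * level_scores[level(c)]``; the maximum
    attainable is the same sum with every level at MET_PREFERRED.
    """
    top = scheme.level_scores[MatchLevel.MET_PREFERRED]
    total = 0.0
    max_attainable = 0.0
    informative = 0
    for crit in scheme.criteria:
        level = profile.levels.get(crit.criterion_id)
        if level is None:
            raise CoverageError(
                f"{profile.candidate_id}/{profile.indication.value}: profile does not "
                f"cover criterion {crit.criterion_id!r}"
            )
        total += crit.weight * scheme.level_scores[level]
        max_attainable += crit.weight * top
        if level.is_informative:
            informative += 1
    return ScoreBreakdown(total, max_attainable, informative / len(scheme.criteria))


def assign_rank(
    total_score: float,
    max_attainable: float,
    phase: Phase,
    scheme: ScoringScheme,
) -> Rank:
    """Rank by the normalized ratio against the phase's cutoffs.

    Both cutoff comparisons are inclusive (>=). Preclinical candidates raise
    :class:`NotRankableError`.
    """
    if phase is Phase.PRECLINICAL:
        raise NotRankableError("preclinical candidates are described, not ranked")
    if max_attainable <= 0:
        raise ValueError("max_attainable must be positive")
    r = total_score / max_attainable
    cut = scheme.thresholds[phase]
    if r >= cut.high:
        return Rank.HIGH
    if r >= cut.medium:
        return Rank.MEDIUM
    return Rank.LOW


@dataclass(frozen=True)
class RankedCandidate:
    candidate_id: str
    name: str
    indication: Indication
    phase: Phase
    total_score: float
    max_attainable: float
    completeness: float
    rank: Rank


@dataclass(frozen=True)
class PipelineRun:
    """Output of the end-to-end screen -> reconcile -> score -> rank flow."""

    screening: ScreeningResult
    ranked: tuple[RankedCandidate, ...]
    profiles: Mapping[tuple[str, str], MatchProfile]
    reference_year: int


def _final_profile(
    candidate: Candidate,
    reconciled: MatchProfile,
    criteria: Sequence[str],
) -> MatchProfile:
    """Fill reconciliation gaps from registry attributes, then as UNKNOWN.

    Reviewer-reconciled levels always win over derived ones (reviewers saw
    the trial evidence the registry attributes only summarize); a reconciled
    UNKNOWN is an explicit statement, not a gap.
    """
    derived = derive_categorical_levels(candidate)
    levels: dict[str, MatchLevel] = {}
    provenance: dict[str, str] = {}
    for crit in criteria:
        if crit in reconciled.levels:
            levels[crit] = reconciled.levels[crit]
            provenance[crit] = reconciled.provenance.get(crit, "agreement")
        elif crit in derived:
            levels[crit] = derived[crit]
            provenance[crit] = "derived"
        else:
            levels[crit] = MatchLevel.UNKNOWN
            provenance[crit] = "unassessed"
    return MatchProfile(reconciled.candidate_id, reconciled.indication, levels, provenance)


def rank_registry(
    registry: Registry,
    assessments: Sequence[ReviewerAssessment],
    scheme: ScoringScheme,
    reference_year: int,
) -> PipelineRun:
    """Run the full triage flow over a registry.

    Screening is applied first; every retained clinical candidate is then
    scored and ranked once per registered indication (a candidate under
    investigation for both prevention and treatment yields two ranked
    rows). Preclinical candidates pass through screening but are not
    ranked.
    """
    screening = apply_exclusions(registry)
    grouped: dict[tuple[str, Indication], dict[ReviewerId, ReviewerAssessment]] = {}
    for rec in assessments:
        grouped.setdefault((rec.candidate_id, rec.indication), {})[rec.reviewer_id] = rec
    ranked: list[RankedCandidate] = []
    profiles: dict[tuple[str, str], MatchProfile] = {}
    for cand in screening.retained:
        if not cand.is_clinical:
            continue
        for ind in sorted(cand.indications, key=lambda i: i.value):
            bucket = grouped.get((cand.candidate_id, ind), {})
            a = bucket.get(ReviewerId.A)
            b = bucket.get(ReviewerId.B)
            if a is None or b is None:
                missing = [r.value for r in (ReviewerId.A, ReviewerId.B) if r not in bucket]
                raise MissingAssessmentError(
                    f"{cand.candidate_id}/{ind.value}: no assessment from reviewer(s) "
                    f"{', '.join(missing)}"
                )
            try:
                reconciled = reconcile(
                    a, b, bucket.get(ReviewerId.ADJUDICATOR), scheme.criterion_ids
                )
            except UnresolvedConflictError as exc:
                raise UnresolvedConflictError(f"{cand.name}: {exc}") from exc
            profile = _final_profile(cand, reconciled, scheme.criterion_ids)
            breakdown = score_profile(profile, scheme)
            rank = assign_rank(breakdown.total_score, breakdown.max_attainable, cand.phase, scheme)
            profiles[(cand.candidate_id, ind.value)] = profile
            ranked.append(
                RankedCandidate(
                    candidate_id=cand.candidate_id,
                    name=cand.name,
                    indication=ind,
                    phase=cand.phase,
                    total_score=breakdown.total_score,
                    max_attainable=breakdown.max_attainable,
                    completeness=breakdown.completeness,
                    rank=rank,
                )
            )
    return PipelineRun(screening, tuple(ranked), profiles, reference_year)


def write_ranked_csv(run: PipelineRun, scheme: ScoringScheme, path: str | Path) -> None:
    """Ranked output table: identity, per-criterion levels, scores, rank."""
    header = (
        ["candidate_id", "name", "indication", "phase"]
        + list(scheme.criterion_ids)
        + ["total_score", "max_attainable", "completeness", "rank"]
    )
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rc in run.ranked:
            profile = run.profiles[(rc.candidate_id, rc.indication.value)]
            writer.writerow(
                [rc.candidate_id, rc.name, rc.indication.value, rc.phase.value]
                + [profile.levels[cid].value for cid in scheme.criterion_ids]
                + [repr(rc.total_score), repr(rc.max_attainable), repr(rc.completeness), rc.rank.value]
            )
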