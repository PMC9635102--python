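"""Seeded synthetic registries and reviewer assessments with planted truth.

The generator emulates the statistical shape of a curated R&D pipeline
registry: a mix of preclinical and phase I-IV candidates with configurable
marginal proportions of phase, product type, archetype, indication and
activity; planted exclusion-rule triggers; and, for every retained clinical
candidate-indication pair, a planted match profile whose normalized score
falls inside a planted rank band. Reviewer A reports the planted truth,
reviewer B deviates per criterion with a configurable probability (drawn
uniformly from the other four levels), and the adjudicator always reports
the truth — so reconciliation provably restores the planted profile.

All randomness flows through one numpy PCG64 generator seeded from the
config, so outputs are byte-identical across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import InfeasibleConfigError
from .registry import (
    Archetype,
    Candidate,
    ColdChain,
    Indication,
    MatchLevel,
    Phase,
    PreclinicalSubclass,
    ProductType,
    Registry,
    ReviewerAssessment,
    ReviewerId,
    TrialSetting,
    write_assessments,
    write_registry,
)
from .screening import EXCLUSION_RULES
from .tpp_engine import (
    MatchProfile,
    Rank,
    ScoringScheme,
    assign_rank,
    default_scheme,
    score_profile,
)

__all__ = [
    "GroundTruth",
    "PlantedCandidate",
    "SyntheticConfig",
    "SyntheticDataset",
    "empirical_mix_check",
    "generate",
    "write_dataset",
]

_REJECTION_CAP = 10_000

#: Levels a planted profile may use per criterion. The three categorical
#: criteria are restricted to the levels their registry attributes can
#: express, so the generated registry stays consistent with the truth.
_LEVEL_CHOICES: dict[str, tuple[MatchLevel, ...]] = {
    "setting": (MatchLevel.MET_PREFERRED, MatchLevel.PARTIALLY_MET),
    "stability": (MatchLevel.MET_PREFERRED, MatchLevel.NOT_MET),
    "who_eml": (MatchLevel.MET_PREFERRED, MatchLevel.NOT_MET),
}
_DEFAULT_CHOICES: tuple[MatchLevel, ...] = (
    MatchLevel.NOT_MET,
    MatchLevel.PARTIALLY_MET,
    MatchLevel.MET_MINIMUM,
    MatchLevel.MET_PREFERRED,
)


def _check_mix(v: Mapping, what: str) -> None:
    total = sum(v.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1 (got {total})")
    if any(p < 0 for p in v.values()):
        raise ValueError(f"{what} entries must be non-negative")


class SyntheticConfig(BaseModel):
    """Generator configuration; all probability vectors must sum to one."""

    model_config = ConfigDict(frozen=True)

    n_candidates: int = 200
    phase_mix: Mapping[Phase, float] = {
        Phase.PRECLINICAL: 0.43,
        Phase.I: 0.07,
        Phase.II: 0.21,
        Phase.III: 0.28,
        Phase.IV: 0.01,
    }
    product_type_mix: Mapping[ProductType, float] = {
        ProductType.DRUG: 0.59,
        ProductType.DIETARY: 0.25,
        ProductType.BIOLOGICAL: 0.16,
    }
    archetype_mix: Mapping[Archetype, float] = {
        Archetype.NEW: 0.25,
        Archetype.REPURPOSED: 0.75,
    }
    indication_mix: Mapping[str, float] = {
        "prevention": 0.45,
        "treatment": 0.45,
        "both": 0.10,
    }
    planted_rank_mix: Mapping[Rank, float] = {
        Rank.HIGH: 0.2,
        Rank.MEDIUM: 0.25,
        Rank.LOW: 0.55,
    }
    exclusion_trigger_rate: float = 0.08  # per rule, independently
    reviewer_disagreement_rate: float = 0.0  # per criterion
    unknown_rate: float = 0.1  # per criterion, before band placement
    active_rate: float = 0.6
    reference_year: int = 2021
    seed: int = 0

    @field_validator(
        "exclusion_trigger_rate", "reviewer_disagreement_rate", "unknown_rate", "active_rate"
    )
    @classmethod
    def _rate(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        return v

    @field_validator("n_candidates")
    @classmethod
    def _n(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_candidates must be >= 1")
        return v

    @model_validator(mode="after")
    def _mixes(self) -> "SyntheticConfig":
        _check_mix(self.phase_mix, "phase_mix")
        _check_mix(self.product_type_mix, "product_type_mix")
        _check_mix(self.archetype_mix, "archetype_mix")
        _check_mix(self.indication_mix, "indication_mix")
        _check_mix(self.planted_rank_mix, "planted_rank_mix")
        return self


@dataclass(frozen=True)
class PlantedCandidate:
    profile: MatchProfile
    rank: Rank


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth: per candidate-indication profile+rank, exclusion flags."""

    planted: Mapping[tuple[str, str], PlantedCandidate]
    exclusion_flags: Mapping[str, tuple[int, ...]]  # candidate_id -> triggered rules

    def to_json(self) -> str:
        payload = {
            "planted": {
                f"{cid}/{ind}": {
                    "rank": pc.rank.value,
                    "levels": {c: lv.value for c, lv in pc.profile.levels.items()},
                }
                for (cid, ind), pc in self.planted.items()
            },
            "exclusion_flags": {cid: list(rules) for cid, rules in self.exclusion_flags.items()},
        }
        return json.dumps(payload, indent=2) + "\n"


@dataclass(frozen=True)
class SyntheticDataset:
    registry: Registry
    assessments: tuple[ReviewerAssessment, ...]
    truth: GroundTruth
    config: SyntheticConfig


def _choice(rng: np.random.Generator, mix: Mapping) -> object:
    keys = list(mix.keys())
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _sample_profile_in_band(
    rng: np.random.Generator,
    rank: Rank,
    phase: Phase,
    scheme: ScoringScheme,
    unknown_rate: float,
    candidate_id: str,
    indication: Indication,
) -> MatchProfile:
    """Rejection-sample a profile whose normalized score lands in the band."""
    for _ in range(_REJECTION_CAP):
        levels: dict[str, MatchLevel] = {}
        for cid in scheme.criterion_ids:
            if rng.random() < unknown_rate:
                levels[cid] = MatchLevel.UNKNOWN
            else:
                choices = _LEVEL_CHOICES.get(cid, _DEFAULT_CHOICES)
                levels[cid] = choices[rng.integers(len(choices))]
        profile = MatchProfile(candidate_id, indication, levels)
        bd = score_profile(profile, scheme)
        if assign_rank(bd.total_score, bd.max_attainable, phase, scheme) is rank:
            return profile
    raise InfeasibleConfigError(
        f"could not place a profile in the {rank.value!r} band at phase "
        f"{phase.value} within {_REJECTION_CAP} draws; the cutoffs are too "
        "tight for the discrete score lattice"
    )


def _registry_attrs_from_profile(levels: Mapping[str, MatchLevel], rng: np.random.Generator) -> dict:
    """Registry attributes consistent with the planted categorical levels."""
    attrs: dict = {}
    setting = levels.get("setting", MatchLevel.UNKNOWN)
    if setting is MatchLevel.MET_PREFERRED:
        attrs["trial_settings"] = frozenset({TrialSetting.HIC, TrialSetting.LMIC})
    elif setting is MatchLevel.PARTIALLY_MET:
        attrs["trial_settings"] = frozenset(
            {TrialSetting.HIC if rng.random() < 0.5 else TrialSetting.LMIC}
        )
    else:
        attrs["trial_settings"] = None
    stability = levels.get("stability", MatchLevel.UNKNOWN)
    attrs["requires_cold_chain"] = {
        MatchLevel.MET_PREFERRED: ColdChain.NO,
        MatchLevel.NOT_MET: ColdChain.YES,
    }.get(stability, ColdChain.UNKNOWN)
    attrs["on_who_eml"] = levels.get("who_eml") is MatchLevel.MET_PREFERRED
    return attrs


def _perturb(
    truth: MatchLevel, rng: np.random.Generator, rate: float
) -> MatchLevel:
    if rng.random() >= rate:
        return truth
    others = [lv for lv in MatchLevel if lv is not truth]
    return others[rng.integers(len(others))]


def generate(config: SyntheticConfig, scheme: ScoringScheme | None = None) -> SyntheticDataset:
    """Generate a registry, reviewer assessments and the planted truth.

    Fully reproducible from ``config.seed``; reviewer A and the adjudicator
    always report the planted truth, reviewer B deviates per criterion with
    probability ``reviewer_disagreement_rate``.
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(config.seed)
    subclasses = list(PreclinicalSubclass)
    registry: list[Candidate] = []
    assessments: list[ReviewerAssessment] = []
    planted: dict[tuple[str, str], PlantedCandidate] = {}
    exclusion_flags: dict[str, tuple[int, ...]] = {}
    for i in range(config.n_candidates):
        cid = f"SYN{i:04d}"
        name = f"candidate-{i:04d}"
        phase: Phase = _choice(rng, config.phase_mix)  # type: ignore[assignment]
        product_type: ProductType = _choice(rng, config.product_type_mix)  # type: ignore[assignment]
        archetype: Archetype = _choice(rng, config.archetype_mix)  # type: ignore[assignment]
        ind_token = _choice(rng, config.indication_mix)
        indications = (
            frozenset({Indication.PREVENTION, Indication.TREATMENT})
            if ind_token == "both"
            else frozenset({Indication(ind_token)})
        )
        triggered = tuple(
            code
            for code, _, _ in EXCLUSION_RULES
            if rng.random() < config.exclusion_trigger_rate
        )
        exclusion_flags[cid] = triggered
        active = rng.random() < config.active_rate
        last_year = (
            config.reference_year - int(rng.integers(0, 4))
            if active
            else config.reference_year - int(4 + rng.integers(0, 6))
        )
        attrs: dict = dict(
            candidate_id=cid,
            name=name,
            indications=indications,
            product_type=product_type,
            archetype=archetype,
            phase=phase,
            last_activity_year=last_year,
            **{attr: (code in triggered) for code, attr, _ in EXCLUSION_RULES},
        )
        if phase is Phase.PRECLINICAL:
            attrs["preclinical_subclass"] = subclasses[rng.integers(len(subclasses))]
            registry.append(Candidate(**attrs))
            continue
        profile_attrs: dict | None = None
        for indication in sorted(indications, key=lambda x: x.value):
            rank: Rank = _choice(rng, config.planted_rank_mix)  # type: ignore[assignment]
            profile = _sample_profile_in_band(
                rng, rank, phase, scheme, config.unknown_rate, cid, indication
            )
            if triggered:
                # Excluded candidates never reach ranking; keep the draw so the
                # stream stays aligned, but plant no truth for them.
                continue
            planted[(cid, indication.value)] = PlantedCandidate(profile, rank)
            if profile_attrs is None:
                profile_attrs = _registry_attrs_from_profile(profile.levels, rng)
            truth_levels = dict(profile.levels)
            b_levels = {
                c: _perturb(lv, rng, config.reviewer_disagreement_rate)
                for c, lv in truth_levels.items()
            }
            assessments.append(
                ReviewerAssessment(
                    candidate_id=cid,
                    indication=indication,
                    reviewer_id=ReviewerId.A,
                    levels=truth_levels,
                )
            )
            assessments.append(
                ReviewerAssessment(
                    candidate_id=cid,
                    indication=indication,
                    reviewer_id=ReviewerId.B,
                    levels=b_levels,
                )
            )
            assessments.append(
                ReviewerAssessment(
                    candidate_id=cid,
                    indication=indication,
                    reviewer_id=ReviewerId.ADJUDICATOR,
                    levels=truth_levels,
                )
            )
        if profile_attrs is not None:
            attrs.update(profile_attrs)
        registry.append(Candidate(**attrs))
    return SyntheticDataset(registry, tuple(assessments), GroundTruth(planted, exclusion_flags), config)


def empirical_mix_check(registry: Registry, config: SyntheticConfig) -> float:
    """Max absolute deviation of empirical vs configured mix proportions
    across phase, product type and archetype categories."""
    n = len(registry)
    dev = 0.0
    for mix, getter in (
        (config.phase_mix, lambda c: c.phase),
        (config.product_type_mix, lambda c: c.product_type),
        (config.archetype_mix, lambda c: c.archetype),
    ):
        for cat, p in mix.items():
            emp = sum(1 for c in registry if getter(c) is cat) / n
            dev = max(dev, abs(emp - p))
    return dev


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write registry.csv, assessments.csv and truth.json into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "registry": out / "registry.csv",
        "assessments": out / "assessments.csv",
        "truth": out / "truth.json",
    }
    write_registry(dataset.registry, paths["registry"])
    write_assessments(dataset.assessments, paths["assessments"])
    paths["truth"].write_text(dataset.truth.to_json(), encoding="utf-8")
    return paths
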