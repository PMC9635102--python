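from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from tpptriage.registry import (
    Archetype,
    Candidate,
    Indication,
    MatchLevel,
    Phase,
    PreclinicalSubclass,
    ProductType,
    ReviewerAssessment,
    ReviewerId,
)
from tpptriage.tpp_engine import CRITERION_IDS, default_scheme

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_candidate(
    candidate_id: str = "C1",
    name: str | None = None,
    indications=("prevention",),
    phase: str = "III",
    product_type: str = "drug",
    archetype: str = "repurposed",
    **overrides,
):
    """Candidate factory with sensible defaults for tests."""
    if phase == "preclinical" and "preclinical_subclass" not in overrides:
        overrides["preclinical_subclass"] = PreclinicalSubclass.SMALL_MOLECULE
    return Candidate(
        candidate_id=candidate_id,
        name=name or candidate_id,
        indications=frozenset(Indication(i) for i in indications),
        product_type=ProductType(product_type),
        archetype=Archetype(archetype),
        phase=Phase(phase),
        **overrides,
    )


def make_assessment(
    candidate_id: str,
    reviewer: str,
    levels: dict[str, MatchLevel] | MatchLevel,
    indication: str = "prevention",
):
    """Assessment factory; a single level is broadcast over all nine criteria."""
    if isinstance(levels, MatchLevel):
        levels = {cid: levels for cid in CRITERION_IDS}
    return ReviewerAssessment(
        candidate_id=candidate_id,
        indication=Indication(indication),
        reviewer_id=ReviewerId(reviewer),
        levels=levels,
    )


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


# ----- hypothesis strategies -----

_EXCLUSION_ATTRS = (
    "approved_for_indication",
    "recommended_or_routine_use",
    "recommended_for_subgroup_only",
    "inactive_negative_outcome",
    "targets_symptom_only",
    "inferior_to_current",
)


@st.composite
def candidates(draw, index: int = 0):
    phase = draw(st.sampled_from(list(Phase)))
    flags = {attr: draw(st.booleans()) for attr in _EXCLUSION_ATTRS}
    return make_candidate(
        candidate_id=f"H{draw(st.integers(0, 10**6))}-{index}",
        indications=draw(
            st.sampled_from([("prevention",), ("treatment",), ("prevention", "treatment")])
        ),
        phase=phase.value,
        **flags,
    )


@st.composite
def registries(draw, min_size: int = 0, max_size: int = 12):
    n = draw(st.integers(min_size, max_size))
    regs = [draw(candidates(index=i)) for i in range(n)]
    # rebuild ids to guarantee uniqueness
    return [
        c.model_copy(update={"candidate_id": f"R{i}"}) for i, c in enumerate(regs)
    ]


levels_strategy = st.sampled_from(list(MatchLevel))


@st.composite
def profiles_levels(draw):
    return {cid: draw(levels_strategy) for cid in CRITERION_IDS}
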