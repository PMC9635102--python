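"""Reconciliation, derived levels, weighted scoring and phase ranking."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_assessment, make_candidate, profiles_levels
from tpptriage.errors import (
    ConfigError,
    CoverageError,
    MissingAssessmentError,
    NotRankableError,
    UnresolvedConflictError,
)
from tpptriage.registry import INFORMATIVE_LEVELS, Indication, MatchLevel, Phase
from tpptriage.tpp_engine import (
    CRITERION_IDS,
    MatchProfile,
    Rank,
    assign_rank,
    default_scheme,
    derive_categorical_levels,
    load_scheme,
    rank_registry,
    reconcile,
    score_profile,
)

L = MatchLevel


def _profile(levels) -> MatchProfile:
    return MatchProfile("C1", Indication.PREVENTION, levels)


class TestReconcile:
    def test_agreement_stands(self):
        a = make_assessment("C1", "A", L.MET_MINIMUM)
        b = make_assessment("C1", "B", L.MET_MINIMUM)
        profile = reconcile(a, b)
        assert profile.levels["efficacy"] is L.MET_MINIMUM
        assert profile.provenance["efficacy"] == "agreement"

    def test_adjudicator_resolves_disagreement(self):
        a = make_assessment("C1", "A", {"safety": L.MET_PREFERRED})
        b = make_assessment("C1", "B", {"safety": L.PARTIALLY_MET})
        adj = make_assessment("C1", "adjudicator", {"safety": L.MET_MINIMUM})
        profile = reconcile(a, b, adj)
        assert profile.levels["safety"] is L.MET_MINIMUM
        assert profile.provenance["safety"] == "adjudicated"

    def test_unresolved_disagreement_names_criterion(self):
        a = make_assessment("C1", "A", {"efficacy": L.MET_PREFERRED})
        b = make_assessment("C1", "B", {"efficacy": L.NOT_MET})
        with pytest.raises(UnresolvedConflictError, match="efficacy"):
            reconcile(a, b)

    def test_mismatched_pair_rejected(self):
        a = make_assessment("C1", "A", L.MET_MINIMUM)
        b = make_assessment("C2", "B", L.MET_MINIMUM)
        with pytest.raises(ValueError, match="same candidate-indication"):
            reconcile(a, b)

    @given(profiles_levels(), profiles_levels(), profiles_levels())
    def test_symmetric_in_reviewers(self, la, lb, ladj):
        a = make_assessment("C1", "A", la)
        b = make_assessment("C1", "B", lb)
        adj = make_assessment("C1", "adjudicator", ladj)
        ab = reconcile(a, b, adj)
        # swapping the reviewer payloads must not change the outcome
        a2 = make_assessment("C1", "A", lb)
        b2 = make_assessment("C1", "B", la)
        ba = reconcile(a2, b2, adj)
        assert ab.levels == ba.levels


class TestDerivedLevels:
    @pytest.mark.parametrize(
        "settings,expected",
        [
            (frozenset({"HIC", "LMIC"}), L.MET_PREFERRED),
            (frozenset({"HIC"}), L.PARTIALLY_MET),
            (frozenset({"LMIC"}), L.PARTIALLY_MET),
            (None, L.UNKNOWN),
        ],
    )
    def test_setting(self, settings, expected):
        cand = make_candidate("C1", trial_settings=settings)
        assert derive_categorical_levels(cand)["setting"] is expected

    @pytest.mark.parametrize(
        "cold,expected",
        [("no", L.MET_PREFERRED), ("yes", L.NOT_MET), ("unknown", L.UNKNOWN)],
    )
    def test_stability(self, cold, expected):
        cand = make_candidate("C1", requires_cold_chain=cold)
        assert derive_categorical_levels(cand)["stability"] is expected

    @pytest.mark.parametrize("on_eml,expected", [(True, L.MET_PREFERRED), (False, L.NOT_MET)])
    def test_who_eml(self, on_eml, expected):
        cand = make_candidate("C1", on_who_eml=on_eml)
        assert derive_categorical_levels(cand)["who_eml"] is expected


class TestScoreProfile:
    def test_all_not_met_scores_zero(self, scheme):
        bd = score_profile(_profile({c: L.NOT_MET for c in CRITERION_IDS}), scheme)
        assert bd.total_score == 0.0
        assert bd.completeness == 1.0

    def test_all_met_preferred(self, scheme):
        # hand-summed: 3 * (2 + 2 + 7*1) = 33
        bd = score_profile(_profile({c: L.MET_PREFERRED for c in CRITERION_IDS}), scheme)
        assert bd.total_score == 33.0
        assert bd.max_attainable == 33.0
        assert bd.completeness == 1.0

    def test_single_informative_criterion(self, scheme):
        levels = {c: L.UNKNOWN for c in CRITERION_IDS}
        levels["efficacy"] = L.MET_MINIMUM
        bd = score_profile(_profile(levels), scheme)
        assert bd.total_score == 4.0  # weight 2 x score 2
        assert bd.completeness == pytest.approx(1 / 9)

    def test_missing_criterion_raises(self, scheme):
        levels = {c: L.MET_MINIMUM for c in CRITERION_IDS if c != "safety"}
        with pytest.raises(CoverageError, match="safety"):
            score_profile(_profile(levels), scheme)

    @given(profiles_levels())
    def test_matches_brute_force_oracle(self, scheme, levels):
        weights = {"efficacy": 2.0, "safety": 2.0}
        scores = {L.NOT_MET: 0, L.PARTIALLY_MET: 1, L.MET_MINIMUM: 2,
                  L.MET_PREFERRED: 3, L.UNKNOWN: 0}
        expected = sum(weights.get(c, 1.0) * scores[levels[c]] for c in CRITERION_IDS)
        assert score_profile(_profile(levels), scheme).total_score == expected

    @given(profiles_levels(), st.sampled_from(CRITERION_IDS))
    def test_monotone_under_level_upgrade(self, scheme, levels, criterion):
        base = score_profile(_profile(levels), scheme).total_score
        current = levels[criterion]
        if current not in INFORMATIVE_LEVELS:
            return
        idx = INFORMATIVE_LEVELS.index(current)
        for upgraded in INFORMATIVE_LEVELS[idx:]:
            bumped = dict(levels, **{criterion: upgraded})
            assert score_profile(_profile(bumped), scheme).total_score >= base

    @given(st.sampled_from(list(MatchLevel)))
    def test_uniform_levels_equal_weight_identity(self, level):
        """With all weights w and all levels l, total = 9 * w * score(l)."""
        scheme = default_scheme()
        uniform = scheme.model_copy(
            update={
                "criteria": tuple(
                    c.model_copy(update={"weight": 1.5}) for c in scheme.criteria
                )
            }
        )
        bd = score_profile(_profile({c: level for c in CRITERION_IDS}), uniform)
        assert bd.total_score == pytest.approx(9 * 1.5 * scheme.level_scores[level])


class TestAssignRank:
    def test_perfect_ratio_is_high(self, scheme):
        assert assign_rank(33.0, 33.0, Phase.II, scheme) is Rank.HIGH

    def test_zero_is_low(self, scheme):
        assert assign_rank(0.0, 33.0, Phase.II, scheme) is Rank.LOW

    def test_cutoffs_are_inclusive(self, scheme):
        assert assign_rank(0.60 * 33, 33.0, Phase.III, scheme) is Rank.HIGH
        assert assign_rank(0.40 * 33, 33.0, Phase.III, scheme) is Rank.MEDIUM

    def test_preclinical_not_rankable(self, scheme):
        with pytest.raises(NotRankableError):
            assign_rank(10.0, 33.0, Phase.PRECLINICAL, scheme)

    @given(st.floats(0, 33), st.floats(0, 33), st.sampled_from(["I", "II", "III", "IV"]))
    def test_rank_non_decreasing_in_score(self, scheme, s1, s2, phase):
        lo, hi = sorted([s1, s2])
        order = {Rank.LOW: 0, Rank.MEDIUM: 1, Rank.HIGH: 2}
        r_lo = assign_rank(lo, 33.0, Phase(phase), scheme)
        r_hi = assign_rank(hi, 33.0, Phase(phase), scheme)
        assert order[r_lo] <= order[r_hi]


class TestSchemeConfig:
    def test_default_scheme_invariants(self, scheme):
        assert len(scheme.criteria) == 9
        assert scheme.weight("efficacy") == scheme.weight("safety") == 2.0

    def test_upweighting_enforced(self, scheme):
        from tpptriage.tpp_engine import ScoringScheme

        with pytest.raises(ValueError, match="efficacy and safety"):
            ScoringScheme(
                criteria=tuple(
                    c.model_copy(update={"weight": 1.0}) for c in scheme.criteria
                ),
                level_scores=scheme.level_scores,
                thresholds=scheme.thresholds,
            )

    def test_load_scheme_round_trips_default(self, scheme):
        from tpptriage.data import default_scheme_path

        assert load_scheme(default_scheme_path()) == scheme

    def test_load_scheme_missing_section(self, tmp_path):
        bad = tmp_path / "s.yaml"
        bad.write_text("criteria: []\n")
        with pytest.raises(ConfigError, match="level_scores"):
            load_scheme(bad)

    def test_non_monotone_level_scores_rejected(self, tmp_path):
        from tpptriage.data import default_scheme_path

        text = default_scheme_path().read_text()
        bad = tmp_path / "s.yaml"
        bad.write_text(text.replace("met_minimum: 2", "met_minimum: 9"))
        with pytest.raises(ConfigError, match="monotone"):
            load_scheme(bad)


class TestRankRegistry:
    def _full_assessments(self, cid, level, indication="prevention"):
        return [
            make_assessment(cid, "A", level, indication=indication),
            make_assessment(cid, "B", level, indication=indication),
        ]

    def test_planted_perfect_profile_ranks_high(self, scheme):
        registry = [make_candidate("C1", phase="II")]
        run = rank_registry(registry, self._full_assessments("C1", L.MET_PREFERRED), scheme, 2021)
        (rc,) = run.ranked
        assert rc.rank is Rank.HIGH
        assert rc.total_score == 33.0

    def test_dual_indication_ranked_twice(self, scheme):
        registry = [make_candidate("C1", indications=("prevention", "treatment"), phase="III")]
        assessments = (
            self._full_assessments("C1", L.MET_PREFERRED, "prevention")
            + self._full_assessments("C1", L.NOT_MET, "treatment")
        )
        run = rank_registry(registry, assessments, scheme, 2021)
        assert len(run.ranked) == 2
        by_ind = {rc.indication.value: rc.rank for rc in run.ranked}
        assert by_ind == {"prevention": Rank.HIGH, "treatment": Rank.LOW}

    def test_excluded_candidate_not_ranked(self, scheme):
        registry = [make_candidate("C1", phase="II", approved_for_indication=True)]
        run = rank_registry(registry, [], scheme, 2021)
        assert run.ranked == ()
        assert len(run.screening.excluded) == 1

    def test_reviewer_levels_win_over_derived(self, scheme):
        # registry says EML-listed (met_preferred), reviewers agree NOT_MET
        registry = [make_candidate("C1", phase="II", on_who_eml=True)]
        run = rank_registry(registry, self._full_assessments("C1", L.NOT_MET), scheme, 2021)
        profile = run.profiles[("C1", "prevention")]
        assert profile.levels["who_eml"] is L.NOT_MET
        assert profile.provenance["who_eml"] == "agreement"

    def test_derived_levels_fill_gaps(self, scheme):
        registry = [
            make_candidate("C1", phase="II", requires_cold_chain="yes",
                           trial_settings=frozenset({"HIC", "LMIC"}))
        ]
        partial = {c: L.MET_MINIMUM for c in CRITERION_IDS
                   if c not in ("setting", "stability", "who_eml")}
        assessments = [
            make_assessment("C1", "A", partial),
            make_assessment("C1", "B", partial),
        ]
        run = rank_registry(registry, assessments, scheme, 2021)
        profile = run.profiles[("C1", "prevention")]
        assert profile.levels["setting"] is L.MET_PREFERRED
        assert profile.levels["stability"] is L.NOT_MET
        assert profile.provenance["setting"] == "derived"

    def test_missing_reviewer_raises(self, scheme):
        registry = [make_candidate("C1", phase="II")]
        assessments = [make_assessment("C1", "A", L.MET_MINIMUM)]
        with pytest.raises(MissingAssessmentError, match="C1"):
            rank_registry(registry, assessments, scheme, 2021)

    def test_unresolved_conflict_carries_candidate_context(self, scheme):
        registry = [make_candidate("C1", "Verapamil", phase="II")]
        assessments = [
            make_assessment("C1", "A", L.MET_PREFERRED),
            make_assessment("C1", "B", L.NOT_MET),
        ]
        with pytest.raises(UnresolvedConflictError, match="Verapamil"):
            rank_registry(registry, assessments, scheme, 2021)
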