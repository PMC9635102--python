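"""Registry data model, I/O round-trips and activity classification."""

from __future__ import annotations

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_assessment, make_candidate, registries
from tpptriage.errors import (
    DuplicateIdError,
    ReferentialError,
    SchemaError,
    ValueTokenError,
)
from tpptriage.registry import (
    Activity,
    MatchLevel,
    classify_activity,
    load_assessments,
    load_registry,
    validate_assessments,
    write_assessments,
    write_registry,
)
from tpptriage.tpp_engine import CRITERION_IDS


@pytest.fixture
def small_registry():
    return [
        make_candidate("C1", "Alpha", phase="III", last_activity_year=2020,
                       trial_settings=frozenset({"HIC", "LMIC"})),
        make_candidate("C2", "Beta", indications=("prevention", "treatment"),
                       phase="II", on_who_eml=True, requires_cold_chain="yes"),
        make_candidate("C3", "Gamma", phase="preclinical"),
    ]


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_write_load_round_trip(tmp_path, small_registry, fmt):
    path = tmp_path / f"reg.{fmt}"
    write_registry(small_registry, path)
    loaded = load_registry(path)
    assert loaded == small_registry
    # a second round-trip through the other format is also the identity
    other = tmp_path / ("reg2.json" if fmt == "csv" else "reg2.csv")
    write_registry(loaded, other)
    assert load_registry(other) == small_registry


@given(registries(min_size=1, max_size=8))
def test_round_trip_property(tmp_path_factory, registry):
    path = tmp_path_factory.mktemp("rt") / "reg.csv"
    write_registry(registry, path)
    assert load_registry(path) == registry


def test_load_preserves_order(tmp_path, small_registry):
    path = tmp_path / "reg.csv"
    write_registry(small_registry, path)
    assert [c.candidate_id for c in load_registry(path)] == ["C1", "C2", "C3"]


def test_invalid_phase_token_rejected(tmp_path, small_registry):
    path = tmp_path / "reg.csv"
    write_registry(small_registry, path)
    text = path.read_text().replace(",III,", ",V,")
    path.write_text(text)
    with pytest.raises(ValueTokenError, match="phase"):
        load_registry(path)


def test_missing_column_names_field(tmp_path):
    path = tmp_path / "reg.csv"
    path.write_text("candidate_id,name\nC1,Alpha\n")
    with pytest.raises(SchemaError, match="archetype"):
        load_registry(path)


def test_duplicate_candidate_id_rejected(tmp_path):
    reg = [make_candidate("C1"), make_candidate("C1", "Other")]
    path = tmp_path / "reg.json"
    # write bypasses the uniqueness check; load must enforce it
    write_registry(reg, path)
    with pytest.raises(DuplicateIdError, match="C1"):
        load_registry(path)


def test_empty_indications_rejected(tmp_path, small_registry):
    path = tmp_path / "reg.json"
    write_registry(small_registry, path)
    records = json.loads(path.read_text())
    records[0]["indications"] = []
    path.write_text(json.dumps(records))
    with pytest.raises(ValueTokenError, match="indications"):
        load_registry(path)


def test_subclass_required_iff_preclinical():
    with pytest.raises(ValueError, match="preclinical_subclass"):
        make_candidate("C1", phase="III", preclinical_subclass="polyphenol")
    with pytest.raises(ValueError, match="preclinical_subclass"):
        make_candidate("C1", phase="preclinical", preclinical_subclass=None)


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "year,expected",
        [(2018, Activity.ACTIVE), (2017, Activity.INACTIVE), (2021, Activity.ACTIVE)],
    )
    def test_three_year_inclusive_boundary(self, year, expected):
        cand = make_candidate("C1", last_activity_year=year)
        assert classify_activity(cand, 2021) is expected

    def test_absent_year_is_inactive(self):
        assert classify_activity(make_candidate("C1"), 2021) is Activity.INACTIVE

    @given(st.integers(1990, 2025), st.integers(1990, 2025))
    def test_monotone_in_activity_year(self, y1, y2):
        lo, hi = sorted([y1, y2])
        ref = 2021
        a_lo = classify_activity(make_candidate("C1", last_activity_year=lo), ref)
        a_hi = classify_activity(make_candidate("C1", last_activity_year=hi), ref)
        assert not (a_lo is Activity.ACTIVE and a_hi is Activity.INACTIVE)


class TestValidateAssessments:
    def test_full_coverage_has_no_defects(self, small_registry):
        recs = [
            make_assessment("C1", "A", MatchLevel.MET_MINIMUM),
            make_assessment("C1", "B", MatchLevel.MET_MINIMUM),
        ]
        report = validate_assessments(small_registry, recs, CRITERION_IDS)
        assert report.ok
        assert ("C2", "prevention") in report.unassessed

    def test_missing_criterion_named(self, small_registry):
        levels = {cid: MatchLevel.MET_MINIMUM for cid in CRITERION_IDS if cid != "stability"}
        recs = [
            make_assessment("C1", "A", MatchLevel.MET_MINIMUM),
            make_assessment("C1", "B", levels),
        ]
        report = validate_assessments(small_registry, recs, CRITERION_IDS)
        assert any(
            d.kind == "missing_criterion" and d.detail == "B: stability"
            and d.candidate_id == "C1"
            for d in report.defects
        )

    def test_unknown_candidate_raises(self, small_registry):
        recs = [make_assessment("NOPE", "A", MatchLevel.MET_MINIMUM)]
        with pytest.raises(ReferentialError, match="NOPE"):
            validate_assessments(small_registry, recs, CRITERION_IDS)

    def test_never_mutates_registry(self, small_registry):
        before = list(small_registry)
        validate_assessments(small_registry, [], CRITERION_IDS)
        assert small_registry == before


def test_assessments_round_trip(tmp_path):
    recs = [
        make_assessment("C1", "A", MatchLevel.MET_PREFERRED),
        make_assessment("C1", "B", {"efficacy": MatchLevel.UNKNOWN}),
        make_assessment("C1", "adjudicator", MatchLevel.NOT_MET, indication="treatment"),
    ]
    path = tmp_path / "a.csv"
    write_assessments(recs, path)
    loaded = load_assessments(path)
    assert [(r.candidate_id, r.indication, r.reviewer_id, dict(r.levels)) for r in loaded] == [
        (r.candidate_id, r.indication, r.reviewer_id, dict(r.levels)) for r in recs
    ]


def test_assessment_bad_level_token(tmp_path):
    path = tmp_path / "a.csv"
    path.write_text(
        "candidate_id,indication,reviewer_id,criterion_id,level\n"
        "C1,prevention,A,efficacy,superb\n"
    )
    with pytest.raises(ValueTokenError, match="superb"):
        load_assessments(path)
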