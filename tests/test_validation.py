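"""Requirement-level validation: missing-MUST attribution, advisory policy,
monotonicity and determinism."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dats import (
    Annotation,
    DateInterval,
    DatsEntity,
    Identifier,
    IssueCode,
    Level,
    StructuralError,
    conforms,
    validate,
)
from dats.validation import interval_ok, is_absolute_iri, parse_iso_date

from conftest import MUST_PERTURBATIONS, make_reference_instance


def test_minimal_dataset_is_must_conformant(minimal_instance, profile):
    report = validate(minimal_instance, profile)
    assert report.at_level(Level.MUST) == []
    assert report.verdicts["MUST"] is True
    assert conforms(minimal_instance, profile, Level.MUST)


def test_reference_instance_is_clean_at_every_level(reference_instance, profile):
    assert validate(reference_instance, profile).issues == []


def test_missing_title_yields_exactly_one_issue(minimal_instance, profile):
    del minimal_instance.properties["title"]
    report = validate(minimal_instance, profile)
    assert [(i.path, i.code) for i in report.at_level(Level.MUST)] == [
        ("Dataset/title", IssueCode.MISSING_MUST)]
    assert report.verdicts["MUST"] is False


@pytest.mark.parametrize("entry", sorted(MUST_PERTURBATIONS), ids="{0[0]}.{0[1]}".format)
def test_perturbation_completeness(entry, profile):
    """Deleting each of the 10 MUST entries yields exactly the predicted issue."""
    instance = make_reference_instance()
    expected_path, mutate = MUST_PERTURBATIONS[entry]
    mutate(instance)
    must_issues = validate(instance, profile).at_level(Level.MUST)
    assert [(i.path, i.code) for i in must_issues] == [
        (expected_path, IssueCode.MISSING_MUST)]


def test_unknown_property_is_advisory(minimal_instance, profile):
    minimal_instance.unknown["colour"] = "teal"
    report = validate(minimal_instance, profile)
    assert report.verdicts["MUST"] is True
    advisories = report.at_level(Level.MAY)
    assert [(i.path, i.code) for i in advisories] == [
        ("Dataset/colour", IssueCode.UNKNOWN_PROPERTY)]
    assert not conforms(minimal_instance, profile, Level.MAY)


def test_empty_value_counts_as_absent(minimal_instance, profile):
    minimal_instance["title"] = "   "
    issues = validate(minimal_instance, profile).at_level(Level.MUST)
    assert [(i.path, i.code) for i in issues] == [
        ("Dataset/title", IssueCode.MISSING_MUST)]


@pytest.mark.parametrize("prop,value", [
    ("description", "free text"),
    ("licenses", [DatsEntity("License", name="CC0-1.0")]),
    ("temporalCoverage", [DateInterval(start="2019", end="2020-06")]),
    ("dates", []),  # empty collections are simply absent
    ("distributions", [DatsEntity(
        "DatasetDistribution",
        access=DatsEntity("Access", landingPage="https://example.org/x"))]),
])
def test_monotonicity_optional_wellformed_additions(minimal_instance, profile,
                                                    prop, value):
    """Adding well-formed optional material never introduces a MUST issue."""
    assert conforms(minimal_instance, profile, Level.MUST)
    minimal_instance[prop] = value
    assert validate(minimal_instance, profile).at_level(Level.MUST) == []


def test_reports_are_deterministic_and_sorted(reference_instance, profile):
    del reference_instance.properties["title"]
    reference_instance["creators"][0].properties.pop("fullName")
    first = validate(reference_instance, profile)
    second = validate(reference_instance, profile)
    assert first.to_json() == second.to_json()
    paths = [i.path for i in first.issues]
    assert paths == sorted(paths)


def test_bad_iri_is_a_must_failure(minimal_instance, profile):
    minimal_instance["types"][0].valueIRI = "definitely not an iri"
    issues = validate(minimal_instance, profile).at_level(Level.MUST)
    assert [(i.path, i.code) for i in issues] == [
        ("Dataset/types/0/valueIRI", IssueCode.BAD_IRI)]


def test_bad_interval_is_a_must_failure(minimal_instance, profile):
    minimal_instance["temporalCoverage"] = [DateInterval(start="2021-06-01", end="2019")]
    issues = validate(minimal_instance, profile).at_level(Level.MUST)
    assert [(i.path, i.code) for i in issues] == [
        ("Dataset/temporalCoverage/0", IssueCode.BAD_INTERVAL)]


def test_access_without_locator_fails_should(minimal_instance, profile):
    minimal_instance["distributions"] = [DatsEntity(
        "DatasetDistribution",
        access=DatsEntity("Access", types=[Annotation(value="download")]))]
    assert conforms(minimal_instance, profile, Level.MUST)
    assert not conforms(minimal_instance, profile, Level.SHOULD)
    report = validate(minimal_instance, profile)
    assert any(i.code is IssueCode.NO_LOCATOR and
               i.path == "Dataset/distributions/0/access"
               for i in report.at_level(Level.SHOULD))


def test_negative_size_rejected(minimal_instance, profile):
    minimal_instance["distributions"] = [DatsEntity(
        "DatasetDistribution",
        access=DatsEntity("Access", landingPage="https://example.org/x"),
        size=-1,
        unit=Annotation(value="MB"))]
    codes = {i.code for i in validate(minimal_instance, profile).at_level(Level.MUST)}
    assert codes == {IssueCode.BAD_VALUE}


def test_absent_entities_yield_no_issues(minimal_instance, profile):
    # applicable-only-if-relevant: no distribution, publication, repository —
    # and no issue mentions any of them; the only advisory is the Dataset's
    # own recommended description.
    report = validate(minimal_instance, profile)
    assert report.at_level(Level.MUST) == []
    assert [(i.path, i.code) for i in report.issues] == [
        ("Dataset/description", IssueCode.MISSING_SHOULD)]


def test_unknown_root_is_structural_error(profile):
    with pytest.raises(StructuralError):
        validate(DatsEntity("Gibberish", name="x"), profile)
    with pytest.raises(StructuralError):
        validate({"title": "not a node"}, profile)  # type: ignore[arg-type]


def test_nested_identifier_must_entry(minimal_instance, profile):
    minimal_instance["identifier"] = Identifier(identifier="",
                                                identifierSource="DOI")
    issues = validate(minimal_instance, profile).at_level(Level.MUST)
    assert [(i.path, i.code) for i in issues] == [
        ("Dataset/identifier/identifier", IssueCode.MISSING_MUST)]


# --- small property checks on the date helpers -----------------------------

_dates = st.dates(min_value=__import__("datetime").date(1000, 1, 1))


@settings(max_examples=100, derandomize=True)
@given(a=_dates, b=_dates)
def test_interval_ordering_matches_date_comparison(a, b):
    interval = DateInterval(start=a.isoformat(), end=b.isoformat())
    assert interval_ok(interval) == (a <= b)


@settings(max_examples=100, derandomize=True)
@given(d=_dates, precision=st.sampled_from(["year", "month", "day"]))
def test_iso_parse_precision(d, precision):
    text = {"year": f"{d.year:04d}",
            "month": f"{d.year:04d}-{d.month:02d}",
            "day": d.isoformat()}[precision]
    parsed = parse_iso_date(text)
    assert parsed is not None
    assert parsed[0] == d.year


@pytest.mark.parametrize("iri,ok", [
    ("https://example.org/x", True),
    ("urn:uuid:1234", True),
    ("doi:10.1/x", True),
    ("not an iri", False),
    ("", False),
    ("/relative/path", False),
])
def test_absolute_iri_judgement(iri, ok):
    assert is_absolute_iri(iri) is ok
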