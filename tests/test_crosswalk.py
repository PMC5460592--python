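"""Crosswalks: shipped specs, accounting invariant, composition with JSON-LD."""

import copy

import pytest

from dats import (
    Annotation,
    CrosswalkError,
    Level,
    apply_crosswalk,
    builtin_spec,
    builtin_specs,
    load_crosswalk,
    to_jsonld,
    write_instance,
)
from dats.crosswalk import source_leaves

COMPLETE_DC = {
    "title": "Soil microbiome survey of Greater Testshire",
    "creator": ["Ada Lovelace", "Grace Hopper"],
    "identifier": "doi:10.1234/dc.0001",
    "description": "A 16S survey.",
    "type": "dataset",
    "subject": ["soil", "microbiome"],
    "date": "2018-03-01",
    "rights": "CC-BY-4.0",
}

COMPLETE_DATACITE = {
    "identifier": {"id": "10.5061/example.42", "type": "DOI"},
    "creators": [{"name": "Ada Lovelace"}, {"name": "Grace Hopper"}],
    "titles": [{"title": "Tidal records 1950-2000"}],
    "publicationYear": "2016",
    "resourceType": {"resourceTypeGeneral": "Dataset"},
    "descriptions": [{"description": "Hourly tide-gauge readings."}],
    "rightsList": [{"rights": "CC0-1.0"}],
}


def test_builtin_specs_resolve_against_registry():
    specs = builtin_specs()
    assert len(specs) >= 3
    assert {s.name for s in specs} >= {"dublin-core", "datacite", "schemaorg"}


def test_dublin_core_example_maps_to_expected_instance(profile):
    record = {"title": "T", "creator": "A B", "identifier": "doi:10.1/x"}
    result = apply_crosswalk(record, builtin_spec("dublin-core"), profile)
    assert write_instance(result.instance) == {
        "identifier": {"identifier": "doi:10.1/x"},
        "title": "T",
        "creators": [{"fullName": "A B"}],
    }
    assert result.unmapped_source_fields == []


def test_missing_creator_reported_not_fatal(profile):
    record = {"title": "T", "identifier": "doi:10.1/x", "type": "dataset"}
    result = apply_crosswalk(record, builtin_spec("dublin-core"), profile)
    must = result.report.at_level(Level.MUST)
    assert [(i.path, i.code.value) for i in must] == [
        ("Dataset/creators", "MISSING_MUST")]


def test_crosswalk_is_deterministic(profile):
    spec = builtin_spec("dublin-core")
    first = apply_crosswalk(COMPLETE_DC, spec, profile)
    second = apply_crosswalk(copy.deepcopy(COMPLETE_DC), spec, profile)
    assert first.instance == second.instance
    assert first.unmapped_source_fields == second.unmapped_source_fields
    assert first.report.to_json() == second.report.to_json()


@pytest.mark.parametrize("record,spec_name", [
    (COMPLETE_DC, "dublin-core"),
    (COMPLETE_DATACITE, "datacite"),
])
def test_complete_records_crosswalk_to_must_conformance(record, spec_name, profile):
    result = apply_crosswalk(record, builtin_spec(spec_name), profile)
    assert result.report.passes(Level.MUST), result.report.to_json()
    assert result.unmapped_source_fields == []


@pytest.mark.parametrize("record,spec_name", [
    (COMPLETE_DC, "dublin-core"),
    (COMPLETE_DATACITE, "datacite"),
    ({**COMPLETE_DC, "coverage": "global", "extra": {"nested": ["a", "b"]}},
     "dublin-core"),
])
def test_conservation_of_source_leaves(record, spec_name, profile):
    """|consumed| + |unmapped| = |leaves|: nothing silently dropped."""
    result = apply_crosswalk(record, builtin_spec(spec_name), profile)
    leaves = source_leaves(record)
    unmapped = set(result.unmapped_source_fields)
    assert unmapped <= leaves
    consumed = leaves - unmapped
    assert len(consumed) + len(unmapped) == len(leaves)
    for extra_leaf in ("coverage", "extra/nested/0", "extra/nested/1"):
        if extra_leaf in leaves:
            assert extra_leaf in unmapped


def test_datacite_publication_year_becomes_typed_date(profile):
    result = apply_crosswalk(COMPLETE_DATACITE, builtin_spec("datacite"), profile)
    dates = result.instance["dates"]
    assert len(dates) == 1
    assert dates[0].date == "2016"  # year precision preserved
    assert dates[0].type == Annotation(value="publication")


def test_schemaorg_composition_recovers_minimal_dataset(minimal_instance,
                                                        profile, mapping):
    """Composition oracle: crosswalking our own Schema.org emission recovers
    the original on every mapped field."""
    document = to_jsonld(minimal_instance, mapping)
    result = apply_crosswalk(document, builtin_spec("schemaorg"), profile)
    recovered = result.instance
    assert recovered["title"] == minimal_instance["title"]
    assert recovered["identifier"] == minimal_instance["identifier"]
    assert recovered["types"] == minimal_instance["types"]
    assert recovered["creators"] == minimal_instance["creators"]
    assert result.report.passes(Level.MUST)
    assert result.unmapped_source_fields == []


def test_required_source_field_error():
    with pytest.raises(CrosswalkError, match="title"):
        apply_crosswalk({"creator": "A B"}, builtin_spec("dublin-core"))


def test_spec_resolution_rejects_bad_targets(registry):
    with pytest.raises(CrosswalkError, match="colour"):
        load_crosswalk({"name": "bad", "rules": [
            {"source": "x", "target": "colour"}]}, registry)
    with pytest.raises(CrosswalkError, match="transform"):
        load_crosswalk({"name": "bad", "rules": [
            {"source": "x", "target": "title", "transform": "frobnicate"}]}, registry)


def test_split_transform_and_defaults(registry, profile):
    spec = load_crosswalk({
        "name": "inline",
        "rules": [
            {"source": "title", "target": "title", "required": True},
            {"source": "authors", "target": "creators[]/fullName",
             "transform": "split", "arg": ";"},
        ],
        "defaults": [
            {"target": "types[]", "value": "dataset"},
        ],
    }, registry)
    result = apply_crosswalk(
        {"title": "T", "authors": "A B; C D"}, spec, profile)
    assert [c["fullName"] for c in result.instance["creators"]] == ["A B", "C D"]
    assert result.instance["types"] == [Annotation(value="dataset")]


def test_scalar_target_keeps_first_value_with_advisory(profile):
    record = dict(COMPLETE_DATACITE,
                  titles=[{"title": "First"}, {"title": "Second"}])
    result = apply_crosswalk(record, builtin_spec("datacite"), profile)
    assert result.instance["title"] == "First"
    assert any("keeping first" in a for a in result.advisories)
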