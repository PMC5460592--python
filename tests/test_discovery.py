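"""Flattening and boolean retrieval, checked against brute-force oracles."""

import io
import itertools

import pytest

from dats import (
    Annotation,
    DatsEntity,
    FACET_KEYS,
    GeneratorConfig,
    NonConformantError,
    QueryError,
    flatten,
    generate,
    query,
    read_ndjson,
    write_instance,
    write_ndjson,
)

from oracles import brute_force_query, count_scalar_leaves, raw_facets


@pytest.fixture(scope="module")
def collection(profile):
    corpus = generate(GeneratorConfig(seed=31, completeness="typical", count=40))
    instances = [item.instance for item in corpus]
    docs = [flatten(inst, profile) for inst in instances]
    raw = [write_instance(inst) for inst in instances]
    return instances, docs, raw


def test_flatten_conservation_leaf_count(collection):
    """Triple count equals the populated-leaf count of an independent walk."""
    _, docs, raw = collection
    for doc, raw_doc in zip(docs, raw):
        assert len(doc.triples) == count_scalar_leaves(raw_doc)


def test_minimal_dataset_triples_cover_exactly_its_leaves(minimal_instance, profile):
    doc = flatten(minimal_instance, profile)
    assert sorted(doc.triples) == sorted([
        ("Dataset", "Dataset/identifier/identifier", "https://example.org/ref/0001"),
        ("Dataset", "Dataset/title", minimal_instance["title"]),
        ("Dataset", "Dataset/types/0/value", "RNA-seq"),
        ("Person", "Dataset/creators/0/fullName", "Ada Lovelace"),
    ])


def test_api_access_annotation_surfaces_as_facet(reference_instance, profile):
    doc = flatten(reference_instance, profile)
    assert "API" in doc.facets["accessType"]
    assert doc.facets["authorization"] == ["public"]
    assert doc.facets["repository"] == ["ExampleBank"]
    assert doc.facets["dataStandard"] == ["MINSEQE"]
    assert set(doc.facets["materialTerm"]) == {"whole embryo", "hoxa1 expression"}
    assert doc.facets["dataTypeTerm"] == ["RNA-seq"]


def test_flatten_refuses_nonconformant(minimal_instance, profile):
    del minimal_instance.properties["title"]
    with pytest.raises(NonConformantError) as err:
        flatten(minimal_instance, profile)
    assert err.value.report.verdicts["MUST"] is False


def test_flatten_is_injective_on_distinct_instances(collection):
    _, docs, _ = collection
    ids = [doc.dataset_id for doc in docs]
    assert len(set(ids)) == len(ids)


def test_facets_match_raw_extraction_oracle(collection):
    _, docs, raw = collection
    for doc, raw_doc in zip(docs, raw):
        expected = raw_facets(raw_doc)
        for key in FACET_KEYS:
            assert set(doc.facets[key]) == expected[key]


def test_query_equals_brute_force_over_facet_predicates(collection):
    _, docs, raw = collection
    values = {key: sorted({v for doc in docs for v in doc.facets[key]})
              for key in FACET_KEYS}
    checked = 0
    for size in (1, 2):
        for keys in itertools.combinations(FACET_KEYS, size):
            pools = [values[k][:3] for k in keys]
            for combo in itertools.product(*pools):
                predicate = dict(zip(keys, combo))
                assert query(docs, facets=predicate) == \
                    brute_force_query(raw, facets=predicate)
                checked += 1
    assert checked > 100


def test_keyword_query_matches_brute_force(collection):
    _, docs, raw = collection
    for keyword in ("transcriptome", "RNA-seq", "Hopper", "no-such-token"):
        assert query(docs, keywords=[keyword]) == \
            brute_force_query(raw, keywords=[keyword])


def test_empty_predicate_returns_all_ids(collection):
    _, docs, _ = collection
    assert query(docs) == sorted(d.dataset_id for d in docs)


def test_unmatched_facet_value_returns_empty(collection):
    _, docs, _ = collection
    assert query(docs, facets={"dataStandard": "NoSuchStandard"}) == []


def test_unknown_facet_is_an_error(collection):
    _, docs, _ = collection
    with pytest.raises(QueryError, match="flavour"):
        query(docs, facets={"flavour": "vanilla"})


def test_custom_facet_extractor(minimal_instance, profile):
    doc = flatten(minimal_instance, profile, extractors={
        "creatorName": lambda inst: [
            c.get("fullName", "") for c in inst["creators"]
            if isinstance(c, DatsEntity)]})
    assert doc.facets["creatorName"] == ["Ada Lovelace"]
    assert query([doc], facets={"creatorName": "ada lovelace"}) == [doc.dataset_id]


def test_ndjson_round_trip(collection):
    _, docs, _ = collection
    buffer = io.StringIO()
    assert write_ndjson(docs, buffer) == len(docs)
    buffer.seek(0)
    back = read_ndjson(buffer)
    assert [d.to_dict() for d in back] == [d.to_dict() for d in docs]
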