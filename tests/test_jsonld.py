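"""Schema.org JSON-LD serialization: context emission, round trips, and an
independent check through a real JSON-LD/RDF processor (rdflib)."""

import json

import pytest

from dats import (
    FormatError,
    GeneratorConfig,
    MappingError,
    compact,
    expand,
    from_jsonld,
    generate,
    load_mapping,
    mapping_gaps,
    mapping_totality,
    to_jsonld,
)

SDO = "https://schema.org/"
DATS_NS = "https://w3id.org/dats/terms#"


def test_dataset_type_resolves_to_schemaorg_iri(minimal_instance, mapping):
    doc = to_jsonld(minimal_instance, mapping)
    expanded = expand(doc, mapping)
    assert expanded["@type"] == SDO + "Dataset"
    assert expanded[SDO + "name"] == minimal_instance["title"]


def test_expand_then_compact_reproduces_document(minimal_instance, mapping):
    doc = to_jsonld(minimal_instance, mapping)
    assert compact(expand(doc, mapping), mapping) == doc


@pytest.mark.parametrize("tier", ["minimal", "typical", "full"])
def test_jsonld_round_trip_over_generated_instances(tier, mapping):
    for item in generate(GeneratorConfig(seed=21, completeness=tier, count=15)):
        doc = to_jsonld(item.instance, mapping)
        assert compact(expand(doc, mapping), mapping) == doc
        assert from_jsonld(doc, mapping) == item.instance


def test_id_minted_from_iri_identifier(minimal_instance, mapping):
    doc = to_jsonld(minimal_instance, mapping)
    assert doc["@id"] == minimal_instance["identifier"].identifier


def test_annotation_value_iri_becomes_node_id(reference_instance, mapping):
    doc = to_jsonld(reference_instance, mapping)
    annotation = doc["types"][0]
    assert annotation["@id"] == "https://example.org/vocab/rna-seq"
    assert "valueIRI" not in annotation
    back = from_jsonld(doc, mapping)
    assert back["types"][0].valueIRI == "https://example.org/vocab/rna-seq"


def test_unmapped_terms_fall_back_to_dats_namespace(reference_instance, mapping):
    doc = to_jsonld(reference_instance, mapping)
    expanded = expand(doc, mapping)
    assert DATS_NS + "producedBy" in expanded
    gaps = mapping_gaps(doc, mapping)
    assert "Dataset.producedBy" in gaps
    assert "Access" in gaps


def test_plain_schemaorg_dataset_node(mapping):
    node = {
        "@context": "https://schema.org",
        "@type": "Dataset",
        "name": "Surface temperatures 1880-2020",
        "description": "Gridded observations.",
        "identifier": "doi:10.1/example",
    }
    instance = from_jsonld(node, mapping)
    assert instance.entity == "Dataset"
    assert instance["title"] == node["name"]
    assert instance["description"] == node["description"]
    assert instance["identifier"].identifier == "doi:10.1/example"


def test_unknown_type_is_a_format_error(mapping):
    with pytest.raises(FormatError, match="Recipe"):
        from_jsonld({"@context": "https://schema.org", "@type": "Recipe",
                     "name": "x"}, mapping)
    with pytest.raises(FormatError):
        from_jsonld({"name": "no type at all"}, mapping)


def test_mapping_totality_no_silent_omissions(mapping, registry):
    report = mapping_totality(mapping, registry)
    assert report["missing"] == []
    # every unmapped term carries a reason
    assert all(u.get("reason") for u in mapping.unmapped)


def test_duplicate_mapping_terms_rejected(registry):
    doc = {
        "namespaces": {"sdo": SDO, "dats": DATS_NS},
        "entities": {"Dataset": "sdo:Dataset"},
        "properties": {"Dataset": {"title": "sdo:name"}},
        "unmapped": [{"term": "Dataset.title", "reason": "duplicate"}],
    }
    with pytest.raises(MappingError, match="Dataset.title"):
        load_mapping(doc, registry)


def test_colliding_type_iris_rejected(registry):
    doc = {
        "namespaces": {"sdo": SDO, "dats": DATS_NS},
        "entities": {"License": "sdo:CreativeWork", "DataStandard": "sdo:CreativeWork"},
    }
    with pytest.raises(MappingError, match="CreativeWork"):
        load_mapping(doc, registry)


def test_rdflib_parses_emitted_documents(reference_instance, mapping):
    """Independent oracle: a conformant JSON-LD processor must see the same
    Schema.org triples our context promises."""
    rdflib = pytest.importorskip("rdflib")
    doc = to_jsonld(reference_instance, mapping)
    graph = rdflib.Graph().parse(data=json.dumps(doc), format="json-ld")
    RDF = rdflib.RDF
    sdo = rdflib.Namespace(SDO)
    root = rdflib.URIRef(reference_instance["identifier"].identifier)
    assert (root, RDF.type, sdo.Dataset) in graph
    assert (root, sdo.name, rdflib.Literal(reference_instance["title"])) in graph
    # the nested identifier node uses the scoped PropertyValue terms
    idents = list(graph.objects(root, sdo.identifier))
    assert len(idents) == 1
    assert (idents[0], sdo.value,
            rdflib.Literal(reference_instance["identifier"].identifier)) in graph
    # unmapped terms surface in the DATS namespace, not silently dropped
    dats_ns = rdflib.Namespace(DATS_NS)
    assert list(graph.objects(root, dats_ns.producedBy))
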