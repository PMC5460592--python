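"""Discovery-oriented flattening and boolean retrieval.

A MUST-conformant instance is flattened into a *field document*: the dataset
identifier, the full set of (entity, attribute, value) triples — one per
populated leaf — and a handful of derived facets that answer the common
discovery questions (how is it accessed, is it public, which standard, which
repository, what is it about, what kind of data).

Retrieval is exact boolean over a collection of field documents: facet
equality plus case-insensitive keyword containment, conjunctively combined,
results ordered by dataset id.  Ranking, stemming and query expansion belong
to a search engine, not to the metadata model; keeping retrieval exact keeps
it oracle-checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence

from ._errors import NonConformantError, QueryError
from .instance import Annotation, DatsEntity, Identifier, iter_leaves, walk_entities
from .registry import EntityRegistry, Level, RequirementProfile, build_core_registry, load_profile
from .validation import validate

#: The shipped facet menu; extensible via the ``extractors`` argument.
FACET_KEYS = (
    "accessType",
    "authorization",
    "dataStandard",
    "repository",
    "materialTerm",
    "dataTypeTerm",
)


def _annotation_values(values: Any) -> list[str]:
    out = []
    for item in values or []:
        if isinstance(item, Annotation) and item.value:
            out.append(item.value)
    return out


def _default_facets(instance: DatsEntity) -> dict[str, list[str]]:
    facets: dict[str, set[str]] = {key: set() for key in FACET_KEYS}
    facets["dataTypeTerm"].update(_annotation_values(instance.get("types")))
    for item in instance.get("isAbout") or []:
        if isinstance(item, Annotation) and item.value:
            facets["materialTerm"].add(item.value)
        elif isinstance(item, DatsEntity) and item.entity == "Material":
            name = item.get("name")
            if name:
                facets["materialTerm"].add(name)
    for _, node in walk_entities(instance):
        if node.entity == "Access":
            facets["accessType"].update(_annotation_values(node.get("types")))
            facets["authorization"].update(_annotation_values(node.get("authorizations")))
        elif node.entity == "DatasetDistribution":
            stored = node.get("storedIn")
            if isinstance(stored, DatsEntity) and stored.get("name"):
                facets["repository"].add(stored["name"])
            for std in node.get("conformsTo") or []:
                if isinstance(std, DatsEntity) and std.get("name"):
                    facets["dataStandard"].add(std["name"])
    return {key: sorted(values) for key, values in facets.items()}


@dataclass
class FieldDocument:
    """Flattened, search-ready view of one dataset."""

    dataset_id: str
    triples: list[tuple[str, str, str]]
    facets: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "datasetId": self.dataset_id,
            "triples": [list(t) for t in self.triples],
            "facets": self.facets,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FieldDocument":
        return cls(
            dataset_id=doc["datasetId"],
            triples=[tuple(t) for t in doc["triples"]],
            facets={k: list(v) for k, v in doc.get("facets", {}).items()},
        )


def flatten(
    instance: DatsEntity,
    profile: Optional[RequirementProfile] = None,
    registry: Optional[EntityRegistry] = None,
    extractors: Optional[Mapping[str, Any]] = None,
) -> FieldDocument:
    """Flatten a MUST-conformant instance into a field document.

    Every populated leaf value appears in exactly one triple.  Non-conformant
    instances are refused with the validation report attached
    (:class:`NonConformantError`).
    """
    registry = registry or build_core_registry()
    profile = profile or load_profile(registry=registry)
    report = validate(instance, profile, registry)
    if not report.passes(Level.MUST):
        raise NonConformantError(
            "refusing to index a non-MUST-conformant instance", report
        )
    ident = instance.get("identifier")
    dataset_id = ident.identifier if isinstance(ident, Identifier) else str(ident)
    triples = [
        (entity, path, str(value)) for entity, path, value in iter_leaves(instance)
    ]
    facets = _default_facets(instance)
    if extractors:
        for key, fn in extractors.items():
            facets[key] = sorted(set(fn(instance)))
    return FieldDocument(dataset_id=dataset_id, triples=triples, facets=facets)


def query(
    documents: Iterable[FieldDocument],
    facets: Optional[Mapping[str, str]] = None,
    keywords: Optional[Sequence[str]] = None,
) -> list[str]:
    """Exact boolean retrieval: facet equality AND keyword containment.

    Facet values compare case-insensitively; keywords match as
    case-insensitive substrings of any triple value.  Returns matching
    dataset ids sorted lexicographically.  An empty predicate matches every
    document.  Unknown facet keys raise :class:`QueryError`.
    """
    documents = list(documents)
    facets = dict(facets or {})
    keywords = list(keywords or [])
    known = set(FACET_KEYS)
    for doc in documents:
        known |= set(doc.facets)
    for key in facets:
        if key not in known:
            raise QueryError(f"unknown facet {key!r}")

    def matches(doc: FieldDocument) -> bool:
        for key, wanted in facets.items():
            have = {v.lower() for v in doc.facets.get(key, [])}
            if str(wanted).lower() not in have:
                return False
        for kw in keywords:
            needle = str(kw).lower()
            if not any(needle in value.lower() for _, _, value in doc.triples):
                return False
        return True

    return sorted(doc.dataset_id for doc in documents if matches(doc))


def write_ndjson(documents: Iterable[FieldDocument], fp) -> int:
    """Write field documents as newline-delimited JSON; returns the count."""
    n = 0
    for doc in documents:
        fp.write(json.dumps(doc.to_dict(), ensure_ascii=False) + "\n")
        n += 1
    return n


def read_ndjson(fp) -> list[FieldDocument]:
    return [FieldDocument.from_dict(json.loads(line)) for line in fp if line.strip()]
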