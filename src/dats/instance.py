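"""In-memory DATS instances: a typed tree of entities rooted at a Dataset.

Structured values (annotations, identifiers, dated events, intervals, open
category/values pairs) are small dataclasses; entities are
:class:`DatsEntity` nodes whose ``properties`` dict is keyed by registry
property names.  Referenced entities are embedded as subtrees — the model is
a tree, not a graph, which keeps validation paths and round-trips simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Optional

from .registry import EntityRegistry, build_core_registry


@dataclass
class Annotation:
    """A controlled-vocabulary term: human-readable value + optional term IRI."""

    value: str
    valueIRI: Optional[str] = None


@dataclass
class Identifier:
    """A structured identifier (DOI, accession, ...) with its issuing scheme."""

    identifier: str
    identifierSource: Optional[str] = None


@dataclass
class EventDate:
    """An ISO-8601 date (any precision: YYYY / YYYY-MM / YYYY-MM-DD) with a
    type annotation saying what the date marks (creation, release, ...)."""

    date: str
    type: Optional[Annotation] = None


@dataclass
class DateInterval:
    """A possibly open ISO-8601 interval; start <= end when both present."""

    start: Optional[str] = None
    end: Optional[str] = None


@dataclass
class ExtraProperty:
    """Open-world escape hatch: a category with a list of values."""

    category: str
    values: list = field(default_factory=list)


class DatsEntity:
    """A node of the instance tree, typed by a registry entity name.

    ``properties`` holds recognized, typed values; ``unknown`` carries raw
    JSON of unrecognized keys (warn-and-carry policy: the model is
    extensible, so unknown detail is preserved, never dropped).  ``aliases``
    records read-time spelling normalizations applied at this node.
    ``explicit_type`` remembers whether the source document carried an
    explicit ``@type`` so that serialization is lossless; it does not take
    part in equality.
    """

    __slots__ = ("entity", "properties", "unknown", "aliases", "explicit_type")

    def __init__(self, entity: str, /, **properties: Any) -> None:
        self.entity = entity
        self.properties: dict[str, Any] = dict(properties)
        self.unknown: dict[str, Any] = {}
        self.aliases: list[str] = []
        self.explicit_type: bool = False

    def __getitem__(self, prop: str) -> Any:
        return self.properties[prop]

    def get(self, prop: str, default: Any = None) -> Any:
        return self.properties.get(prop, default)

    def __setitem__(self, prop: str, value: Any) -> None:
        self.properties[prop] = value

    def __contains__(self, prop: str) -> bool:
        return prop in self.properties

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DatsEntity)
            and self.entity == other.entity
            and self.properties == other.properties
            and self.unknown == other.unknown
        )

    def __repr__(self) -> str:
        keys = ", ".join(self.properties)
        return f"DatsEntity({self.entity!r}: {keys})"


#: Alias for the tree rooted at a Dataset node.
DatsInstance = DatsEntity


def dataset(**properties: Any) -> DatsEntity:
    return DatsEntity("Dataset", **properties)


def person(full_name: str, **properties: Any) -> DatsEntity:
    return DatsEntity("Person", fullName=full_name, **properties)


def organization(name: str, **properties: Any) -> DatsEntity:
    return DatsEntity("Organization", name=name, **properties)


def is_empty(value: Any) -> bool:
    """Emptiness for requirement checking: empty text and empty collections
    count as absent; a structured node counts as present even if its own
    fields are empty (its inner gaps are reported at their own paths)."""
    if value is None:
        return True
    if isinstance(value, str):
        return not value.strip()
    if isinstance(value, (list, tuple, dict)):
        return len(value) == 0
    return False


def walk_entities(
    node: DatsEntity, path: Optional[str] = None
) -> Iterator[tuple[str, DatsEntity]]:
    """Yield (path, node) for every entity node in document order.

    Paths are slash-delimited and rooted at the entity name, e.g.
    ``Dataset/distributions/0/access``.  Structured dataclass values
    (Annotation, Identifier, ...) are not entity nodes and are not yielded.
    """
    path = node.entity if path is None else path
    yield path, node
    for prop, value in node.properties.items():
        items = value if isinstance(value, list) else [value]
        for i, item in enumerate(items):
            if isinstance(item, DatsEntity):
                sub = f"{path}/{prop}/{i}" if isinstance(value, list) else f"{path}/{prop}"
                yield from walk_entities(item, sub)


def iter_leaves(node: DatsEntity, path: Optional[str] = None) -> Iterator[tuple[str, str, Any]]:
    """Yield (owning entity name, path, scalar value) for every populated leaf.

    A leaf is any scalar inside ``properties``, including the fields of
    structured values.  Unknown (carried) raw values are walked too so that
    nothing populated escapes accounting.
    """
    path = node.entity if path is None else path

    def scalars(value: Any, at: str, owner: str) -> Iterator[tuple[str, str, Any]]:
        if value is None:
            return
        if isinstance(value, DatsEntity):
            yield from iter_leaves(value, at)
        elif isinstance(value, Annotation):
            if value.value:
                yield owner, f"{at}/value", value.value
            if value.valueIRI:
                yield owner, f"{at}/valueIRI", value.valueIRI
        elif isinstance(value, Identifier):
            if value.identifier:
                yield owner, f"{at}/identifier", value.identifier
            if value.identifierSource:
                yield owner, f"{at}/identifierSource", value.identifierSource
        elif isinstance(value, EventDate):
            if value.date:
                yield owner, f"{at}/date", value.date
            if value.type is not None:
                yield from scalars(value.type, f"{at}/type", owner)
        elif isinstance(value, DateInterval):
            if value.start:
                yield owner, f"{at}/start", value.start
            if value.end:
                yield owner, f"{at}/end", value.end
        elif isinstance(value, ExtraProperty):
            if value.category:
                yield owner, f"{at}/category", value.category
            for j, v in enumerate(value.values):
                yield from scalars(v, f"{at}/values/{j}", owner)
        elif isinstance(value, list):
            for j, item in enumerate(value):
                yield from scalars(item, f"{at}/{j}", owner)
        elif isinstance(value, dict):
            for k, v in value.items():
                yield from scalars(v, f"{at}/{k}", owner)
        else:  # text / number / bool
            if not (isinstance(value, str) and not value.strip()):
                yield owner, at, value

    for prop, value in node.properties.items():
        yield from scalars(value, f"{path}/{prop}", node.entity)
    for key, value in node.unknown.items():
        yield from scalars(value, f"{path}/{key}", node.entity)


def resolve_union(
    doc: Any, alternatives: tuple[str, ...], registry: Optional[EntityRegistry] = None
) -> str:
    """Decide which union alternative a raw JSON value belongs to.

    An explicit ``@type`` wins.  Otherwise alternatives are scored by how many
    of the document's keys they declare; ties break in declaration order, so
    the first alternative is the default (e.g. an all-ambiguous creator is a
    Person, never a fabricated Organization).  ``Annotation`` wins for plain
    strings and for ``{value, valueIRI}``-shaped mappings.
    """
    registry = registry or build_core_registry()
    if isinstance(doc, str):
        return "Annotation" if "Annotation" in alternatives else alternatives[0]
    if isinstance(doc, dict) and "@type" in doc:
        declared = registry.canonical_entity(str(doc["@type"]))
        if declared in alternatives:
            return declared
        return declared  # caller validates against the registry
    best, best_score = alternatives[0], -1
    for alt in alternatives:
        if alt == "Annotation":
            keys = {"value", "valueIRI"}
        else:
            ent = registry.get(alt)
            keys = set(ent.properties) if ent else set()
        score = len(keys & set(doc)) if isinstance(doc, dict) else 0
        if score > best_score:
            best, best_score = alt, score
    return best
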