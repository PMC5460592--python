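"""Plain-JSON serialization of DATS instances.

Writing follows the Google JSON style used by the model: lowerCamelCase keys,
deterministic key order (registry declaration order), and empty optional
values omitted — presence of a key equals presence of a value.  Reading is
lossless: recognized fields are typed, unknown fields are carried verbatim,
and the historical ``Licence``/``licences`` spellings are normalized to
``License``/``licenses`` with the alias recorded on the node.
"""

from __future__ import annotations

import json
from typing import Any, Optional, Union

from ._errors import FormatError, StructuralError
from .instance import (
    Annotation,
    DateInterval,
    DatsEntity,
    EventDate,
    ExtraProperty,
    Identifier,
    is_empty,
    resolve_union,
)
from .registry import (
    PROPERTY_ALIASES,
    EntityRegistry,
    ValueKind,
    build_core_registry,
)

__all__ = ["read_instance", "write_instance", "dumps", "loads"]


# ---------------------------------------------------------------------------
# writing

def _write_value(value: Any, jsonld: bool, registry: EntityRegistry) -> Any:
    if isinstance(value, DatsEntity):
        return _write_entity(value, None, jsonld, registry)
    if isinstance(value, Annotation):
        doc: dict[str, Any] = {}
        if jsonld:
            doc["@type"] = "Annotation"
            if value.valueIRI:
                doc["@id"] = value.valueIRI
            doc["value"] = value.value
        else:
            doc["value"] = value.value
            if value.valueIRI:
                doc["valueIRI"] = value.valueIRI
        return doc
    if isinstance(value, Identifier):
        doc = {"@type": "Identifier"} if jsonld else {}
        doc["identifier"] = value.identifier
        if value.identifierSource:
            doc["identifierSource"] = value.identifierSource
        return doc
    if isinstance(value, EventDate):
        doc = {"@type": "EventDate"} if jsonld else {}
        doc["date"] = value.date
        if value.type is not None:
            doc["type"] = _write_value(value.type, jsonld, registry)
        return doc
    if isinstance(value, DateInterval):
        doc = {"@type": "DateInterval"} if jsonld else {}
        if value.start:
            doc["start"] = value.start
        if value.end:
            doc["end"] = value.end
        return doc
    if isinstance(value, ExtraProperty):
        doc = {"@type": "ExtraProperty"} if jsonld else {}
        doc["category"] = value.category
        if value.values:
            doc["values"] = [_write_value(v, jsonld, registry) for v in value.values]
        return doc
    if isinstance(value, list):
        return [_write_value(v, jsonld, registry) for v in value]
    return value


def _write_entity(
    node: DatsEntity,
    union: Optional[tuple[str, ...]],
    jsonld: bool,
    registry: EntityRegistry,
) -> dict:
    descriptor = registry.get(node.entity)
    if descriptor is None:
        raise StructuralError(f"cannot write unknown entity {node.entity!r}")
    body: dict[str, Any] = {}
    for prop, pdesc in descriptor.properties.items():
        value = node.get(prop)
        if is_empty(value):
            continue
        if pdesc.kind.base == "ref" and not pdesc.kind.is_list \
                and isinstance(value, DatsEntity):
            body[prop] = _write_entity(value, pdesc.kind.targets, jsonld, registry)
        elif pdesc.kind.base == "ref" and pdesc.kind.is_list:
            body[prop] = [
                _write_entity(v, pdesc.kind.targets, jsonld, registry)
                if isinstance(v, DatsEntity)
                else _write_value(v, jsonld, registry)
                for v in value
            ]
        else:
            body[prop] = _write_value(value, jsonld, registry)
    # carried unknown keys, after the declared ones
    for key, raw in node.unknown.items():
        body[key] = raw

    need_type = jsonld or node.explicit_type
    if not need_type and union and len(union) > 1:
        # emit @type whenever a bare read-back would resolve elsewhere
        need_type = resolve_union(body, union, registry) != node.entity
    if need_type:
        head: dict[str, Any] = {"@type": node.entity}
        if jsonld:
            ident = node.get("identifier")
            from .validation import is_absolute_iri  # local to avoid cycle
            if isinstance(ident, Identifier) and is_absolute_iri(ident.identifier):
                head["@id"] = ident.identifier
        head.update(body)
        return head
    return body


def write_instance(
    instance: DatsEntity,
    registry: Optional[EntityRegistry] = None,
    *,
    _jsonld: bool = False,
) -> dict:
    """Serialize an instance to a JSON tree (no I/O, no context)."""
    registry = registry or build_core_registry()
    return _write_entity(instance, None, _jsonld, registry)


def dumps(instance: DatsEntity, registry: Optional[EntityRegistry] = None, **kwargs) -> str:
    kwargs.setdefault("indent", 2)
    kwargs.setdefault("ensure_ascii", False)
    return json.dumps(write_instance(instance, registry), **kwargs)


# ---------------------------------------------------------------------------
# reading

def _as_text(raw: Any) -> str:
    return raw if isinstance(raw, str) else str(raw)


def _read_annotation(raw: Any) -> Annotation:
    if isinstance(raw, dict):
        return Annotation(
            value=_as_text(raw.get("value", "")),
            valueIRI=raw.get("valueIRI") or raw.get("@id"),
        )
    return Annotation(value=_as_text(raw))


def _read_identifier(raw: Any) -> Identifier:
    if isinstance(raw, dict):
        return Identifier(
            identifier=_as_text(raw.get("identifier", "")),
            identifierSource=raw.get("identifierSource"),
        )
    return Identifier(identifier=_as_text(raw))


def _coerce(raw: Any, kind: ValueKind, registry: EntityRegistry, where: str) -> Any:
    if kind.is_list:
        items = raw if isinstance(raw, list) else [raw]
        inner = ValueKind(kind.base, kind.targets, False)
        return [_coerce(item, inner, registry, where) for item in items]
    base = kind.base
    if base in {"text", "date", "iri"}:
        return raw if isinstance(raw, str) else _as_text(raw)
    if base == "number":
        return raw
    if base == "Annotation":
        return _read_annotation(raw)
    if base == "Identifier":
        return _read_identifier(raw)
    if base == "eventDate":
        if isinstance(raw, dict):
            type_raw = raw.get("type")
            return EventDate(
                date=_as_text(raw.get("date", "")),
                type=_read_annotation(type_raw) if type_raw is not None else None,
            )
        return EventDate(date=_as_text(raw))
    if base == "dateInterval":
        if isinstance(raw, dict):
            return DateInterval(start=raw.get("start"), end=raw.get("end"))
        raise FormatError(f"{where}: date interval must be an object with start/end")
    if base == "extraProperty":
        if isinstance(raw, dict):
            category = raw.get("category", "")
            if isinstance(category, dict):
                category = category.get("value", "")
            values = raw.get("values", [])
            return ExtraProperty(
                category=_as_text(category),
                values=list(values) if isinstance(values, list) else [values],
            )
        raise FormatError(f"{where}: extra property must be an object")
    if base == "ref":
        target = resolve_union(raw, kind.targets, registry)
        target = registry.canonical_entity(target)
        if target == "Annotation":
            return _read_annotation(raw)
        if target not in registry:
            raise FormatError(f"{where}: unknown entity type {target!r}")
        if not isinstance(raw, dict):
            raise FormatError(f"{where}: expected an object for {target}, got {type(raw).__name__}")
        return _read_entity(raw, target, registry)
    raise FormatError(f"{where}: unhandled kind {base!r}")  # pragma: no cover


def _read_entity(doc: dict, entity: str, registry: EntityRegistry) -> DatsEntity:
    descriptor = registry[entity]
    node = DatsEntity(entity)
    node.explicit_type = "@type" in doc
    for key, raw in doc.items():
        if key in {"@type", "@id", "@context"}:
            if key == "@id" and "identifier" in descriptor.properties \
                    and "identifier" not in doc:
                node["identifier"] = Identifier(identifier=_as_text(raw))
            continue
        prop = key
        if key not in descriptor.properties and key in PROPERTY_ALIASES:
            canonical = PROPERTY_ALIASES[key]
            if canonical in descriptor.properties:
                prop = canonical
                node.aliases.append(f"{key}->{canonical}")
        if prop in descriptor.properties:
            node[prop] = _coerce(raw, descriptor.properties[prop].kind, registry,
                                 f"{entity}.{prop}")
        else:
            node.unknown[key] = raw
    return node


def loads(text: str) -> Any:
    """Parse JSON text; malformed input raises with line/column position."""
    return json.loads(text)


def read_instance(
    document: Union[str, dict],
    entity: str = "Dataset",
    registry: Optional[EntityRegistry] = None,
) -> DatsEntity:
    """Read a JSON document (text or parsed tree) into a typed instance.

    Parsing never enforces requirement levels — a document with only a title
    parses fine; the MUST gap is validation's business, not the reader's.
    """
    registry = registry or build_core_registry()
    if isinstance(document, (str, bytes)):
        document = loads(document)
    if not isinstance(document, dict):
        raise StructuralError("instance document root must be a JSON object")
    if "@type" in document:
        entity = registry.canonical_entity(str(document["@type"]))
    else:
        entity = registry.canonical_entity(entity)
    if entity not in registry:
        raise StructuralError(f"root entity {entity!r} is not in the registry")
    return _read_entity(document, entity, registry)
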