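"""Schema.org-annotated JSON-LD serialization.

The wire format is the plain JSON serialization plus linked-data plumbing:
an ``@context`` binding every DATS term to a Schema.org IRI (or, where
Schema.org has no counterpart, to a DATS namespace IRI), ``@type`` on every
node so that type-scoped term definitions apply, and ``@id`` minted from the
identifier when it is itself an IRI.  Annotations put their term IRI in
``@id``.

The term correspondence is a versioned data file (`schemaorg_mapping.yaml`),
never hard-coded: Schema.org evolves, and the gaps in its coverage are part
of the record — every core term is either mapped or explicitly listed as
unmapped with a reason.

Expansion and compaction are implemented here for exactly the profile this
serializer emits: prefix definitions, global type terms, type-scoped property
terms, arrays as unordered sets, plain literals.  They are not a general
JSON-LD processor; emitted documents are nevertheless valid JSON-LD 1.1 and
can be parsed by any conformant processor (the test suite checks this
independently with rdflib).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from ._errors import FormatError, MappingError
from .instance import DatsEntity
from .registry import EntityRegistry, build_core_registry
from .serialization import read_instance, write_instance

#: Structured value types that travel as typed nodes alongside the entities.
VALUE_TYPES = ("Annotation", "Identifier", "EventDate", "DateInterval", "ExtraProperty")
_VALUE_TYPE_PROPS = {
    "Annotation": ("value",),
    "Identifier": ("identifier", "identifierSource"),
    "EventDate": ("date", "type"),
    "DateInterval": ("start", "end"),
    "ExtraProperty": ("category", "values"),
}


@dataclass
class MappingTable:
    """DATS term -> IRI correspondence driving context emission."""

    name: str
    version: str
    namespaces: dict[str, str]
    type_iris: dict[str, str]                  # type term -> IRI
    property_iris: dict[str, dict[str, str]]   # type term -> prop term -> IRI
    unmapped: list[dict] = field(default_factory=list)

    @property
    def schemaorg_ns(self) -> str:
        return self.namespaces["sdo"]

    @property
    def dats_ns(self) -> str:
        return self.namespaces["dats"]

    def curie(self, iri: str) -> str:
        for prefix, ns in self.namespaces.items():
            if iri.startswith(ns):
                return f"{prefix}:{iri[len(ns):]}"
        return iri

    def context(self) -> dict:
        """The JSON-LD 1.1 ``@context``: prefixes plus type-scoped terms."""
        ctx: dict[str, Any] = dict(self.namespaces)
        for type_term, iri in self.type_iris.items():
            entry: dict[str, Any] = {"@id": self.curie(iri)}
            scoped = self.property_iris.get(type_term)
            if scoped:
                entry["@context"] = {p: self.curie(i) for p, i in scoped.items()}
            ctx[type_term] = entry
        return ctx

    def type_iri(self, term: str) -> str:
        return self.type_iris.get(term, self.dats_ns + term)

    def property_iri(self, scope: Optional[str], term: str) -> str:
        if scope and term in self.property_iris.get(scope, {}):
            return self.property_iris[scope][term]
        if ":" in term:  # already a curie or IRI
            return self._expand_curie(term)
        return self.dats_ns + term

    def _expand_curie(self, token: str) -> str:
        prefix, _, local = token.partition(":")
        if prefix in self.namespaces:
            return self.namespaces[prefix] + local
        return token

    # inverse maps -------------------------------------------------------

    @property
    def inv_types(self) -> dict[str, str]:
        return {iri: term for term, iri in self.type_iris.items()}

    def inv_property(self, scope: Optional[str], iri: str) -> Optional[str]:
        if scope:
            for term, candidate in self.property_iris.get(scope, {}).items():
                if candidate == iri:
                    return term
        return None


def _load_mapping_doc(doc: Mapping, registry: EntityRegistry) -> MappingTable:
    namespaces = dict(doc.get("namespaces") or {})
    for required in ("sdo", "dats"):
        if required not in namespaces:
            raise MappingError(f"mapping must declare the {required!r} namespace")

    def expand(token: str, where: str) -> str:
        prefix, sep, local = str(token).partition(":")
        if sep and prefix in namespaces:
            return namespaces[prefix] + local
        if str(token).startswith(("http://", "https://", "urn:")):
            return str(token)
        raise MappingError(f"{where}: {token!r} is neither an absolute IRI nor a known curie")

    mapped_terms: set[str] = set()
    type_iris: dict[str, str] = {}
    for term, target in (doc.get("entities") or {}).items():
        type_iris[term] = expand(target, f"entities.{term}")
        mapped_terms.add(term)
    seen_iris: dict[str, str] = {}
    for term, iri in type_iris.items():
        if iri in seen_iris:
            raise MappingError(
                f"entities {seen_iris[iri]!r} and {term!r} both map to {iri} "
                "(type IRIs must be invertible)"
            )
        seen_iris[iri] = term
    # unmapped entities and value types fall back to the DATS namespace
    for name in tuple(registry.entity_names) + VALUE_TYPES:
        type_iris.setdefault(name, namespaces["dats"] + name)

    property_iris: dict[str, dict[str, str]] = {}
    declared = doc.get("properties") or {}
    for scope, props in declared.items():
        property_iris[scope] = {
            p: expand(t, f"properties.{scope}.{p}") for p, t in (props or {}).items()
        }
        mapped_terms.update(f"{scope}.{p}" for p in (props or {}))
    # complete every scope so the emitted context is total
    for name in registry.entity_names:
        scoped = property_iris.setdefault(name, {})
        for prop in registry[name].properties:
            scoped.setdefault(prop, namespaces["dats"] + prop)
    for vt, props in _VALUE_TYPE_PROPS.items():
        scoped = property_iris.setdefault(vt, {})
        for prop in props:
            scoped.setdefault(prop, namespaces["dats"] + prop)
    for scope, scoped in property_iris.items():
        inverse: dict[str, str] = {}
        for term, iri in scoped.items():
            if iri in inverse:
                raise MappingError(
                    f"scope {scope}: {inverse[iri]!r} and {term!r} both map to {iri}"
                )
            inverse[iri] = term

    unmapped = [dict(u) for u in (doc.get("unmapped") or [])]
    unmapped_terms = [u["term"] for u in unmapped]
    if len(set(unmapped_terms)) != len(unmapped_terms):
        raise MappingError("duplicate terms in the unmapped list")
    twice = mapped_terms & set(unmapped_terms)
    if twice:
        raise MappingError(f"terms both mapped and unmapped: {sorted(twice)}")

    return MappingTable(
        name=doc.get("name", "inline"),
        version=str(doc.get("version", "")),
        namespaces=namespaces,
        type_iris=type_iris,
        property_iris=property_iris,
        unmapped=unmapped,
    )


def load_mapping(
    source=None, registry: Optional[EntityRegistry] = None
) -> MappingTable:
    """Load a mapping table (default: the shipped Schema.org mapping)."""
    registry = registry or build_core_registry()
    if source is None:
        text = resources.files("dats").joinpath(
            "schemas", "schemaorg_mapping.yaml").read_text("utf-8")
        doc = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        doc = source
    else:
        doc = yaml.safe_load(Path(source).read_text("utf-8"))
    return _load_mapping_doc(doc, registry)


@lru_cache(maxsize=1)
def _default_mapping() -> MappingTable:
    return load_mapping()


def mapping_totality(
    mapping: Optional[MappingTable] = None,
    registry: Optional[EntityRegistry] = None,
) -> dict[str, list[str]]:
    """Account for every core registry term: mapped, unmapped, or missing.

    ``missing`` should always be empty for the shipped mapping — no silent
    omissions.
    """
    registry = registry or build_core_registry()
    mapping = mapping or _default_mapping()
    unmapped = {u["term"] for u in mapping.unmapped}
    dats_ns = mapping.dats_ns
    mapped: list[str] = []
    missing: list[str] = []
    for name in registry.entity_names:
        if not mapping.type_iri(name).startswith(dats_ns):
            mapped.append(name)
        elif name not in unmapped:
            missing.append(name)
        for prop in registry[name].properties:
            term = f"{name}.{prop}"
            iri = mapping.property_iri(name, prop)
            if not iri.startswith(dats_ns):
                mapped.append(term)
            elif term not in unmapped:
                missing.append(term)
    return {"mapped": mapped, "unmapped": sorted(unmapped), "missing": missing}


# ---------------------------------------------------------------------------
# emission

def to_jsonld(
    instance: DatsEntity,
    mapping: Optional[MappingTable] = None,
    registry: Optional[EntityRegistry] = None,
) -> dict:
    """Emit the Schema.org-annotated JSON-LD document for an instance."""
    registry = registry or build_core_registry()
    mapping = mapping or _default_mapping()
    body = write_instance(instance, registry, _jsonld=True)
    return {"@context": mapping.context(), **body}


def mapping_gaps(
    document: dict, mapping: Optional[MappingTable] = None
) -> list[str]:
    """Terms in an emitted document that fall back to the DATS namespace."""
    mapping = mapping or _default_mapping()
    gaps: set[str] = set()

    def visit(node: Any, scope: Optional[str]) -> None:
        if isinstance(node, list):
            for item in node:
                visit(item, scope)
            return
        if not isinstance(node, dict):
            return
        node_scope = node.get("@type", scope)
        if "@type" in node and mapping.type_iri(node["@type"]).startswith(mapping.dats_ns):
            gaps.add(node["@type"])
        for key, value in node.items():
            if key.startswith("@"):
                continue
            if mapping.property_iri(node_scope, key).startswith(mapping.dats_ns):
                gaps.add(f"{node_scope}.{key}" if node_scope else key)
            visit(value, None)

    visit({k: v for k, v in document.items() if k != "@context"}, None)
    return sorted(gaps)


# ---------------------------------------------------------------------------
# expansion / compaction (minimal, mapping-aware)

def expand(document: dict, mapping: Optional[MappingTable] = None) -> dict:
    """Replace every term with its IRI, using type-scoped definitions.

    Documents without a usable context are interpreted against a default
    ``@vocab`` of the Schema.org namespace, which is how plain Schema.org
    ``Dataset`` nodes enter the toolkit.
    """
    mapping = mapping or _default_mapping()
    ctx = document.get("@context")
    use_vocab = not isinstance(ctx, dict)  # string / missing context

    def type_to_iri(term: str) -> str:
        if term.startswith(("http://", "https://", "urn:")):
            return term
        if use_vocab:
            if ":" in term:
                return mapping._expand_curie(term)
            return mapping.schemaorg_ns + term
        return mapping.type_iri(term)

    def prop_to_iri(scope: Optional[str], term: str) -> str:
        if term.startswith(("http://", "https://", "urn:")):
            return term
        if use_vocab:
            if ":" in term:
                return mapping._expand_curie(term)
            return mapping.schemaorg_ns + term
        return mapping.property_iri(scope, term)

    def visit(node: Any) -> Any:
        if isinstance(node, list):
            return [visit(item) for item in node]
        if not isinstance(node, dict):
            return node
        out: dict[str, Any] = {}
        scope = node.get("@type")
        for key, value in node.items():
            if key == "@context":
                continue
            if key == "@type":
                out["@type"] = type_to_iri(value)
            elif key == "@id":
                out["@id"] = value
            else:
                out[prop_to_iri(scope, key)] = visit(value)
        return out

    expanded = visit(document)
    if not isinstance(expanded, dict):
        raise FormatError("JSON-LD document root must be a node object")
    return expanded


def compact(expanded: dict, mapping: Optional[MappingTable] = None) -> dict:
    """Inverse of :func:`expand` on its image; re-attaches the context."""
    mapping = mapping or _default_mapping()
    inv_types = mapping.inv_types

    def local_or_curie(iri: str) -> str:
        if iri.startswith(mapping.dats_ns):
            return iri[len(mapping.dats_ns):]
        curie = mapping.curie(iri)
        return curie

    def visit(node: Any) -> Any:
        if isinstance(node, list):
            return [visit(item) for item in node]
        if not isinstance(node, dict):
            return node
        out: dict[str, Any] = {}
        scope = None
        if "@type" in node:
            scope = inv_types.get(node["@type"], local_or_curie(node["@type"]))
        for key, value in node.items():
            if key == "@type":
                out["@type"] = scope
            elif key == "@id":
                out["@id"] = value
            else:
                term = mapping.inv_property(scope, key) or local_or_curie(key)
                out[term] = visit(value)
        return out

    body = visit(expanded)
    return {"@context": mapping.context(), **body}


def schemaorg_view(expanded: dict, mapping: Optional[MappingTable] = None) -> dict:
    """Compact an expanded document against a bare Schema.org vocabulary.

    Schema.org IRIs become local names, DATS-namespace IRIs become
    ``dats:`` curies, anything else stays absolute.  This is the shape the
    Schema.org crosswalk consumes.
    """
    mapping = mapping or _default_mapping()
    sdo, dats = mapping.schemaorg_ns, mapping.dats_ns

    def shorten(iri: str) -> str:
        if iri.startswith(sdo):
            return iri[len(sdo):]
        if iri.startswith(dats):
            return "dats:" + iri[len(dats):]
        return iri

    def visit(node: Any) -> Any:
        if isinstance(node, list):
            return [visit(item) for item in node]
        if not isinstance(node, dict):
            return node
        out = {}
        for key, value in node.items():
            if key == "@type":
                out["@type"] = shorten(value)
            elif key.startswith("@"):
                out[key] = value
            else:
                out[shorten(key)] = visit(value)
        return out

    return visit(expanded)


def from_jsonld(
    document: Union[str, dict],
    mapping: Optional[MappingTable] = None,
    registry: Optional[EntityRegistry] = None,
) -> DatsEntity:
    """Read a JSON-LD document into a typed instance.

    Inverse of :func:`to_jsonld` on its image.  Plain Schema.org ``Dataset``
    nodes (string or absent context) are interpreted through the mapping's
    inverse; Schema.org terms outside the mapping are carried verbatim as
    unknown properties.
    """
    registry = registry or build_core_registry()
    mapping = mapping or _default_mapping()
    if isinstance(document, (str, bytes)):
        import json
        document = json.loads(document)
    if not isinstance(document, dict):
        raise FormatError("JSON-LD document root must be a node object")
    expanded = expand(document, mapping)
    if "@type" not in expanded:
        raise FormatError("JSON-LD node has no @type; cannot determine the entity")
    root_iri = expanded["@type"]
    root_term = mapping.inv_types.get(root_iri)
    if root_term is None and root_iri.startswith(mapping.dats_ns):
        root_term = root_iri[len(mapping.dats_ns):]
    root_term = registry.canonical_entity(root_term) if root_term else None
    if root_term not in registry:
        raise FormatError(f"unknown @type {root_iri!r}")
    compacted = compact(expanded, mapping)
    compacted.pop("@context", None)
    instance = read_instance(compacted, root_term, registry)
    # @type is serialization plumbing here, not document content: the plain
    # JSON writer should not re-emit it
    from .instance import walk_entities
    for _, node in walk_entities(instance):
        node.explicit_type = False
    return instance
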