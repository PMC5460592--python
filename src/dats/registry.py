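"""Entity registry and requirement-level profiles for the DATS core model.

The DATS model is described by *descriptors*: each entity has a name, a
definition and a set of properties; each property has a value kind (text,
number, date, a structured annotation or identifier, a reference to another
entity, or a collection of any of these).  The registry is loaded from a
versioned YAML data file so the roster can be corrected against a model
release without code change.

Requirement levels follow RFC 2119: a profile assigns MUST / SHOULD / MAY to
(entity, property) pairs.  Entities themselves are never mandatory — they are
applicable only if relevant — but when an entity is used, its MUST properties
must be present and non-empty.  The shipped default profile covers the 18 core
entities and carries exactly 10 MUST entries.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from ._errors import ProfileError, RegistryError

_UPPER_CAMEL = re.compile(r"^[A-Z][A-Za-z0-9]*$")
_LOWER_CAMEL = re.compile(r"^[a-z][A-Za-z0-9]*$")

#: Scalar / structured value kinds understood by the model.
SCALAR_KINDS = frozenset(
    {"text", "number", "date", "iri", "Annotation", "Identifier",
     "eventDate", "dateInterval", "extraProperty"}
)

#: Read-time aliases, normalized on ingestion (recorded, never emitted).
ENTITY_ALIASES = {"Licence": "License"}
PROPERTY_ALIASES = {"licences": "licenses", "licence": "licenses"}


@dataclass(frozen=True)
class ValueKind:
    """Parsed value kind of a property.

    ``base`` is one of :data:`SCALAR_KINDS` or ``"ref"``; for references,
    ``targets`` lists the admissible entity names (``Annotation`` may appear
    in a union as an inline controlled-vocabulary alternative).  ``is_list``
    marks collection-valued properties.
    """

    base: str
    targets: tuple[str, ...] = ()
    is_list: bool = False

    @classmethod
    def parse(cls, token: str) -> "ValueKind":
        token = token.strip()
        is_list = False
        if token.startswith("list[") and token.endswith("]"):
            token, is_list = token[5:-1].strip(), True
        if token.startswith("ref:"):
            targets = tuple(t.strip() for t in token[4:].split("|"))
            if not all(targets):
                raise RegistryError(f"empty reference target in kind {token!r}")
            return cls("ref", targets, is_list)
        if token not in SCALAR_KINDS:
            raise RegistryError(f"unknown value kind {token!r}")
        return cls(token, (), is_list)

    def __str__(self) -> str:
        inner = "ref:" + "|".join(self.targets) if self.base == "ref" else self.base
        return f"list[{inner}]" if self.is_list else inner


@dataclass(frozen=True)
class PropertyDescriptor:
    name: str
    kind: ValueKind
    definition: str = ""
    allowed_values: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class EntityDescriptor:
    name: str
    definition: str = ""
    properties: Mapping[str, PropertyDescriptor] = field(default_factory=dict)

    def __post_init__(self):
        if not _UPPER_CAMEL.match(self.name):
            raise RegistryError(f"entity name {self.name!r} is not UpperCamelCase")
        for pname in self.properties:
            if not _LOWER_CAMEL.match(pname):
                raise RegistryError(
                    f"property name {self.name}.{pname!r} is not lowerCamelCase"
                )


class EntityRegistry:
    """Mapping of entity name -> descriptor, with a core/extended partition."""

    def __init__(self) -> None:
        self._entities: dict[str, EntityDescriptor] = {}
        self._core: set[str] = set()
        self.version: str = ""
        self.name: str = ""

    def register(self, descriptor: EntityDescriptor, core: bool = False) -> None:
        if descriptor.name in self._entities:
            raise RegistryError(f"duplicate entity {descriptor.name!r}")
        self._entities[descriptor.name] = descriptor
        if core:
            self._core.add(descriptor.name)

    def __contains__(self, name: str) -> bool:
        return name in self._entities

    def __getitem__(self, name: str) -> EntityDescriptor:
        try:
            return self._entities[name]
        except KeyError:
            raise KeyError(f"unknown entity {name!r}") from None

    def get(self, name: str) -> Optional[EntityDescriptor]:
        return self._entities.get(name)

    def __iter__(self) -> Iterable[str]:
        return iter(self._entities)

    @property
    def entity_names(self) -> tuple[str, ...]:
        return tuple(self._entities)

    @property
    def core_names(self) -> tuple[str, ...]:
        return tuple(n for n in self._entities if n in self._core)

    def canonical_entity(self, name: str) -> str:
        """Resolve read-time aliases (``Licence`` -> ``License``)."""
        return ENTITY_ALIASES.get(name, name)

    def check_closure(self) -> None:
        """Every entity-reference target must exist (Annotation is inline)."""
        for ent in self._entities.values():
            for prop in ent.properties.values():
                for target in prop.kind.targets:
                    if target != "Annotation" and target not in self._entities:
                        raise RegistryError(
                            f"{ent.name}.{prop.name} references unknown "
                            f"entity {target!r}"
                        )


def _data_text(relpath: str) -> str:
    return resources.files("dats").joinpath("schemas", relpath).read_text("utf-8")


def _build_registry(doc: Mapping, core: bool) -> EntityRegistry:
    registry = EntityRegistry()
    registry.name = doc.get("name", "")
    registry.version = str(doc.get("version", ""))
    for ent in doc.get("entities", []):
        props = {}
        for p in ent.get("properties", []):
            allowed = p.get("allowedValues")
            props[p["name"]] = PropertyDescriptor(
                name=p["name"],
                kind=ValueKind.parse(p["kind"]),
                definition=p.get("definition", ""),
                allowed_values=tuple(allowed) if allowed else None,
            )
        registry.register(
            EntityDescriptor(ent["name"], ent.get("definition", ""), props),
            core=core,
        )
    registry.check_closure()
    return registry


@lru_cache(maxsize=1)
def build_core_registry() -> EntityRegistry:
    """Load the shipped core registry (18 entities) from package data."""
    return _build_registry(yaml.safe_load(_data_text("core_registry.yaml")), core=True)


def core_entity_count(registry: Optional[EntityRegistry] = None) -> int:
    """Number of *core* entity descriptors in the registry."""
    registry = registry or build_core_registry()
    return len(registry.core_names)


class Level(enum.IntEnum):
    """RFC 2119 requirement level; higher value = stricter."""

    MAY = 1
    SHOULD = 2
    MUST = 3

    @classmethod
    def parse(cls, token: str) -> "Level":
        try:
            return cls[str(token).upper()]
        except KeyError:
            raise ProfileError(f"unknown requirement level {token!r}") from None


@dataclass
class RequirementProfile:
    """Entity -> property -> requirement level, resolved against a registry."""

    name: str
    version: str
    levels: dict[str, dict[str, Level]]
    registry: EntityRegistry

    def level_of(self, entity: str, prop: str) -> Optional[Level]:
        return self.levels.get(entity, {}).get(prop)

    def entries(self) -> list[tuple[str, str, Level]]:
        return [
            (ent, prop, level)
            for ent, props in self.levels.items()
            for prop, level in props.items()
        ]

    def must_entries(self) -> list[tuple[str, str]]:
        return [(e, p) for e, p, lvl in self.entries() if lvl is Level.MUST]


def load_profile(source=None, registry: Optional[EntityRegistry] = None) -> RequirementProfile:
    """Load and resolve a requirement profile.

    ``source`` may be None (shipped default), a mapping, a YAML/JSON string,
    or a path to a profile file.  Every entry is resolved against the
    registry; unknown entities, properties or level tokens raise
    :class:`ProfileError` naming the offending entry.
    """
    registry = registry or build_core_registry()
    if source is None:
        doc = yaml.safe_load(_data_text("default_profile.yaml"))
    elif isinstance(source, Mapping):
        doc = source
    elif isinstance(source, (str, Path)) and Path(str(source)).suffix in {".yaml", ".yml", ".json"}:
        doc = yaml.safe_load(Path(source).read_text("utf-8"))
    else:
        doc = yaml.safe_load(str(source))
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ProfileError("profile document must be a mapping")

    levels: dict[str, dict[str, Level]] = {}
    for ent_name, props in (doc.get("levels") or {}).items():
        ent_name = registry.canonical_entity(ent_name)
        if ent_name not in registry:
            raise ProfileError(f"profile references unknown entity {ent_name!r}")
        descriptor = registry[ent_name]
        ent_levels: dict[str, Level] = {}
        for prop, token in (props or {}).items():
            if prop not in descriptor.properties:
                raise ProfileError(
                    f"profile references unknown property {ent_name}.{prop}"
                )
            ent_levels[prop] = Level.parse(token)
        levels[ent_name] = ent_levels
    return RequirementProfile(
        name=doc.get("name", "inline"),
        version=str(doc.get("version", "")),
        levels=levels,
        registry=registry,
    )


def mandatory_property_count(profile: RequirementProfile) -> int:
    """Number of MUST-level entries in the profile."""
    return len(profile.must_entries())
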