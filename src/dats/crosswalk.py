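"""Declarative crosswalks from repository metadata records into DATS.

A crosswalk spec is a data file, not code: a list of rules, each mapping a
source path expression to a DATS target path with an optional transform.
This mirrors how harvesting converters feed a discovery index — adopters add
sources by writing a mapping file, not a program.

Accounting is strict: every scalar leaf of the source record is either
consumed by some rule or reported in ``unmapped_source_fields``; nothing is
silently dropped.  The produced instance is validated against the profile
and the report travels with the result, so a thin source record yields an
instance *plus* the list of requirement gaps, never a hard failure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from ._errors import CrosswalkError
from .instance import (
    Annotation,
    DateInterval,
    DatsEntity,
    EventDate,
    Identifier,
    is_empty,
)
from .registry import (
    EntityRegistry,
    RequirementProfile,
    ValueKind,
    build_core_registry,
    load_profile,
)
from .validation import ValidationReport, validate

TRANSFORMS = ("identity", "split", "toAnnotation", "toIdentifier", "toDate", "toDateInterval")

_SEGMENT = re.compile(r"^([^\[\]]+)(?:\[(\*|\d*)\])?$")


def _parse_path(path: str, where: str) -> list[tuple[str, Optional[str]]]:
    segments = []
    for raw in str(path).split("/"):
        m = _SEGMENT.match(raw)
        if not m:
            raise CrosswalkError(f"{where}: bad path segment {raw!r}")
        key, idx = m.group(1), m.group(2)
        segments.append((key, idx))
    return segments


@dataclass(frozen=True)
class Rule:
    source: str
    target: str
    transform: str = "identity"
    arg: Optional[str] = None
    required: bool = False


@dataclass
class CrosswalkSpec:
    name: str
    rules: list[Rule]
    defaults: list[tuple[str, Any]] = field(default_factory=list)
    jsonld: bool = False
    description: str = ""

    def resolve(self, registry: EntityRegistry) -> None:
        """Check every rule against the registry and the closed transform set."""
        for rule in self.rules:
            if rule.transform not in TRANSFORMS:
                raise CrosswalkError(
                    f"{self.name}: unknown transform {rule.transform!r} "
                    f"(expected one of {', '.join(TRANSFORMS)})"
                )
            _walk_target(registry, rule.target, f"{self.name}:{rule.target}")
        for target, _ in self.defaults:
            _walk_target(registry, target, f"{self.name}:{target}")


def _walk_target(registry: EntityRegistry, target: str, where: str) -> None:
    """Static resolution of a target path against entity descriptors."""
    segments = _parse_path(target, where)
    entity = "Dataset"
    for i, (prop, _idx) in enumerate(segments):
        if entity == "Identifier-value":
            if prop not in ("identifier", "identifierSource"):
                raise CrosswalkError(f"{where}: Identifier has no field {prop!r}")
            if i != len(segments) - 1:
                raise CrosswalkError(f"{where}: cannot descend below Identifier.{prop}")
            return
        descriptor = registry[entity]
        if prop not in descriptor.properties:
            raise CrosswalkError(f"{where}: {entity} has no property {prop!r}")
        kind = descriptor.properties[prop].kind
        if i == len(segments) - 1:
            return
        if kind.base == "ref":
            entity = next(t for t in kind.targets if t != "Annotation")
        elif kind.base == "Identifier":
            entity = "Identifier-value"
        else:
            raise CrosswalkError(f"{where}: cannot descend into {entity}.{prop} ({kind})")


# ---------------------------------------------------------------------------
# loading

def _load_spec_doc(doc: Mapping) -> CrosswalkSpec:
    rules = [
        Rule(
            source=r["source"],
            target=r["target"],
            transform=r.get("transform", "identity"),
            arg=r.get("arg"),
            required=bool(r.get("required", False)),
        )
        for r in doc.get("rules", [])
    ]
    defaults = [(d["target"], d["value"]) for d in doc.get("defaults", [])]
    return CrosswalkSpec(
        name=doc.get("name", "inline"),
        rules=rules,
        defaults=defaults,
        jsonld=bool(doc.get("jsonld", False)),
        description=doc.get("description", ""),
    )


def load_crosswalk(
    source: Union[str, Path, Mapping], registry: Optional[EntityRegistry] = None
) -> CrosswalkSpec:
    registry = registry or build_core_registry()
    if isinstance(source, Mapping):
        doc = source
    else:
        doc = yaml.safe_load(Path(source).read_text("utf-8"))
    spec = _load_spec_doc(doc)
    spec.resolve(registry)
    return spec


_BUILTIN = ("dublin_core", "datacite", "schemaorg")


@lru_cache(maxsize=1)
def builtin_specs() -> tuple[CrosswalkSpec, ...]:
    """The shipped crosswalks: Dublin-Core-like, DataCite-like, Schema.org."""
    registry = build_core_registry()
    specs = []
    for name in _BUILTIN:
        text = resources.files("dats").joinpath(
            "schemas", "crosswalks", f"{name}.yaml").read_text("utf-8")
        spec = _load_spec_doc(yaml.safe_load(text))
        spec.resolve(registry)
        specs.append(spec)
    return tuple(specs)


def builtin_spec(name: str) -> CrosswalkSpec:
    for spec in builtin_specs():
        if spec.name == name or spec.name.replace("-", "_") == name.replace("-", "_"):
            return spec
    raise CrosswalkError(f"no builtin crosswalk named {name!r}")


# ---------------------------------------------------------------------------
# source-side resolution

def _source_matches(record: Any, segments) -> list[tuple[str, Any]]:
    matches: list[tuple[str, Any]] = [("", record)]
    for key, idx in segments:
        advanced: list[tuple[str, Any]] = []
        for path, value in matches:
            if not isinstance(value, dict) or key not in value:
                continue
            sub = value[key]
            sub_path = f"{path}/{key}" if path else key
            if idx is None:
                advanced.append((sub_path, sub))
            elif idx == "*":
                items = sub if isinstance(sub, list) else [sub]
                if isinstance(sub, list):
                    advanced.extend((f"{sub_path}/{i}", v) for i, v in enumerate(items))
                else:
                    advanced.append((sub_path, sub))
            else:
                if isinstance(sub, list) and int(idx) < len(sub):
                    advanced.append((f"{sub_path}/{idx}", sub[int(idx)]))
        matches = advanced
    # expand plural source values into individual items
    expanded: list[tuple[str, Any]] = []
    for path, value in matches:
        if isinstance(value, list):
            expanded.extend((f"{path}/{i}", v) for i, v in enumerate(value))
        else:
            expanded.append((path, value))
    return expanded


def source_leaves(record: Any, path: str = "") -> set[str]:
    """All scalar leaf paths of a source record (JSON-LD keywords excluded)."""
    leaves: set[str] = set()
    if isinstance(record, dict):
        for key, value in record.items():
            if key.startswith("@"):
                continue
            leaves |= source_leaves(value, f"{path}/{key}" if path else key)
    elif isinstance(record, list):
        for i, value in enumerate(record):
            leaves |= source_leaves(value, f"{path}/{i}")
    elif record is not None:
        leaves.add(path)
    return leaves


# ---------------------------------------------------------------------------
# transforms

def _pick(raw: Mapping, keys: tuple[str, ...]) -> Optional[str]:
    for key in keys:
        if key in raw and raw[key] not in (None, ""):
            return str(raw[key])
    return None


def _apply_transform(rule: Rule, value: Any, advisories: list[str]) -> list[Any]:
    t = rule.transform
    if t == "identity":
        if isinstance(value, (dict, list)):
            advisories.append(f"{rule.source}: non-scalar value ignored by identity rule")
            return []
        return [value]
    if t == "split":
        delim = rule.arg or ","
        return [part.strip() for part in str(value).split(delim) if part.strip()]
    if t == "toAnnotation":
        if isinstance(value, Mapping):
            term = _pick(value, ("value", "name", "rights", "title"))
            if term is None:
                advisories.append(f"{rule.source}: mapping with no term text skipped")
                return []
            return [Annotation(value=term, valueIRI=_pick(value, ("valueIRI", "@id")))]
        return [Annotation(value=str(value))]
    if t == "toIdentifier":
        if isinstance(value, Mapping):
            ident = _pick(value, ("identifier", "value", "id"))
            if ident is None:
                advisories.append(f"{rule.source}: mapping with no identifier text skipped")
                return []
            source = _pick(value, ("identifierSource", "propertyID", "identifierType", "type"))
            return [Identifier(identifier=ident, identifierSource=source or rule.arg)]
        return [Identifier(identifier=str(value), identifierSource=rule.arg)]
    if t == "toDate":
        return [EventDate(date=str(value), type=Annotation(value=rule.arg or "date"))]
    if t == "toDateInterval":
        if isinstance(value, Mapping):
            return [DateInterval(start=value.get("start"), end=value.get("end"))]
        parts = str(value).split("/")
        start = parts[0].strip() or None
        end = parts[1].strip() or None if len(parts) > 1 else None
        return [DateInterval(start=start, end=end)]
    raise CrosswalkError(f"unknown transform {t!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# target-side assignment

def _coerce_target(value: Any, kind: ValueKind, advisories: list[str], where: str) -> Any:
    base = kind.base
    if base in ("text", "iri", "date"):
        if isinstance(value, Annotation):
            return value.value
        if isinstance(value, (dict, list)):
            advisories.append(f"{where}: non-scalar value skipped")
            return None
        return str(value)
    if base == "number":
        return value
    if base == "Annotation":
        return value if isinstance(value, Annotation) else Annotation(value=str(value))
    if base == "Identifier":
        return value if isinstance(value, Identifier) else Identifier(identifier=str(value))
    if base == "eventDate":
        return value if isinstance(value, EventDate) else EventDate(date=str(value))
    if base == "dateInterval":
        if isinstance(value, DateInterval):
            return value
        advisories.append(f"{where}: expected a date interval")
        return None
    if base == "ref":
        if isinstance(value, DatsEntity):
            return value
        if "Annotation" in kind.targets:
            return value if isinstance(value, Annotation) else Annotation(value=str(value))
        advisories.append(f"{where}: cannot place scalar into {kind}")
        return None
    return value


def _set_target(
    node: DatsEntity,
    segments: list[tuple[str, Optional[str]]],
    value: Any,
    registry: EntityRegistry,
    advisories: list[str],
    where: str,
) -> None:
    prop, idx = segments[0]
    if isinstance(node, Identifier):
        setattr(node, prop, str(value))
        return
    descriptor = registry[node.entity]
    kind = descriptor.properties[prop].kind
    last = len(segments) == 1

    if last:
        if kind.is_list:
            element = ValueKind(kind.base, kind.targets, False)
            coerced = _coerce_target(value, element, advisories, where)
            if coerced is None:
                return
            node.properties.setdefault(prop, []).append(coerced)
        else:
            if not is_empty(node.get(prop)):
                advisories.append(f"{where}: scalar target already set; keeping first value")
                return
            coerced = _coerce_target(value, kind, advisories, where)
            if coerced is not None:
                node[prop] = coerced
        return

    # descend, creating containers as needed
    if kind.base == "Identifier":
        if not isinstance(node.get(prop), Identifier):
            node[prop] = Identifier(identifier="")
        _set_target(node[prop], segments[1:], value, registry, advisories, where)
        return
    if kind.base != "ref":
        raise CrosswalkError(f"{where}: cannot descend into {node.entity}.{prop}")
    target_entity = next(t for t in kind.targets if t != "Annotation")
    if kind.is_list:
        items = node.properties.setdefault(prop, [])
        if idx == "" or idx is None:  # `[]` or bare name: append a fresh element
            child = DatsEntity(target_entity)
            items.append(child)
        else:
            position = int(idx)
            while len(items) <= position:
                items.append(DatsEntity(target_entity))
            child = items[position]
    else:
        if not isinstance(node.get(prop), DatsEntity):
            node[prop] = DatsEntity(target_entity)
        child = node[prop]
    _set_target(child, segments[1:], value, registry, advisories, where)


# ---------------------------------------------------------------------------
# result

@dataclass
class CrosswalkResult:
    instance: DatsEntity
    unmapped_source_fields: list[str]
    report: ValidationReport
    advisories: list[str] = field(default_factory=list)


def apply_crosswalk(
    record: Mapping,
    spec: CrosswalkSpec,
    profile: Optional[RequirementProfile] = None,
    registry: Optional[EntityRegistry] = None,
) -> CrosswalkResult:
    """Map a source record into a validated DATS instance.

    Deterministic: rules apply in declaration order, multi-valued source
    fields map to collections, scalar targets keep the first value and record
    an advisory.  A ``required`` rule whose source path has no match raises
    :class:`CrosswalkError` naming the path.
    """
    registry = registry or build_core_registry()
    profile = profile or load_profile(registry=registry)
    if not isinstance(record, Mapping):
        raise CrosswalkError("source record must be a JSON object")

    if spec.jsonld:
        from .jsonld import expand, schemaorg_view
        record = schemaorg_view(expand(dict(record)))

    instance = DatsEntity("Dataset")
    consumed: set[str] = set()
    advisories: list[str] = []

    for rule in spec.rules:
        src_segments = _parse_path(rule.source, f"{spec.name}:{rule.source}")
        matches = _source_matches(record, src_segments)
        if rule.required and not matches:
            raise CrosswalkError(
                f"{spec.name}: required source field {rule.source!r} is absent"
            )
        tgt_segments = _parse_path(rule.target, f"{spec.name}:{rule.target}")
        for path, raw in matches:
            values = _apply_transform(rule, raw, advisories)
            if not values:
                continue
            for value in values:
                _set_target(instance, tgt_segments, value, registry, advisories,
                            f"{spec.name}:{rule.target}")
            consumed |= source_leaves(raw, path)

    for target, constant in spec.defaults:
        tgt_segments = _parse_path(target, f"{spec.name}:{target}")
        prop = tgt_segments[0][0]
        if is_empty(instance.get(prop)):
            _set_target(instance, tgt_segments, constant, registry, advisories,
                        f"{spec.name}:{target}")

    unmapped = sorted(source_leaves(record) - consumed)
    report = validate(instance, profile, registry)
    return CrosswalkResult(
        instance=instance,
        unmapped_source_fields=unmapped,
        report=report,
        advisories=advisories,
    )
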