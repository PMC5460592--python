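"""Requirement-level validation of DATS instances.

An instance is checked against the entity registry and a requirement profile.
Entities are never mandatory — an absent entity yields no issues — but when an
entity node is present, every MUST property that is absent or empty yields
exactly one ``MISSING_MUST`` issue at its path.  Unknown properties are
advisory (warn-and-carry), since the model is explicitly extensible.

The report is deterministic: issues are sorted by path, then code, so the
same instance and profile always produce byte-identical reports.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass
from typing import Any, Optional
from urllib.parse import urlsplit

from ._errors import StructuralError
from .instance import (
    Annotation,
    DateInterval,
    DatsEntity,
    EventDate,
    ExtraProperty,
    Identifier,
    is_empty,
)
from .registry import (
    EntityRegistry,
    Level,
    RequirementProfile,
    build_core_registry,
    load_profile,
)


class IssueCode(str, enum.Enum):
    MISSING_MUST = "MISSING_MUST"
    MISSING_SHOULD = "MISSING_SHOULD"
    UNKNOWN_PROPERTY = "UNKNOWN_PROPERTY"
    EMPTY_VALUE = "EMPTY_VALUE"
    BAD_IRI = "BAD_IRI"
    BAD_INTERVAL = "BAD_INTERVAL"
    BAD_VALUE = "BAD_VALUE"
    NO_LOCATOR = "NO_LOCATOR"


@dataclass(frozen=True)
class ValidationIssue:
    path: str
    level: Level
    code: IssueCode
    message: str

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "level": self.level.name,
            "code": self.code.value,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def verdicts(self) -> dict[str, bool]:
        """Per-level pass/fail: level L fails iff >= 1 issue at level L."""
        return {
            lvl.name: not any(i.level is lvl for i in self.issues)
            for lvl in (Level.MUST, Level.SHOULD, Level.MAY)
        }

    def at_level(self, level: Level) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level is level]

    def passes(self, level: Level) -> bool:
        """True iff no issue at ``level`` or stricter."""
        return not any(i.level >= level for i in self.issues)

    def to_dict(self) -> dict:
        return {
            "issues": [i.to_dict() for i in self.issues],
            "verdicts": self.verdicts,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


_IRI_SCHEME = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*$")
_ISO_DATE = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2})(?:[T ].+)?)?)?$")


def is_absolute_iri(value: str) -> bool:
    if not isinstance(value, str) or not value.strip() or any(c.isspace() for c in value):
        return False
    parts = urlsplit(value)
    if not parts.scheme or not _IRI_SCHEME.match(parts.scheme):
        return False
    return bool(parts.netloc or parts.path or parts.fragment or parts.query)


def parse_iso_date(value: str) -> Optional[tuple[int, ...]]:
    """Parse an ISO-8601 date at year, month or day precision.

    Returns the available (year[, month[, day]]) components, or None if the
    text is not a calendar date/date-time.
    """
    m = _ISO_DATE.match(value.strip()) if isinstance(value, str) else None
    if not m:
        return None
    return tuple(int(g) for g in m.groups() if g is not None)


def interval_ok(interval: DateInterval) -> bool:
    """start <= end, compared on the components both ends share."""
    if not interval.start or not interval.end:
        return True
    start, end = parse_iso_date(interval.start), parse_iso_date(interval.end)
    if start is None or end is None:
        return True  # unparseable dates are reported separately
    shared = min(len(start), len(end))
    return start[:shared] <= end[:shared]


class _Collector:
    def __init__(self, profile: RequirementProfile, registry: EntityRegistry):
        self.profile = profile
        self.registry = registry
        self.issues: list[ValidationIssue] = []

    def add(self, path: str, level: Level, code: IssueCode, message: str) -> None:
        self.issues.append(ValidationIssue(path, level, code, message))

    # -- value-level well-formedness ------------------------------------

    def check_value(self, value: Any, path: str) -> None:
        if isinstance(value, DatsEntity):
            self.check_entity(value, path)
        elif isinstance(value, Annotation):
            if is_empty(value.value):
                self.add(path, Level.SHOULD, IssueCode.EMPTY_VALUE,
                         "annotation with empty value")
            if value.valueIRI and not is_absolute_iri(value.valueIRI):
                self.add(f"{path}/valueIRI", Level.MUST, IssueCode.BAD_IRI,
                         f"valueIRI {value.valueIRI!r} is not an absolute IRI")
        elif isinstance(value, Identifier):
            self.check_identifier(value, path)
        elif isinstance(value, EventDate):
            if value.date and parse_iso_date(value.date) is None:
                self.add(f"{path}/date", Level.SHOULD, IssueCode.BAD_VALUE,
                         f"{value.date!r} is not an ISO-8601 date")
            if value.type is not None:
                self.check_value(value.type, f"{path}/type")
        elif isinstance(value, DateInterval):
            for endpoint in ("start", "end"):
                text = getattr(value, endpoint)
                if text and parse_iso_date(text) is None:
                    self.add(f"{path}/{endpoint}", Level.SHOULD, IssueCode.BAD_VALUE,
                             f"{text!r} is not an ISO-8601 date")
            if not interval_ok(value):
                self.add(path, Level.MUST, IssueCode.BAD_INTERVAL,
                         f"interval start {value.start!r} is after end {value.end!r}")
        elif isinstance(value, ExtraProperty):
            if is_empty(value.category):
                self.add(f"{path}/category", Level.SHOULD, IssueCode.EMPTY_VALUE,
                         "extra property with empty category")
        elif isinstance(value, list):
            for i, item in enumerate(value):
                self.check_value(item, f"{path}/{i}")

    def check_identifier(self, ident: Identifier, path: str) -> None:
        # Identifier is the 18th core entity: its own profile entries apply
        # whenever an identifier value is present in the tree.
        for prop, level in self.profile.levels.get("Identifier", {}).items():
            if level is Level.MAY:
                continue
            if is_empty(getattr(ident, prop, None)):
                code = (IssueCode.MISSING_MUST if level is Level.MUST
                        else IssueCode.MISSING_SHOULD)
                self.add(f"{path}/{prop}", level, code,
                         f"Identifier.{prop} is required ({level.name}) but absent or empty")

    # -- entity-level checks --------------------------------------------

    def check_entity(self, node: DatsEntity, path: str) -> None:
        descriptor = self.registry.get(node.entity)
        if descriptor is None:
            raise StructuralError(f"instance contains unknown entity {node.entity!r}")

        for prop, level in self.profile.levels.get(node.entity, {}).items():
            if level is Level.MAY:
                continue
            if is_empty(node.get(prop)):
                code = (IssueCode.MISSING_MUST if level is Level.MUST
                        else IssueCode.MISSING_SHOULD)
                self.add(f"{path}/{prop}", level, code,
                         f"{node.entity}.{prop} is required ({level.name}) "
                         "but absent or empty")

        for key in node.unknown:
            self.add(f"{path}/{key}", Level.MAY, IssueCode.UNKNOWN_PROPERTY,
                     f"{node.entity} has no property {key!r} (carried as-is)")

        if node.entity == "Access":
            if is_empty(node.get("landingPage")) and is_empty(node.get("accessURL")):
                self.add(path, Level.SHOULD, IssueCode.NO_LOCATOR,
                         "Access has neither landingPage nor accessURL")

        for prop, value in node.properties.items():
            pdesc = descriptor.properties.get(prop)
            ppath = f"{path}/{prop}"
            level = self.profile.level_of(node.entity, prop)
            if is_empty(value):
                # Empty values on MUST/SHOULD props are already reported as
                # missing; elsewhere an explicitly empty value is advisory.
                if value is not None and (level is None or level is Level.MAY):
                    self.add(ppath, Level.MAY, IssueCode.EMPTY_VALUE,
                             f"{node.entity}.{prop} is present but empty")
                continue
            if pdesc is not None and not pdesc.kind.is_list:
                if pdesc.kind.base == "iri" and not is_absolute_iri(value):
                    self.add(ppath, Level.MUST, IssueCode.BAD_IRI,
                             f"{value!r} is not an absolute IRI")
                    continue
                if pdesc.kind.base == "number" and isinstance(value, (int, float)) and value < 0:
                    self.add(ppath, Level.MUST, IssueCode.BAD_VALUE,
                             f"{node.entity}.{prop} must be non-negative, got {value!r}")
                    continue
                if pdesc.kind.base == "date" and isinstance(value, str) \
                        and parse_iso_date(value) is None:
                    self.add(ppath, Level.SHOULD, IssueCode.BAD_VALUE,
                             f"{value!r} is not an ISO-8601 date")
                    continue
            self.check_value(value, ppath)


def validate(
    instance: DatsEntity,
    profile: Optional[RequirementProfile] = None,
    registry: Optional[EntityRegistry] = None,
) -> ValidationReport:
    """Validate ``instance`` against ``profile`` (default: shipped core profile).

    Raises :class:`StructuralError` if the root is not a registered entity.
    """
    registry = registry or build_core_registry()
    profile = profile or load_profile(registry=registry)
    if not isinstance(instance, DatsEntity):
        raise StructuralError("instance root must be a DATS entity node")
    if instance.entity not in registry:
        raise StructuralError(f"instance root {instance.entity!r} is not a registered entity")
    collector = _Collector(profile, registry)
    collector.check_entity(instance, instance.entity)
    issues = sorted(collector.issues, key=lambda i: (i.path, i.code.value))
    return ValidationReport(issues=issues)


def conforms(
    instance: DatsEntity,
    profile: Optional[RequirementProfile] = None,
    level: Level = Level.MUST,
    registry: Optional[EntityRegistry] = None,
) -> bool:
    """True iff validation reports no issue at ``level`` or stricter."""
    return validate(instance, profile, registry).passes(level)
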