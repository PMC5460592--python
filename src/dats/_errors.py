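"""Exception hierarchy for the toolkit."""


class DatsError(Exception):
    """Base class for all toolkit errors."""


class RegistryError(DatsError):
    """A registry data file is malformed or internally inconsistent."""


class ProfileError(DatsError):
    """A requirement profile names unknown entities/properties or bad levels."""


class StructuralError(DatsError):
    """An instance is not rooted at a known entity, or is not a tree at all."""


class FormatError(DatsError):
    """A document cannot be interpreted (bad JSON shape, unknown @type, ...)."""


class MappingError(DatsError):
    """The DATS/Schema.org mapping table is malformed (e.g. duplicate terms)."""


class CrosswalkError(DatsError):
    """A crosswalk spec is invalid or a required source field is missing."""


class QueryError(DatsError):
    """A discovery query references an unknown facet."""


class ConfigError(DatsError):
    """A generator configuration is inconsistent."""


class NonConformantError(DatsError):
    """An operation that requires a MUST-conformant instance was refused.

    Carries the validation report explaining the refusal.
    """

    def __init__(self, message, report):
        super().__init__(message)
        self.report = report
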