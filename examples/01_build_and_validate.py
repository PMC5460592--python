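"""Build a Dataset instance in code and check its RFC 2119 conformance.

Shows the central contract of the model: entities are applicable only if
relevant, but a present entity must carry its MUST-level properties.
"""

from dats import (
    Annotation,
    DatsEntity,
    Identifier,
    Level,
    load_profile,
    validate,
)

profile = load_profile()  # shipped core profile: 10 MUST entries

instance = DatsEntity(
    "Dataset",
    identifier=Identifier(identifier="https://example.org/demo/0001"),
    title="Single-cell transcriptome atlas of zebrafish fin regeneration",
    types=[Annotation(value="RNA-seq")],
    creators=[DatsEntity("Person", fullName="Ada Lovelace")],
)

report = validate(instance, profile)
print("MUST-conformant:", report.passes(Level.MUST))

# Remove a mandatory property: exactly one issue, at the property's path.
del instance.properties["title"]
report = validate(instance, profile)
for issue in report.at_level(Level.MUST):
    print(f"{issue.code.value} at {issue.path}: {issue.message}")

# The verdicts map says which requirement levels the instance satisfies.
print("verdicts:", report.verdicts)
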