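# dats — a toolkit for the DATS dataset-metadata model

Finding an existing dataset across hundreds of biomedical repositories is a
metadata problem: each repository describes its holdings in its own schema,
and a discovery index can only search what it can normalize.  The DATS
(DAta Tag Suite) model addresses this the way JATS did for the literature —
a compact, dataset-centric metadata model that repositories export into and
indexes search over, targeting the *Findability* and *Accessibility* halves
of FAIR.

This package is a reference implementation of the model's machinery for
repository developers, harvesters and indexer builders:

- **Model registry** — the 18 core entities (a central `Dataset` linked to
  `DatasetDistribution`, `Access`, `License`, `DataRepository`,
  `DataStandard`, `Publication`, `Software`, `Person`, `Organization`,
  `Grant`, `Material`, `DataType`, `Information`, `Method`, `Platform`,
  `Instrument`, `Identifier`), their properties and value kinds, loaded from
  versioned data files under `src/dats/schemas/`.
- **Requirement-level validation** — RFC 2119 profiles (MUST / SHOULD /
  MAY).  Entities are never mandatory, only *applicable if relevant*; when
  an entity is used, its MUST properties must be present and non-empty.  The
  default core profile carries exactly **10 MUST entries** across the **18
  core entities**.  Reports are path-addressed and deterministic.
- **Serializations** — canonical plain JSON (lowerCamelCase keys, declared
  order, empties omitted) and a Schema.org-annotated JSON-LD serialization
  driven by an externalized mapping table; every core term is either mapped
  to a Schema.org IRI or explicitly listed as a coverage gap.
- **Crosswalks** — declarative source→DATS mappings (Dublin-Core-like,
  DataCite-like and Schema.org specs ship in-package) with a strict
  accounting invariant: every source leaf is consumed or reported unmapped.
- **Discovery flattener** — entity/attribute/value triples plus facet keys
  (`accessType`, `authorization`, `dataStandard`, `repository`,
  `materialTerm`, `dataTypeTerm`) and exact boolean retrieval.
- **Synthetic generator** — seeded corpora of valid and systematically
  perturbed instances with exact failure attribution.

## Worked example

```python
from dats import (Annotation, DatsEntity, Identifier, Level,
                  load_profile, validate)

profile = load_profile()          # 18 entities covered, 10 MUST entries
instance = DatsEntity(
    "Dataset",
    identifier=Identifier(identifier="https://example.org/demo/0001"),
    title="Single-cell transcriptome atlas of zebrafish fin regeneration",
    types=[Annotation(value="RNA-seq")],
    creators=[DatsEntity("Person", fullName="Ada Lovelace")],
)
print(validate(instance, profile).passes(Level.MUST))

del instance.properties["title"]
for issue in validate(instance, profile).at_level(Level.MUST):
    print(issue.code.value, "at", issue.path)
```

prints

```
True
MISSING_MUST at Dataset/title
```

`True` says the four-property instance satisfies every MUST entry that
applies to it (absent entities impose nothing); deleting the title produces
exactly one issue, located at the path of the missing property.

The same instance from the shell:

```sh
$ dats stats
model: dats-core v2.2
core entities: 18
mandatory (MUST) properties: 10
...
$ dats validate instance.json   # exit 0 = MUST pass, 1 = MUST fail, 2 = structural
```

The `examples/` directory holds one short narrative script per capability
(validation, JSON/JSON-LD, crosswalks, indexing and query, corpus
generation); each prints what it computes and what the numbers mean.

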