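# Crosswalk for Schema.org Dataset nodes (JSON-LD).  The record is expanded
# and re-compacted against the bare Schema.org vocabulary before the rules
# apply, so source paths use plain Schema.org term names regardless of the
# record's own context.
name: schemaorg
description: >-
  Schema.org Dataset node: name, description, identifier (text or
  PropertyValue), keywords, creator (Person nodes or plain strings),
  license, url.
jsonld: true
rules:
  - {source: name, target: title, required: true}
  - {source: description, target: description}
  - {source: identifier, target: identifier, transform: toIdentifier}
  - {source: "keywords[*]", target: "types[]", transform: toAnnotation}
  - {source: "creator[*]/name", target: "creators[]/fullName"}
  - {source: "creator[*]", target: "creators[]/fullName"}
  - {source: "license[*]/name", target: "licenses[]/name"}
  - {source: url, target: "distributions[]/access/landingPage"}
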