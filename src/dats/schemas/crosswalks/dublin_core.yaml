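# Crosswalk for flat Dublin-Core-like records (dc: element values as plain
# keys; scalar or list-valued).
name: dublin-core
description: >-
  Flat Dublin Core element set: title, creator, identifier, description,
  type, subject, date, rights.
rules:
  - {source: title, target: title, required: true}
  - {source: creator, target: "creators[]/fullName"}
  - {source: identifier, target: identifier, transform: toIdentifier}
  - {source: description, target: description}
  - {source: type, target: "types[]", transform: toAnnotation}
  - {source: subject, target: "isAbout[]", transform: toAnnotation}
  - {source: date, target: "dates[]", transform: toDate, arg: issued}
  - {source: rights, target: "licenses[]/name"}
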