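# Crosswalk for DataCite-like records: identifier-with-type, plural
# creators/titles/descriptions, publicationYear, resourceType.
name: datacite
description: >-
  DataCite kernel shape: identifier {id, type}, creators[].name,
  titles[].title, publicationYear, resourceType.resourceTypeGeneral,
  descriptions[].description, rightsList[].rights.
rules:
  - {source: "titles[*]/title", target: title, required: true}
  - {source: identifier, target: identifier, transform: toIdentifier}
  - {source: "creators[*]/name", target: "creators[]/fullName"}
  - {source: publicationYear, target: "dates[]", transform: toDate, arg: publication}
  - {source: "resourceType/resourceTypeGeneral", target: "types[]", transform: toAnnotation}
  - {source: "descriptions[*]/description", target: description}
  - {source: "rightsList[*]/rights", target: "licenses[]/name"}
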