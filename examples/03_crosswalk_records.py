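"""Map repository metadata records into DATS with the shipped crosswalks.

Every source leaf is either consumed by a rule or listed as unmapped; the
produced instance arrives with its validation report attached, so a thin
record yields an instance plus the list of requirement gaps.
"""

import json

from dats import Level, apply_crosswalk, builtin_spec, write_instance

dc_record = {
    "title": "Soil microbiome survey of Greater Testshire",
    "creator": ["Ada Lovelace", "Grace Hopper"],
    "identifier": "doi:10.1234/dc.0001",
    "type": "dataset",
    "rights": "CC-BY-4.0",
    "coverage": "global",  # no rule consumes this: reported, not dropped
}

result = apply_crosswalk(dc_record, builtin_spec("dublin-core"))
print(json.dumps(write_instance(result.instance), indent=2))
print("unmapped source fields:", result.unmapped_source_fields)
print("MUST-conformant:", result.report.passes(Level.MUST))

datacite_record = {
    "identifier": {"id": "10.5061/example.42", "type": "DOI"},
    "creators": [{"name": "Ada Lovelace"}],
    "titles": [{"title": "Tidal records 1950-2000"}],
    "publicationYear": "2016",
    "resourceType": {"resourceTypeGeneral": "Dataset"},
}
result = apply_crosswalk(datacite_record, builtin_spec("datacite"))
date = result.instance["dates"][0]
print("publicationYear became a typed date:",
      date.date, "/", date.type.value)
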