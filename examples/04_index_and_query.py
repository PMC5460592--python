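"""Flatten a corpus into search-ready field documents and run boolean queries.

Each MUST-conformant instance becomes one document: (entity, attribute,
value) triples plus discovery facets.  Retrieval is exact boolean — the
search-engine layers (ranking, expansion) are deliberately out of scope.
"""

from dats import GeneratorConfig, flatten, generate, query

corpus = generate(GeneratorConfig(seed=31, completeness="typical", count=40))
docs = [flatten(item.instance) for item in corpus]

doc = docs[0]
print("one dataset:", doc.dataset_id)
print("  triples:", len(doc.triples), "facets:",
      {k: v for k, v in doc.facets.items() if v})

public = query(docs, facets={"authorization": "public"})
print("public datasets:", len(public))

api_public = query(docs, facets={"authorization": "public", "accessType": "API"})
print("public AND via API:", len(api_public))

hits = query(docs, keywords=["microbiome"])
print("keyword 'microbiome':", len(hits))
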