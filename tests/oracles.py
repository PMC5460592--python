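"""Independent oracles used by the test suite.

Everything here works on raw written-JSON trees, deliberately sharing no
code with the library's flattener or query engine: leaf counting by direct
tree walk, facet extraction by explicit path lookups, and retrieval by
brute-force filtering.
"""

from __future__ import annotations

from typing import Any, Mapping, Sequence


def count_scalar_leaves(doc: Any) -> int:
    """Number of populated scalar leaves in a written JSON tree."""
    if isinstance(doc, Mapping):
        return sum(count_scalar_leaves(v) for k, v in doc.items()
                   if not k.startswith("@"))
    if isinstance(doc, list):
        return sum(count_scalar_leaves(v) for v in doc)
    if doc is None or (isinstance(doc, str) and not doc.strip()):
        return 0
    return 1


def _ann_values(items) -> set[str]:
    out = set()
    for item in items or []:
        if isinstance(item, Mapping) and item.get("value"):
            out.add(item["value"])
        elif isinstance(item, str):
            out.add(item)
    return out


def raw_facets(doc: Mapping) -> dict[str, set[str]]:
    """Facet values extracted from a written Dataset JSON tree by explicit
    path lookups (independent of the library's extractor)."""
    facets: dict[str, set[str]] = {
        "accessType": set(), "authorization": set(), "dataStandard": set(),
        "repository": set(), "materialTerm": set(), "dataTypeTerm": set(),
    }
    facets["dataTypeTerm"] |= _ann_values(doc.get("types"))
    for item in doc.get("isAbout") or []:
        if isinstance(item, Mapping):
            if item.get("name"):
                facets["materialTerm"].add(item["name"])
            elif item.get("value"):
                facets["materialTerm"].add(item["value"])
    for dist in doc.get("distributions") or []:
        access = dist.get("access") or {}
        facets["accessType"] |= _ann_values(access.get("types"))
        facets["authorization"] |= _ann_values(access.get("authorizations"))
        stored = dist.get("storedIn") or {}
        if stored.get("name"):
            facets["repository"].add(stored["name"])
        for std in dist.get("conformsTo") or []:
            if std.get("name"):
                facets["dataStandard"].add(std["name"])
    return facets


def iter_string_leaves(doc: Any):
    if isinstance(doc, Mapping):
        for k, v in doc.items():
            if not k.startswith("@"):
                yield from iter_string_leaves(v)
    elif isinstance(doc, list):
        for v in doc:
            yield from iter_string_leaves(v)
    elif doc is not None:
        yield str(doc)


def brute_force_query(
    raw_docs: Sequence[Mapping],
    facets: Mapping[str, str] | None = None,
    keywords: Sequence[str] | None = None,
) -> list[str]:
    """Reference retrieval: scan raw written-JSON datasets directly."""
    hits = []
    for doc in raw_docs:
        ok = True
        extracted = raw_facets(doc)
        for key, wanted in (facets or {}).items():
            if str(wanted).lower() not in {v.lower() for v in extracted[key]}:
                ok = False
                break
        if ok:
            for kw in keywords or []:
                if not any(str(kw).lower() in leaf.lower()
                           for leaf in iter_string_leaves(doc)):
                    ok = False
                    break
        if ok:
            hits.append(doc["identifier"]["identifier"])
    return sorted(hits)
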