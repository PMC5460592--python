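# Methods

## The model and its conformance semantics

The toolkit implements a dataset-centric metadata model for discovery
indexing.  The unit of description is the `Dataset`; everything else —
distributions, access conditions, repositories, standards, publications,
people, organizations, grants, materials, data types, methods, platforms,
instruments — hangs off it as an embedded subtree.  Two design commitments
drive the whole implementation:

1. **Descriptors are data, not code.**  The entity roster, property kinds,
   requirement profile, Schema.org mapping and crosswalk specs are versioned
   YAML files under `src/dats/schemas/`.  The registry loader enforces the
   structural invariants (UpperCamelCase entities, lowerCamelCase
   properties, closed reference targets) at load time, so a corrected data
   file is a complete model upgrade.

2. **Entities are applicable only if relevant.**  No entity other than the
   instance root is ever required.  Conformance is judged per *present*
   entity node: each MUST property that is absent or empty yields exactly
   one `MISSING_MUST` issue at its slash-delimited path; an absent entity
   yields nothing.  Empty text and empty collections count as absent —
   an empty title is useless for search — but a present structured node
   (e.g. an `Identifier` with an empty inner string) counts as present, with
   the inner gap reported at its own path.  This keeps issue attribution
   exact: one defect, one issue, one path.

The default core profile covers all 18 entities and allocates the model's
10 MUST entries as `Dataset.{identifier,title,types,creators}`,
`DatasetDistribution.access`, `Identifier.identifier`, `Person.fullName`,
`Organization.name`, `Publication.identifier` and `DataRepository.name`.
The roster and the allocation live in the data files precisely because the
authoritative release, not this package, owns them; the shipped defaults
concentrate the mandatory surface on discoverability essentials (what is
it, who made it, how do I cite and reach it).

Additional levels: `SHOULD` marks recommended-for-discovery properties
(e.g. `Dataset.description`, satellite `name`s); an `Access` entity with
neither `landingPage` nor `accessURL` draws a SHOULD-level `NO_LOCATOR` —
an either/or rule enforced structurally rather than as two independent
profile entries, since either locator alone satisfies it.  Unknown
properties are advisory (`UNKNOWN_PROPERTY` at MAY) and carried verbatim:
the model is explicitly extensible, so unknown detail is preserved, never
dropped and never fatal.  Malformed values (non-absolute IRIs, inverted
date intervals, negative sizes) are MUST-level defects: a dataset whose
landing page is not a URL is not findable.

Because referenced entities are embedded subtrees rather than id-linked
nodes, a dangling cross-reference cannot be represented; no referential
check exists because none is needed under this representation.

## Dates and intervals

ISO 8601 at year, month or day precision (`2016`, `2016-03`,
`2016-03-01`, optionally with a time suffix).  Dates travel as (value,
type-annotation) pairs so that "publication 2016" and "creation 2016" stay
distinguishable.  Intervals `{start, end}` may be open on either side;
ordering is checked on the components both endpoints share, so
`2020-05 ≤ 2020` holds (no contradiction at the shared year) while
`2021-06-01 > 2019` fails.

## Serializations

Plain JSON follows the Google JSON style used by the model: lowerCamelCase
keys, registry declaration order, empty optionals omitted (presence of key
= presence of value).  Reading is lossless and separate from validation: a
document with only a `title` parses fine.  The historical `Licence` /
`licences` spellings are normalized on read with the alias recorded on the
node.  Union-valued positions (e.g. creators may be persons or
organizations) are resolved by scoring declared properties, ties breaking
toward the first alternative — an all-ambiguous creator becomes a `Person`,
never a fabricated `Organization`; where the bare shape would re-resolve
differently (e.g. a `Platform` in `producedBy`, whose shape matches
`Method`), the writer emits an explicit `@type` so round trips are exact.

JSON-LD adds `@context`, `@type` on every node, and `@id` minted from the
identifier when it is itself an IRI; an annotation's term IRI becomes its
node `@id`.  The context is JSON-LD 1.1 with *type-scoped* term
definitions, which lets `identifier` mean `schema.org/identifier` on a
`Dataset` but `schema.org/value` inside a `PropertyValue` without term
collisions.  The mapping table is a data file; terms without a Schema.org
counterpart fall back to a DATS namespace and are enumerated in the file's
`unmapped` list with reasons — the totality check (`mapping_totality`)
guarantees no core term is silently omitted.

Expansion and compaction are implemented in-package for exactly the
profile the serializer emits (prefixes, global type terms, scoped property
terms, arrays as sets, plain literals); they are not a general JSON-LD
processor.  The emitted documents are nevertheless valid JSON-LD 1.1: the
test suite parses them with rdflib, an independent RDF stack, and asserts
the promised Schema.org triples, so the in-package algebra and a
conformant processor are checked against each other rather than collapsed
into one library call.

## Crosswalks

A crosswalk spec is a list of `(sourcePath, targetPath, transform)` rules
plus optional constant defaults.  Source paths use `/` with `[*]` for
array fan-out; target paths use `/` with `[]` to append collection
elements, and the setter is registry-aware (descending into `creators[]`
creates a `Person`, into `licenses[]` a `License`).  Transforms form a
closed set: `identity`, `split(delimiter)`, `toAnnotation`,
`toIdentifier(source)`, `toDate(type)`, `toDateInterval`.  `toDate` exists
because year-only fields like `publicationYear` must become a typed
(date, annotation) pair at year precision; none of the other transforms
can produce one.

Three specs ship: a flat Dublin-Core-like record, a DataCite-like record
(identifier-with-type, plural titles/creators/descriptions), and a
Schema.org `Dataset` node.  The Schema.org spec declares `jsonld: true`:
the record is expanded and re-compacted against the bare Schema.org
vocabulary before rules apply, so the same spec consumes this package's own
JSON-LD emission and any plain Schema.org node regardless of its context.
Multi-valued sources map to collections; scalar targets keep the first
value and record an advisory; ambiguous creators become `Person` with a
`fullName` — structure is never fabricated.  The conservation invariant —
every source leaf consumed or listed unmapped — is asserted exhaustively in
the tests.

## Discovery flattening and retrieval

`flatten` refuses non-MUST-conformant instances (attaching the validation
report) and emits one `(entity, attribute-path, value)` triple per
populated leaf — triple count equals an independent leaf count of the
written JSON, which the tests assert.  Six facet keys are derived:
access type and authorization from `Access`, standard and repository from
`DatasetDistribution`, material terms from `isAbout`, data-type terms from
`Dataset.types`; the set is extensible per call.  Retrieval is exact
boolean conjunction (case-insensitive facet equality, case-insensitive
keyword substring over triple values) with results ordered by dataset id.
Ranking, stemming and query expansion belong to a search engine and are
deliberately out of scope; exactness is what keeps the retrieval layer
checkable against a brute-force scan.

## The synthetic generator

The generator emulates the *shape* of repository records, not their
content: titles, names and vocabularies come from bundled word lists, IRIs
are minted under `https://example.org/`, and no real record or network
source is involved.  Three completeness tiers: `minimal` is exactly the
profile's Dataset-level MUST properties; `typical` adds what a well-curated
record carries (description, dates, license, a distribution with access,
repository and standard, a material); `full` exercises every core entity
including organization creators, publications, grants, methods/platforms,
coverage and extra properties.  Facet-bearing fields draw from small pools
(three authorization states, three access types, four repositories, four
standards) so that query predicates partition a corpus non-trivially.

Invalid instances are produced by applying exactly one perturbation from a
five-item menu — `drop-MUST`, `empty-value`, `bad-IRI`,
`unknown-property`, `bad-interval` — so failure attribution is exact: each
perturbed instance carries the issue (path, code, level) its report must
show.  `unknown-property` is advisory by design, so its instances remain
MUST-valid and are labelled accordingly; the validity label is always the
predicted MUST verdict.  Everything derives from one integer seed; the
same configuration yields a byte-identical corpus.

What passing tests on this corpus do show: the validator, serializers,
crosswalks and index agree with independent oracles over well-typed,
structurally varied instances at realistic completeness.  What they do not
show: robustness to the free-text noise, encoding damage and scale of real
harvested metadata, nor anything about retrieval quality — exact boolean
retrieval has no relevance notion to evaluate.

## Problem sizes and numerical choices

The round-trip and agreement suites run on generated corpora of ~1000
instances across ≥10 seeds and all three tiers; the query sweep uses 100
instances and enumerates every facet predicate of up to three conjuncts
over the observed value pools (several hundred predicates).  These sizes
exercise every code path and value kind while keeping the default test run
fast.  There are no floating-point tolerances anywhere: every comparison in
the toolkit (round trips, reports, retrieval) is exact equality on
discrete structures, which is the point of deterministic serialization and
sorted, path-addressed reports.

## Known limitations

- The extended (domain-specific) entity set is represented only by the
  open `extraProperties` mechanism plus temporal/spatial coverage; the full
  extended roster is out of scope.
- The JSON-LD algebra handles the emitted profile only (no `@graph`,
  `@list`, language maps, or remote contexts).
- Annotation/identifier dicts with keys beyond their declared fields are
  read by their declared fields only.
- Competency-question coverage of the original index cannot be reproduced
  here (the questions themselves are not part of the model release) and is
  represented by the facet/keyword query layer instead.
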