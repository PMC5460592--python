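"""Seeded synthetic instance generator.

Produces corpora of DATS instances for testing and benchmarking: valid
instances at three completeness tiers (``minimal`` = exactly the profile's
Dataset-level MUST properties, ``typical`` = what a well-curated repository
record carries, ``full`` = every core entity exercised), plus systematically
perturbed invalid instances with exact failure attribution — each perturbed
instance carries the list of issues it is predicted to raise.

Content is drawn from bundled word lists and IRIs are minted under an
example namespace; nothing resembles a real record and nothing is fetched
from the network.  The same configuration always yields a byte-identical
corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from ._errors import ConfigError
from .instance import (
    Annotation,
    DateInterval,
    DatsEntity,
    EventDate,
    ExtraProperty,
    Identifier,
    is_empty,
    walk_entities,
)
from .registry import (
    EntityRegistry,
    Level,
    RequirementProfile,
    build_core_registry,
    load_profile,
)

PERTURBATIONS = ("drop-MUST", "empty-value", "bad-IRI", "unknown-property", "bad-interval")

COMPLETENESS_TIERS = ("minimal", "typical", "full")

_ADJECTIVES = ("longitudinal", "multicentre", "single-cell", "population-scale",
               "time-resolved", "comparative", "integrative", "pilot")
_TOPICS = ("transcriptome", "proteome", "microbiome", "methylome", "variant",
           "imaging", "survey", "cohort")
_ORGANISMS = ("Homo sapiens", "Mus musculus", "Danio rerio",
              "Arabidopsis thaliana", "Escherichia coli")
_ASSAYS = ("RNA-seq", "whole genome sequencing", "mass spectrometry",
           "16S rRNA profiling", "flow cytometry")
_FIRST = ("Ada", "Grace", "Alan", "Rosalind", "Barbara", "Edsger", "Radia", "Donald")
_LAST = ("Lovelace", "Hopper", "Turing", "Franklin", "Liskov", "Dijkstra",
         "Perlman", "Knuth")
_ORGS = ("Example Institute of Data Science", "University of Exampleton",
         "Centre for Synthetic Metadata", "Openshelf Foundation")
_ABBREV = ("EIDS", "UoE", "CSM", "OSF")
_REPOS = ("ExampleBank", "Openshelf Archive", "SynthData Commons", "Repositorium")
_STANDARDS = ("MIAME", "MINSEQE", "ISA-Tab", "FHIR")
_LICENSES = ("CC0-1.0", "CC-BY-4.0", "ODC-By-1.0")
_ACCESS_TYPES = ("download", "API", "web page")
_AUTHORIZATIONS = ("public", "restricted", "embargoed")
_AUTHENTICATIONS = ("none", "login", "token")
_MATERIALS = ("blood sample", "leaf tissue", "cell culture", "soil core", "biopsy")
_PLACES = ("Exampleton", "North Atlantic", "Greater Testshire")
_METHODS = ("library preparation", "shotgun sequencing", "tandem MS acquisition")
_PLATFORMS = ("ExampleSeq 3000", "SpectroMax IV")
_VOCAB = "https://example.org/vocab/"


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    completeness: str = "typical"
    count: int = 10
    invalid_fraction: float = 0.0
    menu: tuple[str, ...] = PERTURBATIONS

    def __post_init__(self):
        if self.completeness not in COMPLETENESS_TIERS:
            raise ConfigError(f"unknown completeness tier {self.completeness!r}")
        if self.count < 1:
            raise ConfigError("count must be positive")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ConfigError("invalidFraction must lie in [0, 1]")
        if self.invalid_fraction > 0 and not self.menu:
            raise ConfigError("invalidFraction > 0 requires a non-empty perturbation menu")
        unknown = set(self.menu) - set(PERTURBATIONS)
        if unknown:
            raise ConfigError(f"unknown perturbations: {sorted(unknown)}")


@dataclass(frozen=True)
class Perturbation:
    kind: str
    path: str
    expected_code: str
    expected_level: str


@dataclass
class GeneratedInstance:
    instance: DatsEntity
    valid: bool                      # predicted MUST verdict
    perturbations: list[Perturbation] = field(default_factory=list)


def _iri_term(rng: random.Random, term: str) -> str:
    return _VOCAB + term.lower().replace(" ", "-")


def _person(rng: random.Random) -> DatsEntity:
    return DatsEntity("Person",
                      fullName=f"{rng.choice(_FIRST)} {rng.choice(_LAST)}")


def _build(rng: random.Random, tier: str, index: int) -> DatsEntity:
    title = (f"{rng.choice(_ADJECTIVES).capitalize()} {rng.choice(_TOPICS)} "
             f"study of {rng.choice(_ORGANISMS)}")
    assay = rng.choice(_ASSAYS)
    inst = DatsEntity(
        "Dataset",
        identifier=Identifier(
            identifier=f"https://example.org/dats/dataset/{index:05d}"),
        title=title,
        types=[Annotation(value=assay)],
        creators=[_person(rng)],
    )
    if tier == "minimal":
        return inst

    inst["description"] = (f"A {rng.choice(_ADJECTIVES)} {rng.choice(_TOPICS)} "
                           f"dataset generated by {assay}.")
    inst["types"] = [Annotation(value=assay, valueIRI=_iri_term(rng, assay))]
    inst["dates"] = [EventDate(date=f"20{rng.randint(15, 24):02d}-"
                                    f"{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}",
                               type=Annotation(value="creation"))]
    inst["licenses"] = [DatsEntity("License", name=rng.choice(_LICENSES))]
    inst["isAbout"] = [DatsEntity("Material", name=rng.choice(_MATERIALS))]
    access = DatsEntity(
        "Access",
        landingPage=f"https://example.org/datasets/{index:05d}",
        types=[Annotation(value=rng.choice(_ACCESS_TYPES))],
        authorizations=[Annotation(value=rng.choice(_AUTHORIZATIONS))],
        authentications=[Annotation(value=rng.choice(_AUTHENTICATIONS))],
    )
    inst["distributions"] = [DatsEntity(
        "DatasetDistribution",
        access=access,
        storedIn=DatsEntity("DataRepository", name=rng.choice(_REPOS)),
        conformsTo=[DatsEntity("DataStandard", name=rng.choice(_STANDARDS))],
        formats=[rng.choice(("text/csv", "application/json", "application/x-hdf5"))],
        size=float(rng.randint(1, 900)),
        unit=Annotation(value="MB"),
    )]
    if tier == "typical":
        return inst

    author = _person(rng)
    org_i = rng.randrange(len(_ORGS))
    author["affiliations"] = [DatsEntity("Organization", name=_ORGS[org_i],
                                         abbreviation=_ABBREV[org_i])]
    author["roles"] = [Annotation(value="principal investigator")]
    other_org = rng.randrange(len(_ORGS))
    inst["creators"] = [author, DatsEntity("Organization", name=_ORGS[other_org],
                                           abbreviation=_ABBREV[other_org])]
    inst["relatedPublications"] = [DatsEntity(
        "Publication",
        identifier=Identifier(identifier=f"https://doi.org/10.1234/example.{index:05d}",
                              identifierSource="DOI"),
        title=f"{title}: a data descriptor",
    )]
    inst["fundedBy"] = [DatsEntity(
        "Grant", name=f"Synthetic Science Programme {rng.randint(1, 9)}",
        identifier=Identifier(identifier=f"SSP-{rng.randint(1000, 9999)}"),
    )]
    inst["producedBy"] = [
        DatsEntity("Method", name=rng.choice(_METHODS)),
        DatsEntity("Platform", name=rng.choice(_PLATFORMS)),
    ]
    inst["dimensionsAndInformation"] = [DatsEntity("DataType", name=rng.choice(_TOPICS))]
    inst["spatialCoverage"] = [Annotation(value=rng.choice(_PLACES))]
    year = rng.randint(2010, 2020)
    inst["temporalCoverage"] = [DateInterval(start=f"{year}-01-01",
                                             end=f"{year + rng.randint(1, 3)}-12-31")]
    inst["extraProperties"] = [ExtraProperty(category="processing level",
                                             values=[rng.choice(("raw", "normalized"))])]
    return inst


def _must_candidates(
    inst: DatsEntity, profile: RequirementProfile, text_only: bool = False
) -> list[tuple[str, str, str]]:
    """(entity, property, path-of-node) for MUST entries present in the tree."""
    registry = profile.registry
    out = []
    seen = set()
    for path, node in walk_entities(inst):
        for prop, level in profile.levels.get(node.entity, {}).items():
            if level is not Level.MUST or is_empty(node.get(prop)):
                continue
            if text_only and registry[node.entity].properties[prop].kind.base != "text":
                continue
            key = (node.entity, prop)
            if key not in seen:  # perturb the first node of each kind only
                seen.add(key)
                out.append((node.entity, prop, path))
    # the Identifier entity's own MUST entry, reachable through the root id
    if not text_only and isinstance(inst.get("identifier"), Identifier) \
            and profile.level_of("Identifier", "identifier") is Level.MUST:
        out.append(("Identifier", "identifier", f"{inst.entity}/identifier"))
    return sorted(out)


def _find_node(inst: DatsEntity, path: str) -> DatsEntity:
    for p, node in walk_entities(inst):
        if p == path:
            return node
    raise KeyError(path)


def _perturb(kind: str, item: GeneratedInstance, rng: random.Random,
             profile: RequirementProfile) -> None:
    inst = item.instance
    if kind == "drop-MUST":
        entity, prop, path = rng.choice(_must_candidates(inst, profile))
        if entity == "Identifier":
            inst["identifier"].identifier = ""
            issue_path = f"{path}/identifier"
        else:
            del _find_node(inst, path).properties[prop]
            issue_path = f"{path}/{prop}"
        item.perturbations.append(Perturbation(kind, issue_path, "MISSING_MUST", "MUST"))
        item.valid = False
    elif kind == "empty-value":
        entity, prop, path = rng.choice(_must_candidates(inst, profile, text_only=True))
        _find_node(inst, path)[prop] = ""
        item.perturbations.append(Perturbation(kind, f"{path}/{prop}",
                                               "MISSING_MUST", "MUST"))
        item.valid = False
    elif kind == "bad-IRI":
        inst["types"][0].valueIRI = "not an iri at all"
        item.perturbations.append(Perturbation(
            kind, f"{inst.entity}/types/0/valueIRI", "BAD_IRI", "MUST"))
        item.valid = False
    elif kind == "unknown-property":
        inst.unknown["colour"] = rng.choice(("chartreuse", "vermilion", "teal"))
        item.perturbations.append(Perturbation(
            kind, f"{inst.entity}/colour", "UNKNOWN_PROPERTY", "MAY"))
        # advisory only: the instance stays MUST-conformant
    elif kind == "bad-interval":
        inst["temporalCoverage"] = [DateInterval(start="2021-06-01", end="2019")]
        item.perturbations.append(Perturbation(
            kind, f"{inst.entity}/temporalCoverage/0", "BAD_INTERVAL", "MUST"))
        item.valid = False
    else:  # pragma: no cover
        raise ConfigError(f"unknown perturbation {kind!r}")


def generate(
    config: GeneratorConfig,
    registry: Optional[EntityRegistry] = None,
    profile: Optional[RequirementProfile] = None,
) -> list[GeneratedInstance]:
    """Generate a labelled corpus; deterministic per configuration."""
    registry = registry or build_core_registry()
    profile = profile or load_profile(registry=registry)
    rng = random.Random(config.seed)
    n_invalid = int(round(config.invalid_fraction * config.count))
    perturbed = set(rng.sample(range(config.count), n_invalid)) if n_invalid else set()
    corpus = []
    for i in range(config.count):
        item = GeneratedInstance(instance=_build(rng, config.completeness, i), valid=True)
        if i in perturbed:
            _perturb(rng.choice(sorted(config.menu)), item, rng, profile)
        corpus.append(item)
    return corpus
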