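import pytest

from dats import (
    Annotation,
    DateInterval,
    DatsEntity,
    EventDate,
    ExtraProperty,
    Identifier,
    build_core_registry,
    load_mapping,
    load_profile,
)


@pytest.fixture(scope="session")
def registry():
    return build_core_registry()


@pytest.fixture(scope="session")
def profile(registry):
    return load_profile(registry=registry)


@pytest.fixture(scope="session")
def mapping(registry):
    return load_mapping(registry=registry)


def make_minimal_instance():
    """A Dataset carrying exactly the default profile's four MUST properties."""
    return DatsEntity(
        "Dataset",
        identifier=Identifier(identifier="https://example.org/ref/0001"),
        title="Comparative transcriptome study of Danio rerio",
        types=[Annotation(value="RNA-seq")],
        creators=[DatsEntity("Person", fullName="Ada Lovelace")],
    )


def make_reference_instance():
    """A hand-built, fully valid instance exercising every MUST-bearing entity.

    Validates clean at every level: the per-test perturbations therefore
    account for every issue a report shows.
    """
    access = DatsEntity(
        "Access",
        landingPage="https://example.org/datasets/ref-0001",
        accessURL="https://example.org/api/datasets/ref-0001.json",
        types=[Annotation(value="API")],
        authorizations=[Annotation(value="public")],
        authentications=[Annotation(value="none")],
    )
    distribution = DatsEntity(
        "DatasetDistribution",
        access=access,
        storedIn=DatsEntity("DataRepository", name="ExampleBank"),
        conformsTo=[DatsEntity("DataStandard", name="MINSEQE")],
        formats=["text/csv"],
        size=42.0,
        unit=Annotation(value="MB"),
    )
    author = DatsEntity(
        "Person",
        fullName="Ada Lovelace",
        affiliations=[DatsEntity("Organization",
                                 name="Example Institute of Data Science",
                                 abbreviation="EIDS")],
        roles=[Annotation(value="principal investigator")],
    )
    return DatsEntity(
        "Dataset",
        identifier=Identifier(identifier="https://example.org/ref/0001",
                              identifierSource="example"),
        title="Comparative transcriptome study of Danio rerio",
        description="Synthetic reference record exercising every core entity.",
        types=[Annotation(value="RNA-seq",
                          valueIRI="https://example.org/vocab/rna-seq")],
        creators=[author,
                  DatsEntity("Organization", name="Openshelf Foundation",
                             abbreviation="OSF")],
        distributions=[distribution],
        licenses=[DatsEntity("License", name="CC-BY-4.0")],
        isAbout=[DatsEntity("Material", name="whole embryo"),
                 Annotation(value="hoxa1 expression")],
        producedBy=[DatsEntity("Method", name="shotgun sequencing")],
        dimensionsAndInformation=[DatsEntity("DataType", name="transcript counts")],
        relatedPublications=[DatsEntity(
            "Publication",
            identifier=Identifier(identifier="https://doi.org/10.1234/ref.0001",
                                  identifierSource="DOI"),
            title="A reference data descriptor")],
        fundedBy=[DatsEntity("Grant", name="Synthetic Science Programme 1",
                             identifier=Identifier(identifier="SSP-0001"))],
        dates=[EventDate(date="2017-06-06", type=Annotation(value="creation"))],
        spatialCoverage=[Annotation(value="Exampleton")],
        temporalCoverage=[DateInterval(start="2015-01-01", end="2016-12-31")],
        extraProperties=[ExtraProperty(category="processing level", values=["raw"])],
    )


#: For each MUST entry of the default profile: how to remove it from the
#: reference instance and where the single resulting issue must appear.
MUST_PERTURBATIONS = {
    ("Dataset", "identifier"): ("Dataset/identifier",
                                lambda d: d.properties.pop("identifier")),
    ("Dataset", "title"): ("Dataset/title",
                           lambda d: d.properties.pop("title")),
    ("Dataset", "types"): ("Dataset/types",
                           lambda d: d.properties.pop("types")),
    ("Dataset", "creators"): ("Dataset/creators",
                              lambda d: d.properties.pop("creators")),
    ("DatasetDistribution", "access"): (
        "Dataset/distributions/0/access",
        lambda d: d["distributions"][0].properties.pop("access")),
    ("Identifier", "identifier"): (
        "Dataset/identifier/identifier",
        lambda d: setattr(d["identifier"], "identifier", "")),
    ("Person", "fullName"): ("Dataset/creators/0/fullName",
                             lambda d: d["creators"][0].properties.pop("fullName")),
    ("Organization", "name"): ("Dataset/creators/1/name",
                               lambda d: d["creators"][1].properties.pop("name")),
    ("Publication", "identifier"): (
        "Dataset/relatedPublications/0/identifier",
        lambda d: d["relatedPublications"][0].properties.pop("identifier")),
    ("DataRepository", "name"): (
        "Dataset/distributions/0/storedIn/name",
        lambda d: d["distributions"][0]["storedIn"].properties.pop("name")),
}


@pytest.fixture
def minimal_instance():
    return make_minimal_instance()


@pytest.fixture
def reference_instance():
    return make_reference_instance()
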