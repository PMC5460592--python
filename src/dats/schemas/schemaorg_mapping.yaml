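# DATS -> Schema.org term correspondence driving JSON-LD context emission.
# Terms not mapped here fall back to the DATS namespace and are accounted for
# in `unmapped`, with the reason for the coverage gap.
name: dats-schemaorg
version: "2.2"
namespaces:
  sdo: "https://schema.org/"
  dats: "https://w3id.org/dats/terms#"
entities:
  Dataset: sdo:Dataset
  DatasetDistribution: sdo:DataDownload
  License: sdo:CreativeWork
  DataRepository: sdo:DataCatalog
  Publication: sdo:ScholarlyArticle
  Software: sdo:SoftwareApplication
  Person: sdo:Person
  Organization: sdo:Organization
  Grant: sdo:Grant
  Identifier: sdo:PropertyValue
  Annotation: sdo:DefinedTerm
properties:
  Dataset:
    identifier: sdo:identifier
    title: sdo:name
    description: sdo:description
    types: sdo:keywords
    creators: sdo:creator
    distributions: sdo:distribution
    licenses: sdo:license
    isAbout: sdo:about
    dimensionsAndInformation: sdo:variableMeasured
    relatedPublications: sdo:citation
    fundedBy: sdo:funding
    spatialCoverage: sdo:spatialCoverage
    temporalCoverage: sdo:temporalCoverage
    extraProperties: sdo:additionalProperty
  DatasetDistribution:
    identifier: sdo:identifier
    storedIn: sdo:includedInDataCatalog
    formats: sdo:encodingFormat
    size: sdo:contentSize
    extraProperties: sdo:additionalProperty
  Access:
    landingPage: sdo:url
    accessURL: sdo:contentUrl
    extraProperties: sdo:additionalProperty
  License:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  DataRepository:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  DataStandard:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  Publication:
    identifier: sdo:identifier
    title: sdo:headline
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  Software:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  Person:
    identifier: sdo:identifier
    fullName: sdo:name
    affiliations: sdo:affiliation
    roles: sdo:roleName
    extraProperties: sdo:additionalProperty
  Organization:
    identifier: sdo:identifier
    name: sdo:name
    abbreviation: sdo:alternateName
    roles: sdo:roleName
    extraProperties: sdo:additionalProperty
  Grant:
    identifier: sdo:identifier
    name: sdo:name
    extraProperties: sdo:additionalProperty
  Material:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  DataType:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  Information:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  Method:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  Platform:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  Instrument:
    identifier: sdo:identifier
    name: sdo:name
    types: sdo:keywords
    extraProperties: sdo:additionalProperty
  Identifier:
    identifier: sdo:value
    identifierSource: sdo:propertyID
  Annotation:
    value: sdo:name
  DateInterval:
    start: sdo:startDate
    end: sdo:endDate
unmapped:
  - {term: Access, reason: "no Schema.org type models access conditions (authorization/authentication) of a download"}
  - {term: DataStandard, reason: "Schema.org has no type for format/terminology/reporting standards; CreativeWork is already the License target"}
  - {term: Material, reason: "physical samples/specimens are a Bioschemas extension, not core Schema.org"}
  - {term: DataType, reason: "no Schema.org type for the kind of measurement a dataset records"}
  - {term: Information, reason: "no Schema.org type for a named information dimension"}
  - {term: Method, reason: "experimental procedures are not modelled by core Schema.org"}
  - {term: Platform, reason: "technology platforms are not modelled by core Schema.org"}
  - {term: Instrument, reason: "laboratory instruments are not modelled by core Schema.org"}
  - {term: EventDate, reason: "Schema.org has per-kind date properties, not a typed (date, type) pair"}
  - {term: DateInterval, reason: "no standalone interval type; start/end map to startDate/endDate"}
  - {term: ExtraProperty, reason: "open category/values pairs carried under the DATS namespace to keep PropertyValue unambiguous for Identifier"}
  - {term: Dataset.producedBy, reason: "no Schema.org property links a Dataset to the method/platform/instrument that produced it"}
  - {term: Dataset.dates, reason: "typed date lists have no Schema.org counterpart (only dateCreated/datePublished/dateModified)"}
  - {term: DatasetDistribution.access, reason: "no Schema.org property for access conditions of a DataDownload"}
  - {term: DatasetDistribution.conformsTo, reason: "conformance to standards is a Dublin Core term with no Schema.org equivalent"}
  - {term: DatasetDistribution.unit, reason: "contentSize is a bare text in Schema.org; the unit annotation has no home"}
  - {term: DatasetDistribution.dates, reason: "typed date lists have no Schema.org counterpart"}
  - {term: Access.types, reason: "access mechanism vocabulary is DATS-specific"}
  - {term: Access.authorizations, reason: "authorization states are DATS-specific"}
  - {term: Access.authentications, reason: "authentication requirements are DATS-specific"}
  - {term: Publication.dates, reason: "typed date lists have no Schema.org counterpart"}
  - {term: EventDate.date, reason: "carried under the DATS namespace with its type annotation"}
  - {term: EventDate.type, reason: "carried under the DATS namespace with its date value"}
  - {term: ExtraProperty.category, reason: "DATS namespace; see ExtraProperty"}
  - {term: ExtraProperty.values, reason: "DATS namespace; see ExtraProperty"}
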