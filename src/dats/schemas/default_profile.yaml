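# Default core requirement-level profile (RFC 2119 levels).
# Covers all 18 core entities; exactly 10 MUST entries in total.
name: dats-core-default
version: "2.2"
levels:
  Dataset:
    identifier: MUST
    title: MUST
    types: MUST
    creators: MUST
    description: SHOULD
  DatasetDistribution:
    access: MUST
  Access:
    # At least one locator (landingPage or accessURL) is additionally expected
    # at SHOULD level; that either/or rule is enforced structurally by the
    # validator, not as two independent entries.
    landingPage: MAY
    accessURL: MAY
  Identifier:
    identifier: MUST
  Person:
    fullName: MUST
  Organization:
    name: MUST
  Publication:
    identifier: MUST
    title: SHOULD
  DataRepository:
    name: MUST
  DataStandard:
    name: SHOULD
  License:
    name: SHOULD
  Software:
    name: SHOULD
  Grant:
    name: SHOULD
  Material:
    name: SHOULD
  DataType:
    name: SHOULD
  Information:
    name: SHOULD
  Method:
    name: SHOULD
  Platform:
    name: SHOULD
  Instrument:
    name: SHOULD
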