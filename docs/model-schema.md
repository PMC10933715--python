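# Model-definition document format

Logical models are declarative YAML (or JSON) documents loaded with
`geccolink.load_model`. The bundled fixture
`src/geccolink/data/mini_gecco.yaml` is the reference example.

## Top level

```yaml
name: mini-gecco                       # model name, used in artifact URLs
canonical_base: https://example.org/fhir/geccolink   # URI prefix for
                                       # generated extensions/profiles
templates: { <template-id>: <template>, ... }
nodes: [ <node>, ... ]                 # ordered tree roots
```

## Template

```yaml
condition-diagnosis:
  resource_type: Condition        # one of Patient, Consent, Observation,
                                  # Condition, Procedure,
                                  # MedicationStatement, Immunization
  binding: {mode: condition-verification}   # how the answer populates the
                                  # resource; see modes below
  fixed:                          # FHIR element fragments copied verbatim
    status: final
    category: [ ... ]
    meta: {profile: [ ... ]}
```

Binding modes: `condition-verification` (yes/no/unknown →
confirmed/refuted/unconfirmed verification status, optional severity),
`observation-value` (answer → `value[x]`), `medication-status`
(yes/no/unknown → active/not-taken/unknown), `immunization-event`
(yes/no/unknown → completed/not-done, answered date → occurrence),
`procedure-date` (answered date → `performedDateTime`),
`consent-decision` (yes/no → permit/deny provision),
`patient-field` (with `field: gender` or `field: birthDate`; binds into the
bundle's single Patient).

## Node

```yaml
- path: anamnesis.chronicLungDisease.asthma   # globally unique dot path
  question: Asthma                            # display text
  answer: {kind: yes_no_unknown}              # absent for groups
  template: condition-diagnosis               # profile template id
  codings:                                    # concept codings (all are
    - {system: icd10gm, code: J45.9, display: ...}   # emitted on mapping)
    - {system: snomed, code: "195967001", display: Asthma}
  enable: {when: anamnesis.hasChronicLungDisease, equals: "yes"}
  meta: true                                  # category meta-element
  children: [ <node>, ... ]
```

* A node has either `answer` (leaf) or `children` (group), never both.
* `system` accepts shorthands `snomed`, `loinc`, `icd10gm`, `atc`, `ucum`,
  `gender-amtlich-de`, or any full URI (custom code systems).
* Answer kinds: `yes_no_unknown`, `yes_no_unknown_with_date`,
  `yes_no_unknown_with_severity`, `coded_choice` (requires `options`),
  `date`, `datetime`, `quantity` (requires `unit`, a UCUM code; optional
  `minimum`/`maximum` simulation range), `text`, `integer` (optional
  range).
* `options` entries are `{codings: [<coding>, ...]}`; the first coding is
  the primary one shown in the questionnaire's `answerOption`, the rest
  are emitted alongside it by the mapper.
* `enable.when` must name an answer-bearing node that precedes this node
  in document order; `enable.equals` is `yes`/`no`/`unknown` for the
  three-point kinds or a primary code for `coded_choice`.
* `meta: true` marks a category group whose children must be
  condition-mapped leaves; a no/unknown answer to the controlling question
  (`enable.when`) defaults all children.

Validation on load rejects duplicate paths, dangling or cyclic enable
rules, unknown template ids, and per-kind inconsistencies (options without
`coded_choice`, `unit` without `quantity`, ...).
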