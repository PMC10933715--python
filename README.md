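# geccolink

Patient-reported outcomes (PROs) collected by COVID-19 study apps arrive as
generic FHIR R4 `QuestionnaireResponse` documents: structurally valid, but
semantically opaque — a central research platform cannot tell a cough
severity from a consent checkbox. Research platforms built around the German
Corona Consensus (GECCO) core data set instead expect strictly profiled,
terminology-coded resources (`Patient`, `Condition`, `Observation`,
`Procedure`, `MedicationStatement`, `Immunization`, `Consent`).

`geccolink` closes that gap. It is written for clinical-research informatics
teams who run questionnaire-based studies and need their app data to land in
a GECCO-shaped FHIR store without writing a bespoke mapping script per
questionnaire.

## How it works

Everything is driven by a **logical model**: a hierarchical,
terminology-annotated definition of the data set. Each answer-bearing node
carries

* a `path` (e.g. `anamnesis.chronicLungDisease.asthma`),
* a textual question and an answer kind (`yes_no_unknown`,
  `yes_no_unknown_with_date`, `yes_no_unknown_with_severity`,
  `coded_choice`, `date`, `datetime`, `quantity`, `text`, `integer`),
* the concept codings (SNOMED CT, LOINC, ICD-10-GM, ATC, custom systems),
* the id of a profile template that turns its answer into a FHIR resource.

From the model, a **reference questionnaire** is rendered in which every
item carries an extension with its logical-model path. The mapper binds
answered items back to the model via that annotation — not via `linkId` —
so researchers may rearrange, subset or re-author questionnaires freely:

```
logical model ──render──▶ Questionnaire ──(app / generator)──▶ QuestionnaireResponse
      ▲                                                            │ annotate
      └───────────────binding via path annotations◀────────────────┘
                              │ map
                              ▼
        transaction Bundle of GECCO-profiled resources ──validate──▶ report
```

Key mapping rules:

* the subject reference of every resource is set from the response's
  subject token, and the record time from its `authored` timestamp —
  except `Procedure.performedDateTime` and `Immunization.occurrenceDateTime`,
  which for domain reasons always come from answered dates;
* an answer option holds exactly one coding, but the mapper emits **all**
  concept codings of the node into the resource's code element;
* *meta-elements* (category questions such as "Does the patient suffer from
  a chronic lung disease?") gate their child items via `enableWhen`; a
  no/unknown answer emits one refuted/unconfirmed `Condition` per child.

A seeded random-response generator, a rule-based conformance validator and
a CDISC ODM bridge (`odm-export` / `odm-convert`, carrying paths in ODM
`Alias` tags and conditions in `ConditionDef`s) make the whole pipeline
testable without any external data. A bundled "mini-GECCO" model covers
every structural pattern.

## Worked example

```sh
geccolink pipeline --out-dir run --seed 42
```

prints

```json
{
  "model": "mini-gecco",
  "canonicalBase": "https://example.org/fhir/geccolink",
  "seed": 42,
  "subjects": 10,
  "responsesPerSubject": 2,
  "responsesGenerated": 20,
  "bundlesProduced": 20,
  "bundlesPassed": 20
}
```

i.e. 10 synthetic subjects each submitted 2 random questionnaire responses;
all 20 were mapped to transaction bundles and all 20 bundles passed the
conformance rules. `run/` then contains the rendered questionnaire, one
JSON file per response, bundle and validation report, plus this manifest.
Re-running with the same seed reproduces every file byte for byte.

The same stages are available individually (`render`, `simulate`, `map`,
`validate`, `odm-export`, `odm-convert`) and as library functions:

```python
import geccolink as gl

model = gl.mini_gecco()
questionnaire = gl.render_questionnaire(model)
response, = gl.generate_responses(questionnaire, 1, 1, seed=7)
bundle = gl.map_response(gl.annotate_response(response, questionnaire), model)
report = gl.validate_bundle(bundle, model, authored=response["authored"])
assert report.passed
```

## Layout

* `src/geccolink/model.py` — logical model types, loader, bundled fixture
* `src/geccolink/questionnaire.py` — reference-questionnaire renderer
* `src/geccolink/responses.py` — seeded generator, annotation transfer
* `src/geccolink/mapper.py` — response → profiled-resource mapping
* `src/geccolink/conformance.py` — rule-catalog validator
* `src/geccolink/odm.py` — CDISC ODM bridge
* `src/geccolink/pipeline.py`, `cli.py` — end-to-end run and CLI
* `docs/methods.md` — models, assumptions, design choices
* `docs/model-schema.md` — the model-definition document format
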