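# Methods

## The mapping model

`geccolink` treats questionnaire-based data capture as a projection problem:
a single hierarchical logical model is the source of truth, and both the
questionnaire shown to patients and the profiled resources handed to a
research platform are projections of it. Binding between the two directions
runs over path annotations (an extension on every questionnaire item whose
URL is `<canonical_base>/StructureDefinition/compass-gecco-item` and whose
value is the node's dot path). This assumes:

* **single occurrence** — each model element appears at most once per
  questionnaire; the mapper instantiates one model binding per response and
  rejects duplicate answered paths (`DuplicateAnswerError`). Repeating
  elements are out of scope, matching apps that submit one complete
  questionnaire per day.
* **one subject, one timestamp per response** — the response's subject
  token and `authored` time contextualize every emitted resource.
* **annotations survive transport** — responses either carry the item
  extensions already or a copy of the source questionnaire is available so
  `annotate_response` can transfer them.

### Composite answers

Two recurring patterns in the data set need more than one questionnaire
item per concept: *event with date* (vaccination yes/no/unknown plus an
event date) and *symptom with severity* (present yes/no/unknown plus a
mild/moderate/severe grade). These render as a choice item plus one child
item enabled when the choice is "yes" — asking for the severity of a cough
the patient denies is pointless, so the child stays hidden. The child item
is annotated with the parent's path plus a `#date`/`#severity` fragment;
the mapper groups the fragments back onto the parent concept and emits a
**single** resource combining the parts. The fragment keeps the
duplicate-answer check meaningful (two answers on the bare path are still
an error) while letting every rendered item carry a resolvable annotation.

### Contextual attributes

Per resource type, the subject- and time-specifying attributes are:

| type | subject | time |
|---|---|---|
| Patient | — | — |
| Consent | `patient` | — |
| Observation | `subject` | `effectiveDateTime` = authored |
| Condition | `subject` | `recordedDate` = authored |
| Procedure | `subject` | `performedDateTime` ← answer |
| MedicationStatement | `subject` | `effectiveDateTime` = authored |
| Immunization | `patient` | `occurrenceDateTime` ← answer |

Procedure and Immunization report when the event *happened*, not when the
patient filled in the form, so their times are never inferred from context.

### Encoding choices

Where FHIR offers several defensible encodings, the package fixes one and
exposes it through the template registry:

* yes/no/unknown presence on `Condition` → `verificationStatus`
  `confirmed` / `refuted` / `unconfirmed`; `clinicalStatus: active` is set
  only for confirmed conditions (a refuted condition with an active
  clinical status would be contradictory).
* "not vaccinated"/"unknown" on `Immunization` → `status: not-done` with a
  `statusReason` coding (SNOMED No/Unknown) rather than omitting the
  resource, so negative findings are preserved. `occurrence[x]` is
  mandatory in R4; without an answered event date the package emits
  `occurrenceString: "unknown"`.
* medication yes/no/unknown → `MedicationStatement.status`
  `active` / `not-taken` / `unknown`.
* consent yes/no → provision `permit`/`deny`; unknown omits the provision.
* demographic answers (biological sex, birth date) bind into the bundle's
  single Patient (`gender` plus, for the German official codes X/D, a
  primitive extension carrying the original coding; `birthDate`). They do
  not add bundle entries.
* resource ids are `sha1(subject | path | authored)`, making re-mapping
  idempotent and bundles byte-reproducible; entries use `PUT` requests so
  resubmission of the same response upserts rather than duplicates.
* `linkId`s are hierarchical ordinals ("1.2.3") and questionnaire-local;
  all semantics live in the path annotation.

### Meta-elements

A meta-element is a category group (`meta: true`) whose children are
condition-mapped leaves and whose visibility is controlled by a category
question ("Does the patient suffer from a chronic lung disease?"). If that
question is answered no or unknown, the children are never shown, and the
mapper emits one Condition per child with refuted or unconfirmed status —
a deliberate densification: the platform learns something about every
disease in the category from a single answer. On "yes" the children map
individually; children left unanswered produce nothing. Bundle size is
therefore `1 (Patient) + answered template-bearing leaves after meta
expansion`, counting leaves with non-Patient templates.

## The synthetic-response generator

The generator emulates an app submitting completed questionnaires: answers
uniform over each item's answer options (quantities and integers uniform
over per-item ranges declared on the questionnaire, e.g. body temperature
35–42 °C; dates uniform over 2020-03-01 … 2021-06-30; `authored` uniform
over 2021-05-01 … 2021-06-30, the kind of submission window a COVID-19
follow-up study would cover), honoring `enableWhen` exactly, with subjects
`subject-001`, `subject-002`, …. An optional skip probability (default 0)
leaves enabled items unanswered. A single seeded PRNG makes every run
reproducible byte for byte.

What it does **not** emulate: correlated or clinically plausible answer
profiles (a patient with refuted cough and 41 °C fever is possible here),
free-text variety beyond a small symptom vocabulary, out-of-domain or
malformed answers (covered instead by crafted negative fixtures), partial
submissions mid-questionnaire, and version skew between questionnaire and
response (covered by a dedicated error path). Passing tests therefore show
that the pipeline is closed over everything a *conforming* app can submit —
every option of every item is exercised — not that it is robust to
arbitrarily broken clients.

## Conformance checking

The validator is an explicit, versioned rule catalog (`conformance.RULES`)
rather than a StructureDefinition-snapshot engine: exactly one Patient per
bundle; subject/time attributes per the table above (with the
Procedure/Immunization exception); a code element with at least one coding
matching a model concept mapped to that resource type; code-element systems
restricted to the model's registered terminologies; status elements within
the template's domain; quantity units matching the model. When the caller
supplies the response's `authored` time, context-filled time attributes are
additionally checked for equality. Full terminology-server code validation
and profile-snapshot validation are intentionally out of scope.

## ODM bridge

CDISC ODM study definitions interoperate through two operations. Export
flattens the questionnaire to ODM's form → item-group → item hierarchy
(nested groups cannot be represented), pushing group visibility conditions
down onto the contained items; paths travel in `Alias` tags with context
`gecco-path`, option codings as one alias per coding (context = system
URI), units/ranges as `ucum-unit`/`range-min`/`range-max` aliases, and the
questionnaire URL as a form-level alias. Conditions use the single-equality
grammar `ITEM_OID == "codedValue"` in a `FormalExpression`; anything richer
raises `UnsupportedConditionError` instead of guessing. Conversion back
resolves multi-coded code-list items against a reference questionnaire —
the system used there wins; without a reference, ambiguity is an error.
Because flattening discards nesting, round-trip fidelity is defined
semantically: answerable items must agree on path, question text, option
codings and *effective* (inherited-plus-own) enable conditions, which is
what `semantic_items` compares.

## Problem sizes and determinism

The bundled mini-GECCO model has 16 answer-bearing nodes across 8 branches,
10 profile templates covering all seven resource types, and every answer
kind. The replicated integration test uses 10 subjects × 2 responses
(seeded); property suites run over a 200-response corpus (100 subjects × 2,
seed 1234), large enough that every answer option and both meta-expansion
branches appear many times. All randomness flows from explicit seeds; two
runs with the same configuration produce identical files.

## Known limitations

* One logical-model instance per response: the same element cannot be
  asked twice, and multi-questionnaire studies must keep element sets
  disjoint or map responses separately.
* The rule catalog approximates, but is not, full GECCO profile
  validation; a resource can pass here and still fail a stricter
  terminology-aware validator.
* The ODM subset covers study metadata needed for questionnaires (forms,
  item groups, items, code lists, single-equality conditions); clinical
  data sections, measurement units and administrative metadata are out of
  scope.
* Meta-element expansion is defined only for condition-mapped children.
* Pseudonymization, transport encryption and server submission are out of
  scope; the package starts at a decrypted QuestionnaireResponse and ends
  at a validated transaction bundle.
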