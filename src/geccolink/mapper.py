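"""Transform annotated QuestionnaireResponses into GECCO-profiled resources.

This is the core of the interface component: every answered item is bound —
via its logical-model path annotation — to its node in the logical model,
and the node's profile template turns the typed answer into a FHIR resource
(Condition, Observation, Procedure, MedicationStatement, Immunization,
Consent) carrying *all* concept codings of the node, not just the single
coding an answerOption can hold. Contextual attributes (who and when) are
filled from the response's subject and authored timestamp following the
per-resource-type rules; the Procedure and Immunization event times are the
domain-specific exception and always come from answer content.

Meta-elements — category questions gating a block of disease items — expand
on a negative/unknown category answer into one refuted/unconfirmed Condition
per child, without consulting (nonexistent) child answers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

from . import terminology as t
from .errors import (
    DuplicateAnswerError,
    MappingError,
    ModelConsistencyError,
    PathKindError,
    TemplateBindingError,
    UnknownResourceTypeError,
    UnmappedItemError,
    ValueDomainError,
)
from .model import (
    AnswerKind,
    LogicalModel,
    LogicalNode,
    ProfileTemplate,
    YNU_KINDS,
    walk_leaves,
)
from .questionnaire import item_gecco_path, iter_items, split_part


@dataclass(frozen=True)
class BindingContext:
    """Contextual information of one response: who answered, and when."""

    subject_id: str
    authored: str


@dataclass(frozen=True)
class ContextAssignment:
    """Table-driven contextual attribute assignment for one resource type."""

    subject_element: Optional[str]   # e.g. "subject" or "patient"
    subject_reference: Optional[dict]
    time_element: Optional[str]      # e.g. "recordedDate"
    time_value: Optional[str]        # None when not context-filled


# resource type -> (subject element, time element, time filled from context)
_CONTEXT_TABLE: dict[str, tuple[Optional[str], Optional[str], bool]] = {
    "Patient": (None, None, False),
    "Consent": ("patient", None, False),
    "Observation": ("subject", "effectiveDateTime", True),
    "Condition": ("subject", "recordedDate", True),
    "Procedure": ("subject", "performedDateTime", False),
    "MedicationStatement": ("subject", "effectiveDateTime", True),
    "Immunization": ("patient", "occurrenceDateTime", False),
}


def resource_id(ctx: BindingContext, path: str) -> str:
    """Deterministic resource id so that reruns are idempotent."""
    digest = hashlib.sha1(
        f"{ctx.subject_id}|{path}|{ctx.authored}".encode()
    ).hexdigest()
    return digest


def resolve_context(resource_type: str, ctx: BindingContext) -> ContextAssignment:
    """Subject/time attribute assignments for one of the seven mapped
    resource types. The Procedure and Immunization event times are never
    context-filled; their dates must come from answer content."""
    try:
        subject_el, time_el, filled = _CONTEXT_TABLE[resource_type]
    except KeyError:
        raise UnknownResourceTypeError(
            f"{resource_type!r} is not a mapped resource type"
        ) from None
    reference = None
    if subject_el is not None:
        reference = {
            "reference": f"Patient/{resource_id(ctx, 'patient')}",
            "identifier": {"value": ctx.subject_id},
        }
    return ContextAssignment(
        subject_element=subject_el,
        subject_reference=reference,
        time_element=time_el,
        time_value=ctx.authored if filled else None,
    )


@dataclass
class AnswerRecord:
    """Collected answers for one logical-model path: the main value plus
    composite parts (``date`` / ``severity``)."""

    main: Optional[dict] = None
    parts: dict[str, dict] = field(default_factory=dict)


# --------------------------------------------------------------------------
# answer-domain helpers


def _ynu_token(value: dict, path: str) -> str:
    coding = value.get("valueCoding") or {}
    token = t.YNU_TOKENS.get(coding.get("code"))
    if token is None or coding.get("system") != t.SNOMED:
        raise ValueDomainError(
            f"{path}: answer {coding!r} is not a yes/no/unknown coding"
        )
    return token


def _matched_option(node: LogicalNode, value: dict):
    coding = value.get("valueCoding") or {}
    for opt in node.answer.options:
        if (opt.primary.system == coding.get("system")
                and opt.primary.code == coding.get("code")):
            return opt
    raise ValueDomainError(
        f"{node.path}: answer {coding!r} is not among the declared options"
    )


def _severity_coding(value: dict, path: str) -> dict:
    coding = value.get("valueCoding") or {}
    for known in t.SEVERITY_SCALE:
        if (coding.get("system"), coding.get("code")) == (
                known["system"], known["code"]):
            return dict(known)
    raise ValueDomainError(f"{path}: {coding!r} is not a severity coding")


def _primitive(value: dict, key: str, path: str):
    if key not in value:
        raise ValueDomainError(
            f"{path}: expected {key}, got {sorted(value)!r}"
        )
    return value[key]


def _codeable(codings) -> dict:
    return {"coding": [c.as_fhir() for c in codings]}


# --------------------------------------------------------------------------
# template application


def apply_template(
    template: ProfileTemplate,
    node: LogicalNode,
    answer: AnswerRecord,
    ctx: BindingContext,
) -> dict:
    """Instantiate one profiled resource from a template, a model node and
    its collected answer."""
    mode = template.answer_binding.get("mode")
    builders = {
        "condition-verification": _build_condition,
        "observation-value": _build_observation,
        "medication-status": _build_medication,
        "immunization-event": _build_immunization,
        "procedure-date": _build_procedure,
        "consent-decision": _build_consent,
    }
    if mode not in builders:
        raise TemplateBindingError(
            f"{node.path}: unsupported answer binding {mode!r}"
        )
    return builders[mode](template, node, answer, ctx)


def _base_resource(template: ProfileTemplate, node: LogicalNode,
                   ctx: BindingContext) -> dict:
    resource: dict = {"resourceType": template.resource_type,
                      "id": resource_id(ctx, node.path)}
    for element, value in template.fixed_elements.items():
        resource[element] = _copy_json(value)
    assignment = resolve_context(template.resource_type, ctx)
    if assignment.subject_element is not None:
        resource[assignment.subject_element] = assignment.subject_reference
    if assignment.time_element is not None and assignment.time_value is not None:
        resource[assignment.time_element] = assignment.time_value
    return resource


def _copy_json(value):
    import copy

    return copy.deepcopy(value)


def _require_main(node: LogicalNode, answer: AnswerRecord) -> dict:
    if answer.main is None:
        raise TemplateBindingError(
            f"{node.path}: composite part answered without its main answer"
        )
    return answer.main


def _build_condition(template, node, answer: AnswerRecord, ctx,
                     forced_token: Optional[str] = None) -> dict:
    resource = _base_resource(template, node, ctx)
    resource["code"] = _codeable(node.concept_codings)
    token = forced_token or _ynu_token(_require_main(node, answer), node.path)
    resource["verificationStatus"] = {
        "coding": [dict(t.VERIFICATION_BY_TOKEN[token])]
    }
    if token == "yes":
        resource["clinicalStatus"] = {"coding": [dict(t.CLINICAL_ACTIVE)]}
        if "severity" in answer.parts:
            resource["severity"] = {
                "coding": [_severity_coding(answer.parts["severity"], node.path)]
            }
    return resource


def _build_observation(template, node, answer: AnswerRecord, ctx) -> dict:
    resource = _base_resource(template, node, ctx)
    resource["code"] = _codeable(node.concept_codings)
    value = _require_main(node, answer)
    kind = node.answer.kind
    if kind == AnswerKind.QUANTITY:
        quantity = _primitive(value, "valueQuantity", node.path)
        if quantity.get("code") != node.answer.unit:
            raise ValueDomainError(
                f"{node.path}: unit {quantity.get('code')!r} does not match "
                f"the declared unit {node.answer.unit!r}"
            )
        resource["valueQuantity"] = _copy_json(quantity)
    elif kind == AnswerKind.CODED_CHOICE:
        option = _matched_option(node, value)
        resource["valueCodeableConcept"] = _codeable(option.all_codings())
    elif kind == AnswerKind.DATETIME:
        resource["valueDateTime"] = _primitive(value, "valueDateTime", node.path)
    elif kind == AnswerKind.DATE:
        resource["valueDateTime"] = _primitive(value, "valueDate", node.path)
    elif kind == AnswerKind.INTEGER:
        resource["valueInteger"] = int(_primitive(value, "valueInteger", node.path))
    elif kind == AnswerKind.TEXT:
        resource["valueString"] = _primitive(value, "valueString", node.path)
    else:
        raise TemplateBindingError(
            f"{node.path}: cannot bind {kind.value} to an Observation value"
        )
    return resource


def _build_medication(template, node, answer: AnswerRecord, ctx) -> dict:
    resource = _base_resource(template, node, ctx)
    resource["medicationCodeableConcept"] = _codeable(node.concept_codings)
    token = _ynu_token(_require_main(node, answer), node.path)
    resource["status"] = t.MEDICATION_STATUS_BY_TOKEN[token]
    return resource


def _build_immunization(template, node, answer: AnswerRecord, ctx) -> dict:
    resource = _base_resource(template, node, ctx)
    resource["vaccineCode"] = _codeable(node.concept_codings)
    token = _ynu_token(_require_main(node, answer), node.path)
    resource["status"] = t.IMMUNIZATION_STATUS_BY_TOKEN[token]
    if token != "yes":
        reason = t.NO if token == "no" else t.UNKNOWN
        resource["statusReason"] = {"coding": [dict(reason)]}
    date_part = answer.parts.get("date")
    if token == "yes" and date_part is not None:
        resource["occurrenceDateTime"] = _primitive(
            date_part, "valueDate", node.path)
    else:
        # occurrence[x] is mandatory in FHIR R4; without an answered event
        # date there is nothing context-appropriate to put here
        resource["occurrenceString"] = "unknown"
    return resource


def _build_procedure(template, node, answer: AnswerRecord, ctx) -> dict:
    resource = _base_resource(template, node, ctx)
    resource["code"] = _codeable(node.concept_codings)
    resource.setdefault("status", "completed")
    value = _require_main(node, answer)
    resource["performedDateTime"] = _primitive(value, "valueDate", node.path)
    return resource


def _build_consent(template, node, answer: AnswerRecord, ctx) -> dict:
    resource = _base_resource(template, node, ctx)
    resource["status"] = "active"
    resource["category"] = [_codeable(node.concept_codings)]
    token = _ynu_token(_require_main(node, answer), node.path)
    if token in ("yes", "no"):
        resource["provision"] = {"type": "permit" if token == "yes" else "deny"}
    return resource


# --------------------------------------------------------------------------
# meta-element expansion


def expand_meta(
    category_answer: str,
    category_node: LogicalNode,
    model: LogicalModel,
    ctx: BindingContext,
) -> list[dict]:
    """Default a meta category's children from the category answer.

    For a ``no``/``unknown`` category answer, one Condition per child is
    emitted with refuted/unconfirmed presence, independent of any child
    answers. For ``yes`` nothing is emitted here — children are then mapped
    individually from their own answers.
    """
    if not category_node.is_meta:
        raise MappingError(f"{category_node.path} is not a meta element")
    if category_answer == "yes":
        return []
    if category_answer not in ("no", "unknown"):
        raise ValueDomainError(
            f"{category_node.path}: invalid category answer "
            f"{category_answer!r}"
        )
    conditions = []
    for child in category_node.children:
        template = (model.templates.get(child.target_template)
                    if child.target_template else None)
        if child.children or template is None or template.resource_type != "Condition":
            raise ModelConsistencyError(
                f"meta element {category_node.path}: child {child.path} is "
                f"not a condition-mapped leaf"
            )
        conditions.append(
            _build_condition(template, child, AnswerRecord(), ctx,
                             forced_token=category_answer)
        )
    return conditions


# --------------------------------------------------------------------------
# response mapping


def _collect_answers(response: dict) -> dict[str, AnswerRecord]:
    records: dict[str, AnswerRecord] = {}
    for item in iter_items(response):
        answers = item.get("answer", [])
        if not answers:
            continue
        annotation = item_gecco_path(item)
        if annotation is None:
            raise UnmappedItemError(
                f"answered item {item.get('linkId')!r} carries no "
                f"logical-model path annotation"
            )
        if len(answers) > 1:
            raise DuplicateAnswerError(
                f"{annotation}: repeated answers are not supported"
            )
        base, part = split_part(annotation)
        record = records.setdefault(base, AnswerRecord())
        if part is None:
            if record.main is not None:
                raise DuplicateAnswerError(
                    f"path {base!r} is answered more than once"
                )
            record.main = answers[0]
        else:
            if part in record.parts:
                raise DuplicateAnswerError(
                    f"part {annotation!r} is answered more than once"
                )
            record.parts[part] = answers[0]
    return records


def binding_context(response: dict) -> BindingContext:
    subject = (response.get("subject") or {}).get("identifier", {}).get("value")
    authored = response.get("authored")
    if not subject or not authored:
        raise MappingError(
            "response must carry a subject identifier and an authored "
            "timestamp before mapping"
        )
    return BindingContext(subject_id=subject, authored=authored)


def _build_patient(model: LogicalModel, ctx: BindingContext) -> dict:
    return {
        "resourceType": "Patient",
        "id": resource_id(ctx, "patient"),
        "meta": {
            "profile": [
                model.canonical_base.rstrip("/")
                + "/StructureDefinition/gecco-patient"
            ]
        },
        "identifier": [
            {
                "system": model.canonical_base.rstrip("/") + "/identifiers/subject-id",
                "value": ctx.subject_id,
            }
        ],
    }


def _bind_patient_field(patient: dict, template: ProfileTemplate,
                        node: LogicalNode, answer: AnswerRecord) -> None:
    field_name = template.answer_binding.get("field")
    value = _require_main(node, answer)
    if field_name == "gender":
        option = _matched_option(node, value)
        gender = t.ADMINISTRATIVE_GENDER.get(option.primary.code, "other")
        patient["gender"] = gender
        if option.primary.system == t.GENDER_AMTLICH_DE:
            patient["_gender"] = {
                "extension": [
                    {
                        "url": "http://fhir.de/StructureDefinition/gender-amtlich-de",
                        "valueCoding": option.primary.as_fhir(),
                    }
                ]
            }
    elif field_name == "birthDate":
        patient["birthDate"] = _primitive(value, "valueDate", node.path)
    else:
        raise TemplateBindingError(
            f"{node.path}: unknown patient field {field_name!r}"
        )


def map_response(response: dict, model: LogicalModel) -> dict:
    """Map one annotated QuestionnaireResponse to a transaction Bundle of
    profiled resources.

    The bundle contains exactly one Patient (identifier = the response's
    subject token) plus one resource per answered template-bearing leaf
    after meta-element expansion; demographic answers bind into the Patient
    itself. Resource ids are deterministic, so remapping the same response
    yields byte-identical output.
    """
    ctx = binding_context(response)
    records = _collect_answers(response)

    # resolve every answered path up front
    for path in records:
        node = model.find(path)
        if node is None:
            raise UnmappedItemError(
                f"annotation {path!r} does not resolve in model {model.name!r}"
            )
        if node.answer is None:
            raise PathKindError(f"annotation {path!r} resolves to a group")

    # meta-element expansion: category answered no/unknown defaults children
    expanded: dict[str, dict] = {}     # child path -> emitted Condition
    suppressed: set[str] = set()       # child paths not mapped individually
    for node in model.walk():
        if not node.is_meta or node.enable is None:
            continue
        ctrl = records.get(node.enable.controlling_path)
        if ctrl is None or ctrl.main is None:
            continue
        token = _ynu_token(ctrl.main, node.enable.controlling_path)
        if token in ("no", "unknown"):
            for child, condition in zip(
                node.children, expand_meta(token, node, model, ctx)
            ):
                expanded[child.path] = condition
                suppressed.add(child.path)

    patient = _build_patient(model, ctx)
    resources: list[dict] = [patient]
    for leaf in walk_leaves(model):
        if leaf.path in expanded:
            resources.append(expanded[leaf.path])
            continue
        record = records.get(leaf.path)
        if record is None or leaf.path in suppressed:
            continue
        if leaf.target_template is None:
            continue  # pure category/controlling questions map to nothing
        template = model.templates[leaf.target_template]
        if template.resource_type == "Patient":
            _bind_patient_field(patient, template, leaf, record)
        else:
            resources.append(apply_template(template, leaf, record, ctx))

    base = model.canonical_base.rstrip("/")
    return {
        "resourceType": "Bundle",
        "type": "transaction",
        "entry": [
            {
                "fullUrl": f"{base}/{r['resourceType']}/{r['id']}",
                "resource": r,
                "request": {
                    "method": "PUT",
                    "url": f"{r['resourceType']}/{r['id']}",
                },
            }
            for r in resources
        ],
    }
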