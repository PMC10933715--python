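"""Rule-based conformance checking of mapped bundles.

A lightweight, explicit rule catalog stands in for full FHIR profile
(StructureDefinition snapshot) validation: it checks the structural contract
every mapped bundle must satisfy — exactly one Patient, the per-type subject
and time attributes (with the Procedure/Immunization exception, whose event
times come from answers), a code element carrying at least one of the
model's concept codings, registered terminology systems only, template-
conformant status elements, and model-conformant quantity units.

The catalog is versioned via :data:`RULES`; reports serialize to JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ParseError
from .model import LogicalModel, LogicalNode

#: rule id -> human description (the versioned rule catalog)
RULES: dict[str, str] = {
    "bundle-type": "Bundle.type must be 'transaction'",
    "patient-required": "bundle must contain exactly one Patient resource",
    "subject-required": "resource must carry its subject-specifying attribute",
    "subject-reference": "subject attribute must reference the bundle's Patient",
    "time-required": "resource must carry its time-specifying attribute",
    "time-context": "context-filled time attribute must equal the response's "
                    "authored timestamp",
    "code-required": "resource must carry a code element with at least one coding",
    "code-unknown": "code element must contain a coding of a model concept "
                    "mapped to this resource type",
    "system-unregistered": "code-element coding systems must be registered in "
                           "the model",
    "status-invalid": "status element must match the template",
    "unit-mismatch": "quantity unit must match the model's declared unit",
}

#: resource type -> (subject element, time element, context-filled)
CONTEXT_ATTRIBUTES: dict[str, tuple[Optional[str], Optional[str], bool]] = {
    "Patient": (None, None, False),
    "Consent": ("patient", None, False),
    "Observation": ("subject", "effectiveDateTime", True),
    "Condition": ("subject", "recordedDate", True),
    "Procedure": ("subject", "performedDateTime", False),
    "MedicationStatement": ("subject", "effectiveDateTime", True),
    "Immunization": ("patient", "occurrenceDateTime", False),
}

#: where each resource type keeps its concept codings
_CODE_ELEMENT: dict[str, str] = {
    "Condition": "code",
    "Observation": "code",
    "Procedure": "code",
    "MedicationStatement": "medicationCodeableConcept",
    "Immunization": "vaccineCode",
    "Consent": "category",
}

_STATUS_DOMAIN = {
    "condition-verification": ("verificationStatus",
                               {"confirmed", "refuted", "unconfirmed"}),
    "medication-status": ("status", {"active", "not-taken", "unknown"}),
    "immunization-event": ("status", {"completed", "not-done"}),
    "consent-decision": ("status", {"active"}),
}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str          # "error" | "warning"
    resource_index: int    # entry position in the bundle, -1 for bundle-level
    rule_id: str
    message: str

    def to_dict(self) -> dict:
        return {
            "severity": self.severity,
            "resourceIndex": self.resource_index,
            "ruleId": self.rule_id,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    resources_checked: int = 0

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "resourcesChecked": self.resources_checked,
            "issues": [i.to_dict() for i in self.issues],
        }


def _codings_of(element) -> list[dict]:
    """Codings of a CodeableConcept or a list of CodeableConcepts."""
    if isinstance(element, list):
        return [c for part in element for c in _codings_of(part)]
    if isinstance(element, dict):
        return list(element.get("coding", []))
    return []


def _concept_index(model: LogicalModel) -> dict[tuple[str, str], LogicalNode]:
    index: dict[tuple[str, str], LogicalNode] = {}
    for node in model.walk():
        if node.target_template is None:
            continue
        for coding in node.concept_codings:
            index.setdefault(coding.key(), node)
    return index


def validate_bundle(
    bundle: dict,
    model: LogicalModel,
    authored: Optional[str] = None,
) -> ValidationReport:
    """Check a mapped bundle against the rule catalog.

    When the response's ``authored`` timestamp is supplied, the context-
    filled time attributes are additionally checked for equality with it.
    Raises :class:`ParseError` if ``bundle`` is not a FHIR Bundle structure.
    """
    if not isinstance(bundle, dict) or bundle.get("resourceType") != "Bundle":
        raise ParseError("document is not a FHIR Bundle")
    entries = bundle.get("entry", [])
    if not isinstance(entries, list) or any(
        not isinstance(e, dict) or not isinstance(e.get("resource"), dict)
        for e in entries
    ):
        raise ParseError("malformed bundle entries")

    report = ValidationReport(resources_checked=len(entries))
    err = lambda idx, rule, msg: report.issues.append(  # noqa: E731
        ValidationIssue("error", idx, rule, msg))

    if bundle.get("type") != "transaction":
        err(-1, "bundle-type", f"bundle type is {bundle.get('type')!r}")

    resources = [e["resource"] for e in entries]
    patients = [
        (i, r) for i, r in enumerate(resources)
        if r.get("resourceType") == "Patient"
    ]
    if len(patients) != 1:
        err(-1, "patient-required",
            f"bundle contains {len(patients)} Patient resources")
    patient_ref = (
        f"Patient/{patients[0][1].get('id')}" if len(patients) == 1 else None
    )

    index = _concept_index(model)
    registered = model.registered_systems()

    for i, resource in enumerate(resources):
        rtype = resource.get("resourceType")
        if rtype == "Patient" or rtype not in CONTEXT_ATTRIBUTES:
            continue
        _check_context(resource, i, rtype, patient_ref, authored, err)
        node = _check_code(resource, i, rtype, index, registered, err)
        if node is not None:
            _check_template(resource, i, rtype, node, model, err)
    return report


def _check_context(resource, i, rtype, patient_ref, authored, err) -> None:
    subject_el, time_el, context_filled = CONTEXT_ATTRIBUTES[rtype]
    subject = resource.get(subject_el)
    if not isinstance(subject, dict) or not subject.get("reference"):
        err(i, "subject-required",
            f"{rtype}.{subject_el} missing or without reference")
    elif patient_ref is not None and subject["reference"] != patient_ref:
        err(i, "subject-reference",
            f"{rtype}.{subject_el} references {subject['reference']!r}, "
            f"expected {patient_ref!r}")
    if time_el is None:
        return
    time_value = resource.get(time_el)
    if rtype == "Immunization" and time_value is None:
        time_value = resource.get("occurrenceString")
    if rtype == "Procedure" and time_value is None:
        time_value = resource.get("performedPeriod")
    if time_value is None:
        err(i, "time-required", f"{rtype}.{time_el} is missing")
    elif context_filled and authored is not None and time_value != authored:
        err(i, "time-context",
            f"{rtype}.{time_el} = {time_value!r} differs from authored "
            f"{authored!r}")


def _check_code(resource, i, rtype, index, registered, err):
    element_name = _CODE_ELEMENT[rtype]
    codings = _codings_of(resource.get(element_name))
    if not codings:
        err(i, "code-required", f"{rtype}.{element_name} has no coding")
        return None
    unregistered = sorted(
        {c.get("system", "") for c in codings} - registered
    )
    if unregistered:
        err(i, "system-unregistered",
            f"{rtype}.{element_name} uses unregistered systems "
            f"{unregistered!r}")
    node = None
    for coding in codings:
        node = index.get((coding.get("system"), coding.get("code")))
        if node is not None:
            break
    if node is None:
        err(i, "code-unknown",
            f"{rtype}.{element_name} matches no model concept")
    return node


def _check_template(resource, i, rtype, node: LogicalNode,
                    model: LogicalModel, err) -> None:
    template = model.templates.get(node.target_template)
    if template is None or template.resource_type != rtype:
        err(i, "code-unknown",
            f"{rtype} concept {node.path!r} is mapped to "
            f"{template.resource_type if template else None!r}")
        return
    fixed_status = template.fixed_elements.get("status")
    if fixed_status is not None and resource.get("status") != fixed_status:
        err(i, "status-invalid",
            f"{rtype}.status = {resource.get('status')!r}, template fixes "
            f"{fixed_status!r}")
    mode = template.answer_binding.get("mode")
    domain = _STATUS_DOMAIN.get(mode)
    if domain is not None:
        element, allowed = domain
        value = resource.get(element)
        if element == "verificationStatus":
            codes = {c.get("code") for c in _codings_of(value)}
            if not codes or not codes <= allowed:
                err(i, "status-invalid",
                    f"{rtype}.verificationStatus {sorted(codes)!r} outside "
                    f"{sorted(allowed)!r}")
        elif value not in allowed:
            err(i, "status-invalid",
                f"{rtype}.{element} = {value!r} outside {sorted(allowed)!r}")
    if rtype == "Observation" and "valueQuantity" in resource:
        unit = resource["valueQuantity"].get("code")
        declared = node.answer.unit if node.answer else None
        if declared is not None and unit != declared:
            err(i, "unit-mismatch",
                f"Observation unit {unit!r} differs from declared "
                f"{declared!r}")
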