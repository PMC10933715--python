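"""Terminology constants: code-system URIs and the fixed answer scales.

The medical terminologies used throughout are the ones the GECCO data set is
coded with: SNOMED CT, LOINC, ICD-10-GM, ATC and UCUM, plus per-model custom
code systems (e.g. a COVID-19 vaccine list and ventilation types) registered
under the model's canonical base.
"""

from __future__ import annotations

SNOMED = "http://snomed.info/sct"
LOINC = "http://loinc.org"
ICD10GM = "http://fhir.de/CodeSystem/bfarm/icd-10-gm"
ATC = "http://fhir.de/CodeSystem/bfarm/atc"
UCUM = "http://unitsofmeasure.org"
GENDER_AMTLICH_DE = "http://fhir.de/CodeSystem/gender-amtlich-de"

#: shorthand tokens accepted in model definition documents
SYSTEM_ALIASES: dict[str, str] = {
    "snomed": SNOMED,
    "loinc": LOINC,
    "icd10gm": ICD10GM,
    "atc": ATC,
    "ucum": UCUM,
    "gender-amtlich-de": GENDER_AMTLICH_DE,
}

# HL7 terminology code systems used by the mapper's status elements.
CONDITION_VER_STATUS = "http://terminology.hl7.org/CodeSystem/condition-ver-status"
CONDITION_CLINICAL = "http://terminology.hl7.org/CodeSystem/condition-clinical"
CONSENT_SCOPE = "http://terminology.hl7.org/CodeSystem/consentscope"
OBSERVATION_CATEGORY = "http://terminology.hl7.org/CodeSystem/observation-category"
CONDITION_CATEGORY = "http://terminology.hl7.org/CodeSystem/condition-category"

# yes / no / unknown — the ubiquitous three-point scale of the data set.
YES = {"system": SNOMED, "code": "373066001", "display": "Yes"}
NO = {"system": SNOMED, "code": "373067005", "display": "No"}
UNKNOWN = {"system": SNOMED, "code": "261665006", "display": "Unknown"}
YES_NO_UNKNOWN = (YES, NO, UNKNOWN)

#: semantic token per yes/no/unknown code, used by enable rules ("= yes")
#: and by the meta-element expansion.
YNU_TOKENS: dict[str, str] = {
    YES["code"]: "yes",
    NO["code"]: "no",
    UNKNOWN["code"]: "unknown",
}

# Symptom severity: fixed three-point coded scale (SNOMED severity findings).
SEVERITY_MILD = {"system": SNOMED, "code": "255604002", "display": "Mild"}
SEVERITY_MODERATE = {"system": SNOMED, "code": "6736007", "display": "Moderate"}
SEVERITY_SEVERE = {"system": SNOMED, "code": "24484000", "display": "Severe"}
SEVERITY_SCALE = (SEVERITY_MILD, SEVERITY_MODERATE, SEVERITY_SEVERE)

# Condition verification status per yes/no/unknown answer. "unknown" is
# rendered as "unconfirmed" on the verification element (configurable at the
# template level via fixed elements).
VERIFICATION_BY_TOKEN = {
    "yes": {"system": CONDITION_VER_STATUS, "code": "confirmed", "display": "Confirmed"},
    "no": {"system": CONDITION_VER_STATUS, "code": "refuted", "display": "Refuted"},
    "unknown": {"system": CONDITION_VER_STATUS, "code": "unconfirmed", "display": "Unconfirmed"},
}

CLINICAL_ACTIVE = {"system": CONDITION_CLINICAL, "code": "active", "display": "Active"}

#: MedicationStatement.status per yes/no/unknown answer
MEDICATION_STATUS_BY_TOKEN = {"yes": "active", "no": "not-taken", "unknown": "unknown"}

#: Immunization.status per yes/no/unknown answer (FHIR R4 allows only
#: completed / entered-in-error / not-done; "unknown" maps to not-done with a
#: statusReason carrying the unknown coding)
IMMUNIZATION_STATUS_BY_TOKEN = {"yes": "completed", "no": "not-done", "unknown": "not-done"}

#: administrative gender token per biological-sex answer code
ADMINISTRATIVE_GENDER = {
    "248153007": "male",     # SNOMED Male
    "248152002": "female",   # SNOMED Female
    "261665006": "unknown",  # SNOMED Unknown
    "X": "other",            # gender-amtlich-de: divers
    "D": "other",            # gender-amtlich-de: unbestimmt
}


def resolve_system(token: str) -> str:
    """Expand a shorthand system token to its canonical URI.

    Full URIs pass through unchanged; unknown shorthands are treated as
    custom-system URIs and returned verbatim.
    """
    return SYSTEM_ALIASES.get(token, token)
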