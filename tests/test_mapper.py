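"""Response-to-resource mapping: templates, context rules, meta expansion."""

import copy
import json

import pytest

from geccolink import map_response, resolve_context, expand_meta
from geccolink.mapper import AnswerRecord, BindingContext, apply_template
from geccolink import terminology as t
from geccolink.errors import (
    DuplicateAnswerError,
    PathKindError,
    UnknownResourceTypeError,
    UnmappedItemError,
    ValueDomainError,
)
from geccolink.questionnaire import item_gecco_path, iter_items

from oracles import expected_bundle_size

CTX = BindingContext(subject_id="S1", authored="2021-05-01T10:00:00+00:00")
ANN = ("https://example.org/fhir/geccolink"
       "/StructureDefinition/compass-gecco-item")


def _response(items, subject="S1", authored="2021-05-01T10:00:00+00:00"):
    return {
        "resourceType": "QuestionnaireResponse",
        "status": "completed",
        "subject": {"identifier": {"value": subject}},
        "authored": authored,
        "item": items,
    }


def _answer_item(link, path, value):
    return {
        "linkId": link,
        "extension": [{"url": ANN, "valueString": path}],
        "answer": [value],
    }


def _resources(bundle):
    return [e["resource"] for e in bundle["entry"]]


def _of_type(bundle, rtype):
    return [r for r in _resources(bundle) if r["resourceType"] == rtype]


class TestResolveContext:
    @pytest.mark.parametrize(
        "rtype,subject_el,time_el,filled",
        [
            ("Patient", None, None, False),
            ("Consent", "patient", None, False),
            ("Observation", "subject", "effectiveDateTime", True),
            ("Condition", "subject", "recordedDate", True),
            ("Procedure", "subject", "performedDateTime", False),
            ("MedicationStatement", "subject", "effectiveDateTime", True),
            ("Immunization", "patient", "occurrenceDateTime", False),
        ],
    )
    def test_table_assignments(self, rtype, subject_el, time_el, filled):
        assignment = resolve_context(rtype, CTX)
        assert assignment.subject_element == subject_el
        assert assignment.time_element == time_el
        if filled:
            assert assignment.time_value == CTX.authored
        else:
            assert assignment.time_value is None

    def test_unknown_type(self):
        with pytest.raises(UnknownResourceTypeError):
            resolve_context("Device", CTX)


class TestApplyTemplate:
    def test_yes_answer_gives_confirmed_condition_with_all_codings(self, model):
        node = model.find("anamnesis.chronicLungDisease.asthma")
        template = model.templates[node.target_template]
        resource = apply_template(
            template, node, AnswerRecord(main={"valueCoding": dict(t.YES)}), CTX)
        assert resource["resourceType"] == "Condition"
        codes = {(c["system"], c["code"]) for c in resource["code"]["coding"]}
        assert codes == {c.key() for c in node.concept_codings}
        assert len(codes) == 2  # ICD-10-GM and SNOMED CT
        assert resource["verificationStatus"]["coding"][0]["code"] == "confirmed"
        assert resource["recordedDate"] == CTX.authored

    def test_quantity_observation_binding(self, model):
        node = model.find("vitalSigns.bodyTemperature")
        template = model.templates[node.target_template]
        value = {"valueQuantity": {"value": 37.8, "unit": "Cel",
                                   "system": t.UCUM, "code": "Cel"}}
        resource = apply_template(template, node, AnswerRecord(main=value), CTX)
        assert resource["valueQuantity"]["value"] == 37.8
        assert resource["effectiveDateTime"] == CTX.authored
        assert resource["status"] == "final"

    def test_severity_composite_gives_single_condition_with_severity(self, model):
        node = model.find("symptoms.cough")
        template = model.templates[node.target_template]
        record = AnswerRecord(
            main={"valueCoding": dict(t.YES)},
            parts={"severity": {"valueCoding": dict(t.SEVERITY_MILD)}},
        )
        resource = apply_template(template, node, record, CTX)
        assert resource["resourceType"] == "Condition"
        assert resource["severity"]["coding"][0]["code"] == t.SEVERITY_MILD["code"]
        assert resource["verificationStatus"]["coding"][0]["code"] == "confirmed"

    def test_coded_choice_emits_all_codings_of_chosen_option(self, model):
        node = model.find("therapy.ventilationType")
        template = model.templates[node.target_template]
        option = node.answer.options[1]  # non-invasive ventilation
        record = AnswerRecord(main={"valueCoding": option.primary.as_fhir()})
        resource = apply_template(template, node, record, CTX)
        emitted = {(c["system"], c["code"])
                   for c in resource["valueCodeableConcept"]["coding"]}
        assert emitted == {c.key() for c in option.all_codings()}
        assert len(emitted) == 2  # custom system plus SNOMED CT


class TestMapResponse:
    def test_empty_response_maps_to_patient_only(self, model):
        bundle = map_response(_response([]), model)
        (resource,) = _resources(bundle)
        assert resource["resourceType"] == "Patient"
        assert resource["identifier"][0]["value"] == "S1"

    def test_observation_context_attributes(self, model, questionnaire):
        items = [_answer_item(
            "6.1", "vitalSigns.bodyTemperature",
            {"valueQuantity": {"value": 38.2, "unit": "Cel",
                               "system": t.UCUM, "code": "Cel"}})]
        bundle = map_response(_response(items), model)
        (observation,) = _of_type(bundle, "Observation")
        (patient,) = _of_type(bundle, "Patient")
        assert observation["subject"]["reference"] == f"Patient/{patient['id']}"
        assert observation["effectiveDateTime"] == CTX.authored

    def test_vaccination_date_comes_from_answer_not_authored(self, model):
        items = [
            _answer_item("7.1", "vaccination.covid19Vaccination",
                         {"valueCoding": dict(t.YES)}),
            _answer_item("7.1.1", "vaccination.covid19Vaccination#date",
                         {"valueDate": "2021-03-04"}),
        ]
        bundle = map_response(_response(items), model)
        (immunization,) = _of_type(bundle, "Immunization")
        assert immunization["occurrenceDateTime"] == "2021-03-04"
        assert immunization["occurrenceDateTime"] != CTX.authored
        assert immunization["status"] == "completed"
        assert immunization["patient"]["reference"].startswith("Patient/")

    def test_demographics_bind_into_patient(self, model):
        items = [
            _answer_item("2.1", "demographics.biologicalSex",
                         {"valueCoding": {"system": t.SNOMED,
                                          "code": "248152002",
                                          "display": "Female"}}),
            _answer_item("2.2", "demographics.dateOfBirth",
                         {"valueDate": "1957-11-02"}),
        ]
        bundle = map_response(_response(items), model)
        (patient,) = _resources(bundle)
        assert patient["gender"] == "female"
        assert patient["birthDate"] == "1957-11-02"

    def test_mapping_is_deterministic(self, model, annotated_corpus):
        a = map_response(annotated_corpus[0], model)
        b = map_response(annotated_corpus[0], model)
        assert json.dumps(a) == json.dumps(b)

    def test_subject_closure(self, model, annotated_corpus):
        for response in annotated_corpus[:50]:
            bundle = map_response(response, model)
            (patient,) = _of_type(bundle, "Patient")
            ref = f"Patient/{patient['id']}"
            for resource in _resources(bundle):
                if resource["resourceType"] == "Patient":
                    continue
                element = ("patient" if resource["resourceType"]
                           in ("Consent", "Immunization") else "subject")
                assert resource[element]["reference"] == ref

    def test_bundle_size_matches_counting_oracle(self, model, annotated_corpus):
        for response in annotated_corpus[:100]:
            bundle = map_response(response, model)
            assert len(bundle["entry"]) == expected_bundle_size(response, model)


class TestMetaExpansion:
    def test_category_no_defaults_children_to_refuted(self, model):
        items = [_answer_item("1.1", "anamnesis.hasChronicLungDisease",
                              {"valueCoding": dict(t.NO)})]
        bundle = map_response(_response(items), model)
        conditions = _of_type(bundle, "Condition")
        assert len(conditions) == 2  # asthma and copd
        for condition in conditions:
            assert condition["verificationStatus"]["coding"][0]["code"] == "refuted"
            assert "clinicalStatus" not in condition
            assert "severity" not in condition

    def test_category_unknown_marks_all_children_unconfirmed(self, model):
        items = [_answer_item("1.1", "anamnesis.hasChronicLungDisease",
                              {"valueCoding": dict(t.UNKNOWN)})]
        bundle = map_response(_response(items), model)
        conditions = _of_type(bundle, "Condition")
        group = model.find("anamnesis.chronicLungDisease")
        assert len(conditions) == len(group.children)
        for condition in conditions:
            assert condition["verificationStatus"]["coding"][0]["code"] == "unconfirmed"

    def test_category_yes_maps_only_answered_children(self, model):
        items = [
            _answer_item("1.1", "anamnesis.hasChronicLungDisease",
                         {"valueCoding": dict(t.YES)}),
            _answer_item("1.2.1", "anamnesis.chronicLungDisease.asthma",
                         {"valueCoding": dict(t.YES)}),
            # copd left unanswered
        ]
        bundle = map_response(_response(items), model)
        conditions = _of_type(bundle, "Condition")
        assert len(conditions) == 1
        asthma_codes = {c["code"] for c in conditions[0]["code"]["coding"]}
        assert "195967001" in asthma_codes
        assert conditions[0]["verificationStatus"]["coding"][0]["code"] == "confirmed"

    def test_expand_meta_direct(self, model):
        group = model.find("anamnesis.chronicLungDisease")
        conditions = expand_meta("unknown", group, model, CTX)
        assert len(conditions) == len(group.children)
        assert expand_meta("yes", group, model, CTX) == []


class TestMappingErrors:
    def test_unannotated_answered_item(self, model):
        items = [{"linkId": "6.1",
                  "answer": [{"valueInteger": 20}]}]
        with pytest.raises(UnmappedItemError):
            map_response(_response(items), model)

    def test_unresolvable_annotation(self, model):
        items = [_answer_item("9.9", "nowhere.path", {"valueInteger": 1})]
        with pytest.raises(UnmappedItemError):
            map_response(_response(items), model)

    def test_path_resolving_to_group(self, model):
        items = [_answer_item("1", "anamnesis", {"valueCoding": dict(t.YES)})]
        with pytest.raises(PathKindError):
            map_response(_response(items), model)

    def test_duplicate_path_answer(self, model):
        item = _answer_item("6.2", "vitalSigns.respiratoryRate",
                            {"valueInteger": 18})
        dup = copy.deepcopy(item)
        dup["linkId"] = "6.9"
        with pytest.raises(DuplicateAnswerError):
            map_response(_response([item, dup]), model)

    def test_value_outside_option_domain(self, model):
        items = [_answer_item(
            "1.1", "anamnesis.hasChronicLungDisease",
            {"valueCoding": {"system": t.SNOMED, "code": "999999"}})]
        with pytest.raises(ValueDomainError):
            map_response(_response(items), model)

    def test_unit_mismatch_is_value_domain_error(self, model):
        items = [_answer_item(
            "6.1", "vitalSigns.bodyTemperature",
            {"valueQuantity": {"value": 99.5, "unit": "degF",
                               "system": t.UCUM, "code": "[degF]"}})]
        with pytest.raises(ValueDomainError):
            map_response(_response(items), model)


def test_pipeline_round_trip_is_annotation_order_independent(
        model, questionnaire, annotated_corpus):
    """Mapping consumes annotations, not linkIds: re-labelling linkIds of an
    annotated response leaves the mapped bundle unchanged."""
    response = copy.deepcopy(annotated_corpus[0])
    for i, item in enumerate(iter_items(response)):
        item["linkId"] = f"X{i}"
    assert json.dumps(map_response(response, model)) == \
        json.dumps(map_response(annotated_corpus[0], model))
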