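"""CDISC ODM bridge: parse, convert, export, and round-trip equivalence."""

import pytest
from lxml import etree

from geccolink import (
    convert_odm,
    odm_export,
    parse_odm,
    semantic_items,
    semantically_equal,
)
from geccolink.errors import (
    AmbiguousCodingError,
    OdmReferenceError,
    ParseError,
    UnsupportedConditionError,
)
from geccolink.odm import ODM_NS
from geccolink.questionnaire import item_gecco_path, iter_items
from geccolink import terminology as t

EMPTY_ODM = f"""<ODM xmlns="{ODM_NS}">
  <Study OID="S.1">
    <GlobalVariables><StudyName>empty</StudyName></GlobalVariables>
    <MetaDataVersion OID="MDV.1" Name="m"/>
  </Study>
</ODM>"""


@pytest.fixture(scope="module")
def exported_xml(questionnaire):
    return odm_export(questionnaire)


@pytest.fixture(scope="module")
def study(exported_xml):
    return parse_odm(exported_xml)


class TestParse:
    def test_items_carry_path_aliases(self, study):
        item = study.items["I.anamnesis.hasChronicLungDisease"]
        assert ("gecco-path", "anamnesis.hasChronicLungDisease") in item.aliases
        assert item.question == ("Does the patient suffer from a chronic "
                                 "lung disease?")

    def test_itemdef_count_matches_answerable_items(self, study, questionnaire):
        answerable = [i for i in iter_items(questionnaire)
                      if i.get("type") != "group"]
        assert len(study.items) == len(answerable)

    def test_empty_odm(self):
        parsed = parse_odm(EMPTY_ODM)
        assert parsed.forms == [] and parsed.items == {}

    def test_malformed_xml(self):
        with pytest.raises(ParseError):
            parse_odm("<ODM><unclosed>")
        with pytest.raises(ParseError):
            parse_odm("<NotOdm/>")

    def test_dangling_codelist_reference(self, exported_xml):
        broken = exported_xml.replace(
            'CodeListOID="CL.I.anamnesis.hasChronicLungDisease"',
            'CodeListOID="CL.MISSING"', 1)
        with pytest.raises(OdmReferenceError):
            parse_odm(broken)

    def test_condition_parsed_to_equality(self, study):
        cond = study.conditions["C.I.anamnesis.chronicLungDisease.asthma"]
        assert cond.controlling_item_oid == "I.anamnesis.hasChronicLungDisease"
        assert cond.required_coded_value == t.YES["code"]

    def test_unsupported_condition_expression(self, exported_xml):
        broken = exported_xml.replace(
            f'I.anamnesis.hasChronicLungDisease == "{t.YES["code"]}"',
            "I.a == yes and I.b == no", 1)
        with pytest.raises(UnsupportedConditionError):
            parse_odm(broken)


class TestConvert:
    def test_round_trip_semantic_equivalence(self, questionnaire, study):
        converted = convert_odm(study, reference=questionnaire)
        assert semantically_equal(questionnaire, converted)

    def test_round_trip_without_reference_when_unambiguous(self, questionnaire,
                                                           study):
        converted = convert_odm(study)
        assert semantically_equal(questionnaire, converted)

    def test_alias_carry_over(self, questionnaire, study):
        converted = convert_odm(study, reference=questionnaire)
        expected = {
            item.alias("gecco-path")
            for item in study.items.values()
        }
        converted_paths = {
            item_gecco_path(i) for i in iter_items(converted)
            if i.get("type") != "group" and item_gecco_path(i)
        }
        assert converted_paths == expected

    def test_condition_def_becomes_enable_when(self, questionnaire, study):
        converted = convert_odm(study, reference=questionnaire)
        by_path = {item_gecco_path(i): i for i in iter_items(converted)}
        asthma = by_path["anamnesis.chronicLungDisease.asthma"]
        controlling = by_path["anamnesis.hasChronicLungDisease"]
        (cond,) = asthma["enableWhen"]
        assert cond["question"] == controlling["linkId"]
        assert cond["answerCoding"]["code"] == t.YES["code"]
        assert cond["answerCoding"]["system"] == t.SNOMED

    def test_questionnaire_url_taken_from_form(self, questionnaire, study):
        converted = convert_odm(study, reference=questionnaire)
        assert converted["url"] == questionnaire["url"]

    def test_one_coding_per_answer_option(self, questionnaire, study):
        converted = convert_odm(study, reference=questionnaire)
        for item in iter_items(converted):
            for option in item.get("answerOption", []):
                assert set(option) == {"valueCoding"}


def _inject_second_coding(xml: str) -> str:
    """Add a LOINC answer-list alias next to the SNOMED 'Yes' coding of the
    asthma code list, making that code-list item multi-coded."""
    root = etree.fromstring(xml.encode())
    ns = {"odm": ODM_NS}
    (code_list,) = root.xpath(
        "//odm:CodeList[@OID='CL.I.anamnesis.chronicLungDisease.asthma']",
        namespaces=ns)
    yes_item = code_list.xpath(
        f"odm:CodeListItem[@CodedValue='{t.YES['code']}']", namespaces=ns)[0]
    etree.SubElement(yes_item, f"{{{ODM_NS}}}Alias",
                     Context="http://loinc.org", Name="LA33-6")
    return etree.tostring(root, encoding="unicode")


class TestMultiCodingResolution:
    def test_reference_questionnaire_selects_its_system(self, questionnaire,
                                                        exported_xml):
        multi = parse_odm(_inject_second_coding(exported_xml))
        converted = convert_odm(multi, reference=questionnaire)
        by_path = {item_gecco_path(i): i for i in iter_items(converted)}
        options = by_path["anamnesis.chronicLungDisease.asthma"]["answerOption"]
        yes_option = next(o for o in options
                          if o["valueCoding"]["code"] == t.YES["code"])
        assert yes_option["valueCoding"]["system"] == t.SNOMED

    def test_ambiguous_without_reference(self, exported_xml):
        multi = parse_odm(_inject_second_coding(exported_xml))
        with pytest.raises(AmbiguousCodingError):
            convert_odm(multi)


class TestExport:
    def test_empty_questionnaire_exports_empty_form(self):
        xml = odm_export({"resourceType": "Questionnaire", "url": "urn:q",
                          "title": "empty", "status": "active"})
        parsed = parse_odm(xml)
        assert len(parsed.forms) == 1
        assert parsed.items == {}

    def test_semantic_items_detects_differences(self, questionnaire, study):
        converted = convert_odm(study, reference=questionnaire)
        items = semantic_items(converted)
        items.pop("anamnesis.chronicLungDisease.asthma")
        mutated = dict(semantic_items(questionnaire))
        assert mutated != items
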