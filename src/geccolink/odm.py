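"""CDISC ODM 1.3 bridge: study definitions ↔ annotated FHIR Questionnaires.

Items inside an ODM form carry their logical-model path in an Alias tag
(context ``gecco-path``); the converter turns that into the item-annotation
extension the mapper needs, converts the supported single-equality
ConditionDef grammar into ``enableWhen``, and — because a FHIR answerOption
holds exactly one Coding while an ODM CodeListItem may carry several coding
aliases — resolves multi-coded code-list items against a reference
questionnaire: the system used there is the one exported.

ODM is hierarchy-poor compared to questionnaires (one level of item groups
under a form), so the exporter flattens nested groups and pushes their
visibility conditions down onto the contained items; semantic equivalence
of a round trip is therefore judged with :func:`semantic_items`, which
compares answerable items on path, text, option codings and *effective*
enable conditions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .errors import (
    AmbiguousCodingError,
    OdmReferenceError,
    ParseError,
    UnsupportedConditionError,
)
from .questionnaire import (
    MAX_VALUE_URL,
    MIN_VALUE_URL,
    UNIT_URL,
    annotation_url,
    item_gecco_path,
    iter_items,
)

logger = logging.getLogger(__name__)

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
PATH_CONTEXT = "gecco-path"
UNIT_CONTEXT = "ucum-unit"
URL_CONTEXT = "url"
RANGE_MIN_CONTEXT = "range-min"
RANGE_MAX_CONTEXT = "range-max"
_META_CONTEXTS = {PATH_CONTEXT, UNIT_CONTEXT, URL_CONTEXT,
                  RANGE_MIN_CONTEXT, RANGE_MAX_CONTEXT}
DEFAULT_BASE = "https://example.org/fhir/geccolink"

_CONDITION_RE = re.compile(r'^\s*(\S+)\s*==\s*"?([^"]+?)"?\s*$')

_KNOWN_TAGS = {
    "ODM", "Study", "GlobalVariables", "StudyName", "StudyDescription",
    "ProtocolName", "MetaDataVersion", "Protocol", "StudyEventRef",
    "StudyEventDef", "FormRef", "FormDef", "ItemGroupRef", "ItemGroupDef",
    "ItemRef", "ItemDef", "Question", "TranslatedText", "CodeListRef",
    "CodeList", "CodeListItem", "Decode", "Alias", "ConditionDef",
    "Description", "FormalExpression",
}


# --------------------------------------------------------------------------
# parsed ODM structures


@dataclass
class OdmCodeListItem:
    coded_value: str
    decode: Optional[str] = None
    aliases: list[tuple[str, str]] = field(default_factory=list)

    def coding_aliases(self) -> list[tuple[str, str]]:
        return [(c, n) for c, n in self.aliases if c not in _META_CONTEXTS]


@dataclass
class OdmCodeList:
    oid: str
    name: str
    items: list[OdmCodeListItem] = field(default_factory=list)


@dataclass
class OdmCondition:
    oid: str
    controlling_item_oid: str
    required_coded_value: str


@dataclass
class OdmItem:
    oid: str
    name: str
    datatype: str
    question: Optional[str] = None
    codelist_oid: Optional[str] = None
    aliases: list[tuple[str, str]] = field(default_factory=list)

    def alias(self, context: str) -> Optional[str]:
        for ctx, name in self.aliases:
            if ctx == context:
                return name
        return None


@dataclass
class OdmItemGroup:
    oid: str
    name: str
    aliases: list[tuple[str, str]] = field(default_factory=list)
    item_refs: list[tuple[str, Optional[str]]] = field(default_factory=list)

    def alias(self, context: str) -> Optional[str]:
        for ctx, name in self.aliases:
            if ctx == context:
                return name
        return None


@dataclass
class OdmForm:
    oid: str
    name: str
    url: Optional[str] = None
    group_refs: list[tuple[str, Optional[str]]] = field(default_factory=list)


@dataclass
class OdmStudy:
    oid: str
    forms: list[OdmForm] = field(default_factory=list)
    item_groups: dict[str, OdmItemGroup] = field(default_factory=dict)
    items: dict[str, OdmItem] = field(default_factory=dict)
    code_lists: dict[str, OdmCodeList] = field(default_factory=dict)
    conditions: dict[str, OdmCondition] = field(default_factory=dict)


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _text_of(element, *path_names: str) -> Optional[str]:
    node = element
    for name in path_names:
        node = next((c for c in node if _local(c.tag) == name), None)
        if node is None:
            return None
    return (node.text or "").strip() or None


def _aliases_of(element) -> list[tuple[str, str]]:
    return [
        (c.get("Context", ""), c.get("Name", ""))
        for c in element
        if _local(c.tag) == "Alias"
    ]


# --------------------------------------------------------------------------
# parsing


def parse_odm(document: str | bytes) -> OdmStudy:
    """Parse an ODM study-definition document into an :class:`OdmStudy`.

    Unknown elements are ignored with a logged warning; dangling OID
    references raise :class:`OdmReferenceError`; condition expressions
    outside the supported ``ITEM_OID == "value"`` grammar raise
    :class:`UnsupportedConditionError`.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed ODM XML: {exc}") from exc
    if _local(root.tag) != "ODM":
        raise ParseError(f"root element is {_local(root.tag)!r}, not ODM")

    for element in root.iter():
        if isinstance(element.tag, str) and _local(element.tag) not in _KNOWN_TAGS:
            logger.warning("ignoring unknown ODM element <%s>",
                           _local(element.tag))

    study_el = next((c for c in root if _local(c.tag) == "Study"), None)
    if study_el is None:
        raise ParseError("ODM document contains no Study element")
    study = OdmStudy(oid=study_el.get("OID", "S.1"))

    mdv = next((c for c in study_el if _local(c.tag) == "MetaDataVersion"), None)
    if mdv is None:
        return study

    for el in mdv:
        tag = _local(el.tag)
        if tag == "FormDef":
            form = OdmForm(oid=el.get("OID", ""), name=el.get("Name", ""))
            for ctx, name in _aliases_of(el):
                if ctx == URL_CONTEXT:
                    form.url = name
            form.group_refs = [
                (c.get("ItemGroupOID", ""),
                 c.get("CollectionExceptionConditionOID"))
                for c in el if _local(c.tag) == "ItemGroupRef"
            ]
            study.forms.append(form)
        elif tag == "ItemGroupDef":
            group = OdmItemGroup(oid=el.get("OID", ""), name=el.get("Name", ""),
                                 aliases=_aliases_of(el))
            group.item_refs = [
                (c.get("ItemOID", ""),
                 c.get("CollectionExceptionConditionOID"))
                for c in el if _local(c.tag) == "ItemRef"
            ]
            study.item_groups[group.oid] = group
        elif tag == "ItemDef":
            item = OdmItem(
                oid=el.get("OID", ""), name=el.get("Name", ""),
                datatype=el.get("DataType", "text"),
                question=_text_of(el, "Question", "TranslatedText"),
                aliases=_aliases_of(el),
            )
            ref = next((c for c in el if _local(c.tag) == "CodeListRef"), None)
            if ref is not None:
                item.codelist_oid = ref.get("CodeListOID")
            study.items[item.oid] = item
        elif tag == "CodeList":
            code_list = OdmCodeList(oid=el.get("OID", ""), name=el.get("Name", ""))
            for c in el:
                if _local(c.tag) != "CodeListItem":
                    continue
                code_list.items.append(OdmCodeListItem(
                    coded_value=c.get("CodedValue", ""),
                    decode=_text_of(c, "Decode", "TranslatedText"),
                    aliases=_aliases_of(c),
                ))
            study.code_lists[code_list.oid] = code_list
        elif tag == "ConditionDef":
            expression = _text_of(el, "FormalExpression")
            if expression is None:
                raise UnsupportedConditionError(
                    f"ConditionDef {el.get('OID')!r} has no FormalExpression"
                )
            match = _CONDITION_RE.match(expression)
            if match is None or " and " in expression or " or " in expression:
                raise UnsupportedConditionError(
                    f"unsupported condition expression {expression!r}"
                )
            study.conditions[el.get("OID", "")] = OdmCondition(
                oid=el.get("OID", ""),
                controlling_item_oid=match.group(1),
                required_coded_value=match.group(2),
            )

    _check_references(study)
    return study


def _check_references(study: OdmStudy) -> None:
    for form in study.forms:
        for group_oid, cond_oid in form.group_refs:
            if group_oid not in study.item_groups:
                raise OdmReferenceError(f"dangling ItemGroupOID {group_oid!r}")
            if cond_oid is not None and cond_oid not in study.conditions:
                raise OdmReferenceError(f"dangling ConditionOID {cond_oid!r}")
    for group in study.item_groups.values():
        for item_oid, cond_oid in group.item_refs:
            if item_oid not in study.items:
                raise OdmReferenceError(f"dangling ItemOID {item_oid!r}")
            if cond_oid is not None and cond_oid not in study.conditions:
                raise OdmReferenceError(f"dangling ConditionOID {cond_oid!r}")
    for item in study.items.values():
        if item.codelist_oid is not None and item.codelist_oid not in study.code_lists:
            raise OdmReferenceError(
                f"dangling CodeListOID {item.codelist_oid!r} on {item.oid!r}"
            )
    for condition in study.conditions.values():
        if condition.controlling_item_oid not in study.items:
            raise OdmReferenceError(
                f"condition {condition.oid!r} controls unknown item "
                f"{condition.controlling_item_oid!r}"
            )


# --------------------------------------------------------------------------
# conversion ODM -> Questionnaire


_DATATYPE_TO_ITEMTYPE = {
    "date": "date",
    "datetime": "dateTime",
    "integer": "integer",
    "float": "quantity",
    "string": "string",
    "text": "string",
}


def _reference_index(reference: Optional[dict]) -> dict[str, dict]:
    """gecco-path -> questionnaire item of the reference questionnaire."""
    if reference is None:
        return {}
    return {
        path: item
        for item in iter_items(reference)
        if (path := item_gecco_path(item)) is not None
    }


def _resolve_codelist_item(
    cl_item: OdmCodeListItem,
    item_path: Optional[str],
    ref_index: dict[str, dict],
) -> dict:
    """Pick the single coding of a code-list item, using the reference
    questionnaire's system when several coding aliases exist."""
    codings = cl_item.coding_aliases()
    if not codings:
        raise OdmReferenceError(
            f"code-list item {cl_item.coded_value!r} has no coding alias"
        )
    chosen = None
    if len(codings) == 1:
        chosen = codings[0]
    else:
        ref_item = ref_index.get(item_path or "")
        if ref_item is not None:
            ref_keys = {
                (opt["valueCoding"].get("system"), opt["valueCoding"].get("code"))
                for opt in ref_item.get("answerOption", [])
                if "valueCoding" in opt
            }
            ref_systems = {s for s, _ in ref_keys}
            for system, code in codings:
                if (system, code) in ref_keys:
                    chosen = (system, code)
                    break
            else:
                for system, code in codings:
                    if system in ref_systems:
                        chosen = (system, code)
                        break
        if chosen is None:
            raise AmbiguousCodingError(
                f"code-list item {cl_item.coded_value!r} carries "
                f"{len(codings)} codings and the reference questionnaire "
                f"does not disambiguate them"
            )
    coding = {"system": chosen[0], "code": chosen[1]}
    if cl_item.decode:
        coding["display"] = cl_item.decode
    return coding


def convert_odm(study: OdmStudy, reference: Optional[dict] = None) -> dict:
    """Convert an :class:`OdmStudy` (first form) into an annotated FHIR R4
    Questionnaire compatible with the mapper."""
    ref_index = _reference_index(reference)
    ann_url = annotation_url(DEFAULT_BASE)
    if not study.forms:
        return {"resourceType": "Questionnaire",
                "url": f"urn:odm:{study.oid}", "status": "active"}
    form = study.forms[0]

    # first pass: linkIds for every group and item, in document order
    linkid_of: dict[str, str] = {}
    for g, (group_oid, _) in enumerate(form.group_refs, start=1):
        linkid_of[group_oid] = str(g)
        for i, (item_oid, _) in enumerate(
                study.item_groups[group_oid].item_refs, start=1):
            linkid_of[item_oid] = f"{g}.{i}"

    def enable_when(cond_oid: Optional[str]) -> Optional[list[dict]]:
        if cond_oid is None:
            return None
        condition = study.conditions[cond_oid]
        ctrl = study.items[condition.controlling_item_oid]
        if ctrl.codelist_oid is None:
            raise UnsupportedConditionError(
                f"condition {cond_oid!r} controls non-coded item {ctrl.oid!r}"
            )
        code_list = study.code_lists[ctrl.codelist_oid]
        cl_item = next(
            (c for c in code_list.items
             if c.coded_value == condition.required_coded_value), None)
        if cl_item is None:
            raise OdmReferenceError(
                f"condition {cond_oid!r} requires value "
                f"{condition.required_coded_value!r} absent from code list "
                f"{code_list.oid!r}"
            )
        coding = _resolve_codelist_item(
            cl_item, ctrl.alias(PATH_CONTEXT), ref_index)
        return [{"question": linkid_of[ctrl.oid], "operator": "=",
                 "answerCoding": coding}]

    def convert_item(item_oid: str, cond_oid: Optional[str]) -> dict:
        item = study.items[item_oid]
        entry: dict = {"linkId": linkid_of[item_oid]}
        if item.question:
            entry["text"] = item.question
        path = item.alias(PATH_CONTEXT)
        extensions = []
        if path is not None:
            extensions.append({"url": ann_url, "valueString": path})
        if item.codelist_oid is not None:
            entry["type"] = "choice"
            code_list = study.code_lists[item.codelist_oid]
            entry["answerOption"] = [
                {"valueCoding": _resolve_codelist_item(c, path, ref_index)}
                for c in code_list.items
            ]
        else:
            entry["type"] = _DATATYPE_TO_ITEMTYPE.get(item.datatype, "string")
            if entry["type"] == "quantity":
                unit = item.alias(UNIT_CONTEXT) or "1"
                extensions.append({
                    "url": UNIT_URL,
                    "valueCoding": {"system": "http://unitsofmeasure.org",
                                    "code": unit},
                })
        for context, url in ((RANGE_MIN_CONTEXT, MIN_VALUE_URL),
                             (RANGE_MAX_CONTEXT, MAX_VALUE_URL)):
            bound = item.alias(context)
            if bound is not None:
                if entry["type"] == "integer":
                    extensions.append({"url": url, "valueInteger": int(float(bound))})
                else:
                    extensions.append({"url": url, "valueDecimal": float(bound)})
        if extensions:
            entry["extension"] = extensions
        entry["required"] = False
        conditions = enable_when(cond_oid)
        if conditions:
            entry["enableWhen"] = conditions
        return entry

    items = []
    for group_oid, group_cond in form.group_refs:
        group = study.item_groups[group_oid]
        group_item: dict = {
            "linkId": linkid_of[group_oid],
            "text": group.name,
            "type": "group",
            "required": False,
        }
        group_path = group.alias(PATH_CONTEXT)
        if group_path is not None:
            group_item["extension"] = [
                {"url": ann_url, "valueString": group_path}
            ]
        conditions = enable_when(group_cond)
        if conditions:
            group_item["enableWhen"] = conditions
        group_item["item"] = [
            convert_item(oid, cond) for oid, cond in group.item_refs
        ]
        items.append(group_item)

    doc: dict = {
        "resourceType": "Questionnaire",
        "url": form.url or f"urn:odm:{study.oid}:{form.oid}",
        "name": form.name.replace("-", "_") or form.oid,
        "title": form.name or form.oid,
        "status": "active",
    }
    if items:
        doc["item"] = items
    return doc


# --------------------------------------------------------------------------
# export Questionnaire -> ODM


def odm_export(questionnaire: dict) -> str:
    """Export an annotated questionnaire as an ODM study-definition XML
    string (parseable by :func:`parse_odm`).

    Nested groups are flattened to ODM's single form/item-group hierarchy;
    their visibility conditions are pushed down onto the contained items.
    Items with more than one effective condition are outside the supported
    grammar and raise :class:`UnsupportedConditionError`.
    """
    nsmap = {None: ODM_NS}
    root = etree.Element(f"{{{ODM_NS}}}ODM", nsmap=nsmap,
                         FileOID="geccolink-export", FileType="Snapshot",
                         ODMVersion="1.3.2")
    study_el = etree.SubElement(root, f"{{{ODM_NS}}}Study", OID="S.1")
    gv = etree.SubElement(study_el, f"{{{ODM_NS}}}GlobalVariables")
    name_el = etree.SubElement(gv, f"{{{ODM_NS}}}StudyName")
    name_el.text = questionnaire.get("title") or questionnaire.get("name") or "export"
    mdv = etree.SubElement(study_el, f"{{{ODM_NS}}}MetaDataVersion",
                           OID="MDV.1", Name="export")

    def oid_for(item: dict) -> str:
        return "I." + (item_gecco_path(item) or item["linkId"])

    # collect: top-level groups (or a synthetic one) with flattened leaves
    top_groups: list[tuple[dict | None, list[tuple[dict, list[dict]]]]] = []

    def flatten(items: list[dict], inherited: list[dict],
                out: list[tuple[dict, list[dict]]]) -> None:
        for item in items:
            own = list(item.get("enableWhen", []))
            if item.get("type") == "group":
                flatten(item.get("item", []), inherited + own, out)
            else:
                out.append((item, inherited + own))
                flatten(item.get("item", []), inherited, out)

    loose: list[tuple[dict, list[dict]]] = []
    for item in questionnaire.get("item", []):
        if item.get("type") == "group":
            collected: list[tuple[dict, list[dict]]] = []
            flatten(item.get("item", []), [], collected)
            top_groups.append((item, collected))
        else:
            flatten([item], [], loose)
    if loose:
        top_groups.append((None, loose))

    oid_by_linkid = {
        item["linkId"]: oid_for(item) for item in iter_items(questionnaire)
    }

    form = etree.SubElement(mdv, f"{{{ODM_NS}}}FormDef", OID="F.1",
                            Name=questionnaire.get("title") or "form")
    if questionnaire.get("url"):
        etree.SubElement(form, f"{{{ODM_NS}}}Alias", Context=URL_CONTEXT,
                         Name=questionnaire["url"])

    conditions: dict[str, tuple[str, str]] = {}  # oid -> (ctrl oid, value)

    def condition_oid(owner_oid: str, effective: list[dict]) -> Optional[str]:
        if not effective:
            return None
        if len(effective) > 1:
            raise UnsupportedConditionError(
                f"{owner_oid}: {len(effective)} conditions; only a single "
                f"equality is supported"
            )
        cond = effective[0]
        if cond.get("operator") != "=" or "answerCoding" not in cond:
            raise UnsupportedConditionError(
                f"{owner_oid}: only coded equality conditions are supported"
            )
        oid = "C." + owner_oid
        conditions[oid] = (
            oid_by_linkid[cond["question"]],
            cond["answerCoding"].get("code", ""),
        )
        return oid

    item_defs: list[dict] = []
    seen_defs: set[str] = set()
    for g, (group_item, leaves) in enumerate(top_groups, start=1):
        group_oid = (
            "IG." + (item_gecco_path(group_item) or group_item["linkId"])
            if group_item is not None else "IG.main"
        )
        group_ref = etree.SubElement(form, f"{{{ODM_NS}}}ItemGroupRef",
                                     ItemGroupOID=group_oid,
                                     OrderNumber=str(g))
        if group_item is not None:
            cond = condition_oid(group_oid, list(group_item.get("enableWhen", [])))
            if cond is not None:
                group_ref.set("CollectionExceptionConditionOID", cond)
        group_def = etree.SubElement(
            mdv, f"{{{ODM_NS}}}ItemGroupDef", OID=group_oid,
            Name=(group_item or {}).get("text") or "Items", Repeating="No")
        if group_item is not None and item_gecco_path(group_item):
            etree.SubElement(group_def, f"{{{ODM_NS}}}Alias",
                             Context=PATH_CONTEXT,
                             Name=item_gecco_path(group_item))
        for order, (leaf, effective) in enumerate(leaves, start=1):
            leaf_oid = oid_for(leaf)
            if leaf_oid in seen_defs:
                raise UnsupportedConditionError(
                    f"duplicate item OID {leaf_oid!r} in export"
                )
            seen_defs.add(leaf_oid)
            ref = etree.SubElement(group_def, f"{{{ODM_NS}}}ItemRef",
                                   ItemOID=leaf_oid, OrderNumber=str(order),
                                   Mandatory="No")
            cond = condition_oid(leaf_oid, effective)
            if cond is not None:
                ref.set("CollectionExceptionConditionOID", cond)
            item_defs.append(leaf)

    for leaf in item_defs:
        _write_item_def(mdv, leaf, oid_for(leaf))

    for oid, (ctrl_oid, value) in conditions.items():
        cond_el = etree.SubElement(mdv, f"{{{ODM_NS}}}ConditionDef", OID=oid,
                                   Name=oid)
        expr = etree.SubElement(cond_el, f"{{{ODM_NS}}}FormalExpression",
                                Context="geccolink")
        expr.text = f'{ctrl_oid} == "{value}"'

    return etree.tostring(root, pretty_print=True, encoding="unicode")


_ITEMTYPE_TO_DATATYPE = {
    "date": "date",
    "dateTime": "datetime",
    "integer": "integer",
    "quantity": "float",
    "string": "string",
    "text": "string",
}


def _ext_raw(item: dict, url: str):
    for ext in item.get("extension", []):
        if ext.get("url") == url:
            for key, val in ext.items():
                if key.startswith("value"):
                    return val
    return None


def _write_item_def(mdv, leaf: dict, oid: str) -> None:
    itype = leaf.get("type", "string")
    datatype = "text" if itype == "choice" else _ITEMTYPE_TO_DATATYPE.get(
        itype, "string")
    item_el = etree.SubElement(mdv, f"{{{ODM_NS}}}ItemDef", OID=oid,
                               Name=leaf.get("text") or oid,
                               DataType=datatype)
    if leaf.get("text"):
        q = etree.SubElement(item_el, f"{{{ODM_NS}}}Question")
        tt = etree.SubElement(q, f"{{{ODM_NS}}}TranslatedText")
        tt.set("{http://www.w3.org/XML/1998/namespace}lang", "en")
        tt.text = leaf["text"]
    if itype == "choice":
        etree.SubElement(item_el, f"{{{ODM_NS}}}CodeListRef",
                         CodeListOID="CL." + oid)
    path = item_gecco_path(leaf)
    if path:
        etree.SubElement(item_el, f"{{{ODM_NS}}}Alias", Context=PATH_CONTEXT,
                         Name=path)
    unit = _ext_raw(leaf, UNIT_URL)
    if itype == "quantity" and unit:
        etree.SubElement(item_el, f"{{{ODM_NS}}}Alias", Context=UNIT_CONTEXT,
                         Name=unit.get("code", "1"))
    for url, context in ((MIN_VALUE_URL, RANGE_MIN_CONTEXT),
                         (MAX_VALUE_URL, RANGE_MAX_CONTEXT)):
        bound = _ext_raw(leaf, url)
        if bound is not None:
            etree.SubElement(item_el, f"{{{ODM_NS}}}Alias", Context=context,
                             Name=str(bound))
    if itype == "choice":
        code_list = etree.SubElement(mdv, f"{{{ODM_NS}}}CodeList",
                                     OID="CL." + oid,
                                     Name="CL." + oid, DataType="text")
        for option in leaf.get("answerOption", []):
            coding = option.get("valueCoding", {})
            cl_item = etree.SubElement(code_list,
                                       f"{{{ODM_NS}}}CodeListItem",
                                       CodedValue=coding.get("code", ""))
            decode = etree.SubElement(cl_item, f"{{{ODM_NS}}}Decode")
            tt = etree.SubElement(decode, f"{{{ODM_NS}}}TranslatedText")
            tt.text = coding.get("display") or coding.get("code", "")
            etree.SubElement(cl_item, f"{{{ODM_NS}}}Alias",
                             Context=coding.get("system", ""),
                             Name=coding.get("code", ""))


# --------------------------------------------------------------------------
# semantic comparison


@dataclass(frozen=True)
class SemanticItem:
    path: str
    text: Optional[str]
    options: frozenset
    effective_enable: frozenset  # {(controlling base path, code)}


def semantic_items(questionnaire: dict) -> dict[str, SemanticItem]:
    """Answerable items keyed by path annotation, with effective (inherited
    plus own) enable conditions expressed in path terms."""
    path_by_linkid = {
        item["linkId"]: item_gecco_path(item)
        for item in iter_items(questionnaire)
    }

    result: dict[str, SemanticItem] = {}

    def walk(items: list[dict], inherited: tuple) -> None:
        for item in items:
            own = tuple(
                (path_by_linkid.get(c.get("question")),
                 c.get("answerCoding", {}).get("code"))
                for c in item.get("enableWhen", [])
            )
            effective = inherited + own
            if item.get("type") != "group":
                path = item_gecco_path(item)
                if path is not None:
                    options = frozenset(
                        (o["valueCoding"].get("system"), o["valueCoding"].get("code"))
                        for o in item.get("answerOption", [])
                        if "valueCoding" in o
                    )
                    result[path] = SemanticItem(
                        path=path,
                        text=item.get("text"),
                        options=options,
                        effective_enable=frozenset(effective),
                    )
                walk(item.get("item", []), inherited)
            else:
                walk(item.get("item", []), effective)

    walk(questionnaire.get("item", []), ())
    return result


def semantically_equal(left: dict, right: dict) -> bool:
    """True when two questionnaires agree on paths, question texts, option
    codings and effective enable conditions of all annotated items."""
    return semantic_items(left) == semantic_items(right)
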