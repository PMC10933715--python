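"""Render an annotated FHIR R4 Questionnaire from a logical model.

This is the reference questionnaire of the pipeline: one item per model node
with the hierarchy preserved, composite answer kinds expanded into a choice
item plus a dependent child item, enable rules rendered as ``enableWhen``,
and every item annotated with an extension carrying its logical-model path.
That annotation — not the questionnaire-local ``linkId`` — is what the mapper
uses to identify items, so arbitrary re-arranged questionnaires remain
mappable as long as the annotations survive.

Questionnaire documents are plain JSON-serializable dicts in FHIR R4 shape.
"""

from __future__ import annotations

from typing import Iterator, Optional

from . import terminology as t
from .errors import DanglingRuleError
from .model import (
    AnswerKind,
    COMPOSITE_KINDS,
    LogicalModel,
    LogicalNode,
    YNU_KINDS,
)

#: suffix of the item-annotation extension URL (prefixed by canonical_base)
ANNOTATION_SUFFIX = "/StructureDefinition/compass-gecco-item"
MIN_VALUE_URL = "http://hl7.org/fhir/StructureDefinition/minValue"
MAX_VALUE_URL = "http://hl7.org/fhir/StructureDefinition/maxValue"
UNIT_URL = "http://hl7.org/fhir/StructureDefinition/questionnaire-unit"

_ITEM_TYPE = {
    AnswerKind.YES_NO_UNKNOWN: "choice",
    AnswerKind.YES_NO_UNKNOWN_WITH_DATE: "choice",
    AnswerKind.YES_NO_UNKNOWN_WITH_SEVERITY: "choice",
    AnswerKind.CODED_CHOICE: "choice",
    AnswerKind.DATE: "date",
    AnswerKind.DATETIME: "dateTime",
    AnswerKind.QUANTITY: "quantity",
    AnswerKind.TEXT: "string",
    AnswerKind.INTEGER: "integer",
}


def annotation_url(canonical_base: str) -> str:
    return canonical_base.rstrip("/") + ANNOTATION_SUFFIX


def linkid_scheme(node_position: tuple[int, ...]) -> str:
    """Hierarchical numeric linkId from 1-based tree coordinates.

    ``(1,)`` → ``"1"``; ``(1, 2)`` → ``"1.2"``. Injective by construction.
    """
    if not node_position or any(i < 1 for i in node_position):
        raise ValueError(f"invalid tree coordinates: {node_position!r}")
    return ".".join(str(i) for i in node_position)


def item_gecco_path(item: dict) -> Optional[str]:
    """The logical-model path annotated on a (questionnaire or response)
    item, or None. Composite parts carry ``path#date`` / ``path#severity``."""
    for ext in item.get("extension", []):
        if ext.get("url", "").endswith(ANNOTATION_SUFFIX):
            return ext.get("valueString")
    return None


def split_part(path: str) -> tuple[str, Optional[str]]:
    """Split a path annotation into (base path, composite part or None)."""
    base, _, part = path.partition("#")
    return base, (part or None)


def iter_items(doc: dict) -> Iterator[dict]:
    """All items of a Questionnaire/QuestionnaireResponse, document order."""

    def rec(items: list[dict]) -> Iterator[dict]:
        for item in items:
            yield item
            yield from rec(item.get("item", []))

    yield from rec(doc.get("item", []))


def _option_entry(coding) -> dict:
    return {"valueCoding": coding.as_fhir()}


def _answer_coding_for(node: LogicalNode, token: str) -> dict:
    """Coding a controlling item must be answered with for rule token
    ``token`` (a yes/no/unknown word or a coded-choice primary code)."""
    kind = node.answer.kind
    if kind in YNU_KINDS:
        by_token = {"yes": t.YES, "no": t.NO, "unknown": t.UNKNOWN}
        if token in by_token:
            return dict(by_token[token])
    for opt in node.answer.options:
        if opt.primary.code == token:
            return opt.primary.as_fhir()
    raise DanglingRuleError(
        f"enable rule answer {token!r} is not a valid answer of "
        f"{node.path!r}"
    )


def render_questionnaire(model: LogicalModel) -> dict:
    """Render the model into a schema-valid FHIR R4 Questionnaire dict.

    Deterministic: two renders of the same model are identical. Raises
    :class:`DanglingRuleError` if an enable rule points at an item that does
    not precede its dependent in document order.
    """
    ann_url = annotation_url(model.canonical_base)
    linkid_by_path: dict[str, str] = {}

    def annotate(item: dict, path: str) -> None:
        item.setdefault("extension", []).append(
            {"url": ann_url, "valueString": path}
        )

    def render_node(node: LogicalNode, coords: tuple[int, ...]) -> dict:
        link_id = linkid_scheme(coords)
        linkid_by_path[node.path] = link_id
        item: dict = {"linkId": link_id, "text": node.question}
        annotate(item, node.path)
        if node.enable is not None:
            ctrl_path = node.enable.controlling_path
            if ctrl_path not in linkid_by_path:
                raise DanglingRuleError(
                    f"node {node.path}: enable rule target {ctrl_path!r} "
                    f"does not precede it in document order"
                )
            ctrl_node = model.find(ctrl_path)
            item["enableWhen"] = [
                {
                    "question": linkid_by_path[ctrl_path],
                    "operator": "=",
                    "answerCoding": _answer_coding_for(
                        ctrl_node, node.enable.required_answer
                    ),
                }
            ]
        if node.answer is None:
            item["type"] = "group"
            item["item"] = [
                render_node(child, coords + (i,))
                for i, child in enumerate(node.children, start=1)
            ]
            item["required"] = False
            return item

        kind = node.answer.kind
        item["type"] = _ITEM_TYPE[kind]
        item["required"] = False
        if kind in YNU_KINDS:
            item["answerOption"] = [_option_entry(c) for c in
                                    (_as_codings(t.YES_NO_UNKNOWN))]
        elif kind == AnswerKind.CODED_CHOICE:
            item["answerOption"] = [
                _option_entry(opt.primary) for opt in node.answer.options
            ]
        elif kind == AnswerKind.QUANTITY:
            item["extension"].append(
                {"url": UNIT_URL,
                 "valueCoding": {"system": t.UCUM, "code": node.answer.unit}}
            )
        if kind in (AnswerKind.QUANTITY, AnswerKind.INTEGER):
            if node.answer.minimum is not None:
                item["extension"].append(
                    _range_ext(MIN_VALUE_URL, kind, node.answer.minimum)
                )
            if node.answer.maximum is not None:
                item["extension"].append(
                    _range_ext(MAX_VALUE_URL, kind, node.answer.maximum)
                )
        if kind in COMPOSITE_KINDS:
            item["item"] = [_render_part(node, coords, ann_url, link_id)]
        return item

    items = [
        render_node(root, (i,)) for i, root in enumerate(model.roots, start=1)
    ]
    doc: dict = {
        "resourceType": "Questionnaire",
        "url": model.canonical_base.rstrip("/") + "/Questionnaire/" + model.name,
        "name": model.name.replace("-", "_"),
        "title": model.name,
        "status": "active",
    }
    if items:
        doc["item"] = items
    return doc


def _as_codings(raw: tuple[dict, ...]):
    from .model import Coding

    return tuple(Coding(**c) for c in raw)


def _range_ext(url: str, kind: AnswerKind, value: float) -> dict:
    if kind == AnswerKind.INTEGER:
        return {"url": url, "valueInteger": int(value)}
    return {"url": url, "valueDecimal": value}


def _render_part(node: LogicalNode, coords: tuple[int, ...], ann_url: str,
                 parent_link: str) -> dict:
    """Dependent child item of a composite kind: shown only when the parent
    choice is answered "yes"."""
    kind = node.answer.kind
    if kind == AnswerKind.YES_NO_UNKNOWN_WITH_DATE:
        part, text, itype = "date", "Date", "date"
        extra: dict = {}
    else:
        part, text, itype = "severity", "Severity", "choice"
        extra = {
            "answerOption": [_option_entry(c)
                             for c in _as_codings(t.SEVERITY_SCALE)]
        }
    item = {
        "linkId": linkid_scheme(coords + (1,)),
        "text": text,
        "type": itype,
        "required": False,
        "extension": [
            {"url": ann_url, "valueString": f"{node.path}#{part}"}
        ],
        "enableWhen": [
            {"question": parent_link, "operator": "=",
             "answerCoding": dict(t.YES)}
        ],
        **extra,
    }
    return item
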