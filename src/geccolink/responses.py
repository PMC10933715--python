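"""Seeded random QuestionnaireResponse generation and path annotation.

The generator draws an answer for every enabled item of a questionnaire so
that, over enough draws, every answer option of every item gets exercised —
the same idea the pipeline's validation rests on. Items whose ``enableWhen``
conditions evaluate false against the answers drawn so far are left
unanswered, which is well-defined because rendered questionnaires only ever
reference controlling items earlier in document order.

``annotate_response`` transfers the logical-model path annotations of a
known questionnaire onto a response, enabling the mapper to work with
responses produced by apps that do not copy extensions themselves.
"""

from __future__ import annotations

import copy
import random
from datetime import date, datetime, timedelta, timezone
from typing import Optional

from .errors import InvalidQuestionnaireError, LinkIdMismatchError
from .questionnaire import (
    MAX_VALUE_URL,
    MIN_VALUE_URL,
    UNIT_URL,
    item_gecco_path,
    iter_items,
)

_TEXT_POOL = (
    "fatigue", "headache", "loss of taste", "shortness of breath", "none",
)
DEFAULT_AUTHORED_WINDOW = ("2021-05-01", "2021-06-30")
DEFAULT_DATE_WINDOW = ("2020-03-01", "2021-06-30")


def _check_questionnaire(questionnaire: dict) -> dict[str, dict]:
    if (
        not isinstance(questionnaire, dict)
        or questionnaire.get("resourceType") != "Questionnaire"
    ):
        raise InvalidQuestionnaireError("not a FHIR Questionnaire document")
    index: dict[str, dict] = {}
    for item in iter_items(questionnaire):
        link = item.get("linkId")
        if not link:
            raise InvalidQuestionnaireError("item without linkId")
        if link in index:
            raise InvalidQuestionnaireError(f"duplicate linkId {link!r}")
        index[link] = item
        for cond in item.get("enableWhen", []):
            if cond.get("question") not in index:
                raise InvalidQuestionnaireError(
                    f"item {link!r}: enableWhen references unknown or "
                    f"later linkId {cond.get('question')!r}"
                )
            if cond.get("operator") != "=" or "answerCoding" not in cond:
                raise InvalidQuestionnaireError(
                    f"item {link!r}: unsupported enableWhen condition"
                )
    return index


def _coding_matches(a: dict, b: dict) -> bool:
    return a.get("system") == b.get("system") and a.get("code") == b.get("code")


def _enabled(item: dict, answers: dict[str, list[dict]]) -> bool:
    """All-of evaluation of an item's enableWhen against drawn answers."""
    for cond in item.get("enableWhen", []):
        want = cond["answerCoding"]
        got = answers.get(cond["question"], [])
        if not any(
            "valueCoding" in ans and _coding_matches(ans["valueCoding"], want)
            for ans in got
        ):
            return False
    return True


def _ext_value(item: dict, url: str):
    for ext in item.get("extension", []):
        if ext.get("url") == url:
            for key, val in ext.items():
                if key.startswith("value"):
                    return val
    return None


def _parse_day(token: str) -> date:
    return date.fromisoformat(token)


def _random_date(rng: random.Random, window: tuple[str, str]) -> str:
    lo, hi = _parse_day(window[0]), _parse_day(window[1])
    return (lo + timedelta(days=rng.randint(0, (hi - lo).days))).isoformat()


def _random_datetime(rng: random.Random, window: tuple[str, str]) -> str:
    day = _random_date(rng, window)
    stamp = datetime.fromisoformat(day).replace(
        hour=rng.randint(6, 21), minute=rng.randint(0, 59),
        second=rng.randint(0, 59), tzinfo=timezone.utc,
    )
    return stamp.strftime("%Y-%m-%dT%H:%M:%S+00:00")


def _draw_answer(item: dict, rng: random.Random,
                 date_window: tuple[str, str]) -> Optional[dict]:
    itype = item.get("type")
    if itype == "choice":
        options = item.get("answerOption", [])
        if not options:
            raise InvalidQuestionnaireError(
                f"choice item {item.get('linkId')!r} without answerOption"
            )
        return {"valueCoding": copy.deepcopy(rng.choice(options)["valueCoding"])}
    if itype == "date":
        return {"valueDate": _random_date(rng, date_window)}
    if itype == "dateTime":
        return {"valueDateTime": _random_datetime(rng, date_window)}
    if itype == "quantity":
        lo = _ext_value(item, MIN_VALUE_URL)
        hi = _ext_value(item, MAX_VALUE_URL)
        lo = 0.0 if lo is None else float(lo)
        hi = 100.0 if hi is None else float(hi)
        unit = _ext_value(item, UNIT_URL) or {"code": "1"}
        value = round(rng.uniform(lo, hi), 1)
        return {
            "valueQuantity": {
                "value": value,
                "unit": unit.get("code", "1"),
                "system": unit.get("system", "http://unitsofmeasure.org"),
                "code": unit.get("code", "1"),
            }
        }
    if itype == "integer":
        lo = _ext_value(item, MIN_VALUE_URL)
        hi = _ext_value(item, MAX_VALUE_URL)
        return {"valueInteger": rng.randint(
            0 if lo is None else int(lo), 10 if hi is None else int(hi))}
    if itype == "string":
        return {"valueString": rng.choice(_TEXT_POOL)}
    raise InvalidQuestionnaireError(
        f"unsupported item type {itype!r} on {item.get('linkId')!r}"
    )


def generate_responses(
    questionnaire: dict,
    n_subjects: int,
    per_subject: int,
    seed: int,
    *,
    skip_probability: float = 0.0,
    authored_window: tuple[str, str] = DEFAULT_AUTHORED_WINDOW,
    date_window: tuple[str, str] = DEFAULT_DATE_WINDOW,
    annotate: bool = False,
) -> list[dict]:
    """Generate ``n_subjects × per_subject`` enableWhen-consistent random
    QuestionnaireResponses. Deterministic for a fixed seed.

    Answers are uniform over each item's answer domain; quantities and
    integers are drawn from the ranges declared on the questionnaire items.
    ``skip_probability`` optionally leaves enabled items unanswered to
    simulate skipped non-required questions.
    """
    if n_subjects < 0 or per_subject < 0:
        raise ValueError("counts must be non-negative")
    _check_questionnaire(questionnaire)
    rng = random.Random(seed)
    responses = []
    for s in range(1, n_subjects + 1):
        subject = f"subject-{s:03d}"
        for _ in range(per_subject):
            responses.append(
                _generate_one(questionnaire, subject, rng,
                              skip_probability, authored_window, date_window)
            )
    if annotate:
        responses = [annotate_response(r, questionnaire) for r in responses]
    return responses


def _generate_one(questionnaire, subject, rng, skip_probability,
                  authored_window, date_window) -> dict:
    answers: dict[str, list[dict]] = {}

    def build(items: list[dict]) -> list[dict]:
        out = []
        for q_item in items:
            if not _enabled(q_item, answers):
                continue
            entry: dict = {"linkId": q_item["linkId"]}
            if q_item.get("text"):
                entry["text"] = q_item["text"]
            if q_item.get("type") == "group":
                children = build(q_item.get("item", []))
                if not children:
                    continue
                entry["item"] = children
            else:
                if skip_probability and rng.random() < skip_probability:
                    continue
                answer = _draw_answer(q_item, rng, date_window)
                if answer is None:
                    continue
                answers[q_item["linkId"]] = [answer]
                entry["answer"] = [answer]
                children = build(q_item.get("item", []))
                if children:
                    entry["item"] = children
            out.append(entry)
        return out

    items = build(questionnaire.get("item", []))
    response: dict = {
        "resourceType": "QuestionnaireResponse",
        "questionnaire": questionnaire.get("url"),
        "status": "completed",
        "subject": {"identifier": {"value": subject}},
        "authored": _random_datetime(rng, authored_window),
    }
    if items:
        response["item"] = items
    return response


def annotate_response(response: dict, questionnaire: dict) -> dict:
    """Transfer the path annotations of ``questionnaire`` onto a copy of
    ``response``. Idempotent; answer values are untouched, only extensions
    are added. Raises :class:`LinkIdMismatchError` when the response
    references a linkId the questionnaire does not define (version skew).
    """
    index = _check_questionnaire(questionnaire)
    annotated = copy.deepcopy(response)
    for item in iter_items(annotated):
        link = item.get("linkId")
        q_item = index.get(link)
        if q_item is None:
            raise LinkIdMismatchError(
                f"response references linkId {link!r} absent from the "
                f"questionnaire"
            )
        if item_gecco_path(item) is not None:
            continue
        for ext in q_item.get("extension", []):
            if ext.get("url", "").endswith("/StructureDefinition/compass-gecco-item"):
                item.setdefault("extension", []).append(copy.deepcopy(ext))
                break
    return annotated
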