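"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (plain recursion
over the raw JSON/model structures) without calling the code paths they
check.
"""

from __future__ import annotations


def count_answer_bearing_nodes(node_dicts: list[dict]) -> int:
    """Recursive count of nodes carrying an answer spec in a raw model
    document (list of node mappings)."""
    total = 0
    for node in node_dicts:
        if "answer" in node:
            total += 1
        total += count_answer_bearing_nodes(node.get("children", []))
    return total


def response_answers_by_linkid(response: dict) -> dict[str, list[dict]]:
    answers: dict[str, list[dict]] = {}

    def rec(items):
        for item in items:
            if item.get("answer"):
                answers[item["linkId"]] = item["answer"]
            rec(item.get("item", []))

    rec(response.get("item", []))
    return answers


def enabled_linkids(questionnaire: dict, response: dict) -> set[str]:
    """All linkIds whose item (and every ancestor) has its enableWhen
    satisfied by the response's answers — evaluated from scratch."""
    answers = response_answers_by_linkid(response)

    def satisfied(item: dict) -> bool:
        for cond in item.get("enableWhen", []):
            want = cond.get("answerCoding", {})
            hit = False
            for ans in answers.get(cond.get("question"), []):
                coding = ans.get("valueCoding")
                if coding and coding.get("system") == want.get("system") \
                        and coding.get("code") == want.get("code"):
                    hit = True
            if not hit:
                return False
        return True

    enabled: set[str] = set()

    def rec(items, ancestors_ok: bool):
        for item in items:
            ok = ancestors_ok and satisfied(item)
            if ok:
                enabled.add(item["linkId"])
            rec(item.get("item", []), ok)

    rec(questionnaire.get("item", []), True)
    return enabled


def answered_paths(response: dict) -> set[str]:
    """Base paths (fragment stripped) of main answers in an annotated
    response, read directly from the extensions."""
    paths: set[str] = set()

    def rec(items):
        for item in items:
            if item.get("answer"):
                for ext in item.get("extension", []):
                    if ext.get("url", "").endswith("compass-gecco-item"):
                        value = ext.get("valueString", "")
                        if "#" not in value:
                            paths.add(value)
            rec(item.get("item", []))

    rec(response.get("item", []))
    return paths


def expected_bundle_size(response: dict, model) -> int:
    """1 (Patient) + answered template-bearing leaves after meta expansion.

    Leaves whose template targets the Patient resource merge into the
    Patient and add no entry. A meta category answered no/unknown replaces
    its children's individual resources with one defaulted Condition per
    child.
    """
    from geccolink import terminology as t

    paths = answered_paths(response)
    tokens: dict[str, str] = {}

    def rec(items):
        for item in items:
            if item.get("answer"):
                coding = item["answer"][0].get("valueCoding") or {}
                token = t.YNU_TOKENS.get(coding.get("code"))
                for ext in item.get("extension", []):
                    if ext.get("url", "").endswith("compass-gecco-item") \
                            and token:
                        tokens[ext["valueString"]] = token
            rec(item.get("item", []))

    rec(response.get("item", []))

    count = 0
    suppressed: set[str] = set()
    for node in model.walk():
        if node.is_meta and node.enable is not None:
            token = tokens.get(node.enable.controlling_path)
            if token in ("no", "unknown"):
                count += len(node.children)
                suppressed.update(c.path for c in node.children)
    for node in model.walk():
        if not node.is_leaf or node.path in suppressed:
            continue
        if node.path not in paths or node.target_template is None:
            continue
        if model.templates[node.target_template].resource_type != "Patient":
            count += 1
    return 1 + count
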