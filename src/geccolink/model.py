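"""The hierarchical logical model driving the whole pipeline.

The logical model is a terminology-annotated tree of clinical concepts — the
data-set definition from which the reference questionnaire is rendered and to
which annotated responses are bound during mapping. Each answer-bearing node
carries a textual question, an answer specification (its data type and answer
domain), the concept codings (SNOMED CT / LOINC / ICD-10-GM / ATC / custom)
of the clinical concept, and the id of the profile template that turns its
answer into a FHIR resource.

Models are externalized as declarative YAML/JSON documents (schema in
``docs/model-schema.md``); a bundled "mini-GECCO" fixture covering every
structural pattern ships with the package and is returned by
:func:`mini_gecco`.
"""

from __future__ import annotations

import enum
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterator, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, PrivateAttr, model_validator

from .errors import (
    CycleError,
    DanglingRuleError,
    DuplicatePathError,
    ModelConsistencyError,
    ModelError,
    UnknownTemplateError,
)
from .terminology import resolve_system

#: the seven resource types a profile template may target
MAPPED_RESOURCE_TYPES = frozenset(
    {"Patient", "Consent", "Observation", "Condition",
     "Procedure", "MedicationStatement", "Immunization"}
)


class Coding(BaseModel):
    """A single code from a terminology system."""

    model_config = ConfigDict(frozen=True)

    system: str
    code: str
    display: Optional[str] = None

    @model_validator(mode="after")
    def _non_empty(self) -> "Coding":
        if not self.system or not self.code:
            raise ValueError("Coding.system and Coding.code must be non-empty")
        return self

    def key(self) -> tuple[str, str]:
        return (self.system, self.code)

    def as_fhir(self) -> dict:
        d = {"system": self.system, "code": self.code}
        if self.display:
            d["display"] = self.display
        return d


class AnswerKind(str, enum.Enum):
    YES_NO_UNKNOWN = "yes_no_unknown"
    YES_NO_UNKNOWN_WITH_DATE = "yes_no_unknown_with_date"
    YES_NO_UNKNOWN_WITH_SEVERITY = "yes_no_unknown_with_severity"
    CODED_CHOICE = "coded_choice"
    DATE = "date"
    DATETIME = "datetime"
    QUANTITY = "quantity"
    TEXT = "text"
    INTEGER = "integer"


#: kinds that expand to a yes/no/unknown choice plus a dependent child item
COMPOSITE_KINDS = frozenset(
    {AnswerKind.YES_NO_UNKNOWN_WITH_DATE, AnswerKind.YES_NO_UNKNOWN_WITH_SEVERITY}
)
YNU_KINDS = COMPOSITE_KINDS | {AnswerKind.YES_NO_UNKNOWN}


class AnswerOption(BaseModel):
    """One selectable answer: exactly one primary coding (the one emitted
    into the questionnaire's answerOption) plus optional additional codings
    the mapper emits alongside it into the target resource."""

    model_config = ConfigDict(frozen=True)

    primary: Coding
    additional: tuple[Coding, ...] = ()

    def all_codings(self) -> tuple[Coding, ...]:
        return (self.primary, *self.additional)


class AnswerSpec(BaseModel):
    """Data type and answer domain of a question."""

    model_config = ConfigDict(frozen=True)

    kind: AnswerKind
    options: tuple[AnswerOption, ...] = ()
    unit: Optional[str] = None
    # simulation range for quantity/integer answers (inclusive); design
    # choice exposed here so the generator and the documentation agree
    minimum: Optional[float] = None
    maximum: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "AnswerSpec":
        if (self.kind == AnswerKind.CODED_CHOICE) != bool(self.options):
            raise ValueError("options must be non-empty iff kind is coded_choice")
        if (self.kind == AnswerKind.QUANTITY) != (self.unit is not None):
            raise ValueError("unit must be present iff kind is quantity")
        keys = [c.key() for opt in self.options for c in opt.all_codings()]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (system, code) pair in answer options")
        return self


class EnableRule(BaseModel):
    """Visibility condition: node is enabled when the controlling question is
    answered with the given code token (string equality on the primary
    coding's code, e.g. ``= yes``)."""

    model_config = ConfigDict(frozen=True)

    controlling_path: str
    required_answer: str


class ProfileTemplate(BaseModel):
    """A template function for one GECCO profile: fixed elements plus a
    binding rule describing how the answer populates the resource."""

    model_config = ConfigDict(frozen=True)

    template_id: str
    resource_type: str
    fixed_elements: dict = {}
    answer_binding: dict = {}

    @model_validator(mode="after")
    def _check(self) -> "ProfileTemplate":
        if self.resource_type not in MAPPED_RESOURCE_TYPES:
            raise ValueError(
                f"resource_type {self.resource_type!r} is not one of the "
                f"seven mapped types"
            )
        return self


class LogicalNode(BaseModel):
    """One element of the logical model.

    Leaves carry an :class:`AnswerSpec`; groups only structure. Meta nodes
    are category groups whose children are condition-mapped leaves: a
    negative/unknown answer to the category's controlling question defaults
    every child instead of asking each one.
    """

    path: str
    question: str
    answer: Optional[AnswerSpec] = None
    concept_codings: tuple[Coding, ...] = ()
    target_template: Optional[str] = None
    enable: Optional[EnableRule] = None
    is_meta: bool = False
    children: tuple["LogicalNode", ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "LogicalNode":
        if self.answer is None and not self.children:
            raise ValueError(f"node {self.path}: group without children")
        if self.answer is not None and self.children:
            raise ValueError(f"node {self.path}: node has both answer and children")
        if self.is_meta and (not self.children or self.target_template):
            raise ValueError(
                f"node {self.path}: meta node must have children and no template"
            )
        if self.target_template and not self.concept_codings:
            raise ValueError(
                f"node {self.path}: template-bearing node needs concept codings"
            )
        return self

    @property
    def is_leaf(self) -> bool:
        return self.answer is not None


class LogicalModel(BaseModel):
    """A validated logical model: node tree plus template registry."""

    name: str
    canonical_base: str = "https://example.org/fhir/geccolink"
    roots: tuple[LogicalNode, ...] = ()
    templates: dict[str, ProfileTemplate] = {}

    _index: dict[str, LogicalNode] = PrivateAttr(default_factory=dict)

    @model_validator(mode="after")
    def _validate_model(self) -> "LogicalModel":
        index: dict[str, LogicalNode] = {}
        for node in self.walk():
            if node.path in index:
                raise DuplicatePathError(f"duplicate path {node.path!r}")
            index[node.path] = node
        for node in index.values():
            if node.target_template is not None:
                if node.target_template not in self.templates:
                    raise UnknownTemplateError(
                        f"node {node.path}: unknown template {node.target_template!r}"
                    )
            if node.enable is not None:
                ctrl = index.get(node.enable.controlling_path)
                if ctrl is None:
                    raise DanglingRuleError(
                        f"node {node.path}: enable rule targets nonexistent "
                        f"path {node.enable.controlling_path!r}"
                    )
                if ctrl.answer is None:
                    raise DanglingRuleError(
                        f"node {node.path}: enable rule targets group "
                        f"{ctrl.path!r}, which has no answer"
                    )
        self._check_cycles(index)
        self._index = index
        return self

    def _check_cycles(self, index: dict[str, LogicalNode]) -> None:
        # edge: node -> controlling node (including rules inherited from
        # ancestors, since a child is only shown when its ancestors are)
        parents: dict[str, Optional[str]] = {}

        def fill(node: LogicalNode, parent: Optional[str]) -> None:
            parents[node.path] = parent
            for child in node.children:
                fill(child, node.path)

        for root in self.roots:
            fill(root, None)

        def controllers(path: str) -> Iterator[str]:
            cur: Optional[str] = path
            while cur is not None:
                rule = index[cur].enable
                if rule is not None:
                    yield rule.controlling_path
                cur = parents[cur]

        WHITE, GREY, BLACK = 0, 1, 2
        state = {p: WHITE for p in index}

        def visit(path: str, trail: tuple[str, ...]) -> None:
            if state[path] == GREY:
                raise CycleError(f"enable-rule cycle through {path!r}: {trail}")
            if state[path] == BLACK:
                return
            state[path] = GREY
            for ctrl in controllers(path):
                visit(ctrl, trail + (path,))
            state[path] = BLACK

        for p in index:
            visit(p, ())

    # -- queries --------------------------------------------------------

    def walk(self) -> Iterator[LogicalNode]:
        """All nodes in depth-first document order."""

        def rec(node: LogicalNode) -> Iterator[LogicalNode]:
            yield node
            for child in node.children:
                yield from rec(child)

        for root in self.roots:
            yield from rec(root)

    def find(self, path: str) -> Optional[LogicalNode]:
        return self._index.get(path)

    def registered_systems(self) -> set[str]:
        """All terminology-system URIs occurring anywhere in the model."""
        systems: set[str] = set()
        for node in self.walk():
            for coding in node.concept_codings:
                systems.add(coding.system)
            if node.answer:
                for opt in node.answer.options:
                    for coding in opt.all_codings():
                        systems.add(coding.system)
        from . import terminology as t
        systems |= {t.SNOMED, t.LOINC, t.ICD10GM, t.ATC, t.UCUM,
                    t.GENDER_AMTLICH_DE}
        return systems


def walk_leaves(model: LogicalModel) -> list[LogicalNode]:
    """Answer-bearing nodes in depth-first document order (deterministic)."""
    return [n for n in model.walk() if n.is_leaf]


# --------------------------------------------------------------------------
# loading from declarative documents


def _parse_coding(obj: dict) -> Coding:
    return Coding(
        system=resolve_system(str(obj["system"])),
        code=str(obj["code"]),
        display=obj.get("display"),
    )


def _parse_option(obj: dict) -> AnswerOption:
    codings = [_parse_coding(c) for c in obj.get("codings", [])]
    if not codings:
        raise ModelError(f"answer option without codings: {obj!r}")
    return AnswerOption(primary=codings[0], additional=tuple(codings[1:]))


def _parse_answer(obj: dict) -> AnswerSpec:
    return AnswerSpec(
        kind=AnswerKind(obj["kind"]),
        options=tuple(_parse_option(o) for o in obj.get("options", [])),
        unit=obj.get("unit"),
        minimum=obj.get("minimum"),
        maximum=obj.get("maximum"),
    )


def _parse_node(obj: dict) -> LogicalNode:
    enable = None
    if "enable" in obj:
        enable = EnableRule(
            controlling_path=obj["enable"]["when"],
            required_answer=str(obj["enable"]["equals"]),
        )
    try:
        return LogicalNode(
            path=obj["path"],
            question=obj["question"],
            answer=_parse_answer(obj["answer"]) if "answer" in obj else None,
            concept_codings=tuple(
                _parse_coding(c) for c in obj.get("codings", [])
            ),
            target_template=obj.get("template"),
            enable=enable,
            is_meta=bool(obj.get("meta", False)),
            children=tuple(_parse_node(c) for c in obj.get("children", [])),
        )
    except (ModelError, ValueError) as exc:
        if isinstance(exc, ModelError):
            raise
        raise ModelError(str(exc)) from exc


def load_model(source: Union[str, Path, dict]) -> LogicalModel:
    """Load and validate a logical model from a YAML/JSON document.

    ``source`` may be a file path or an already-parsed mapping. Raises
    :class:`DuplicatePathError`, :class:`DanglingRuleError`,
    :class:`UnknownTemplateError` or :class:`CycleError` on invariant
    violations and :class:`ModelError` on any other defect.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    if not isinstance(doc, dict):
        raise ModelError("model document must be a mapping")
    try:
        templates = {
            tid: ProfileTemplate(
                template_id=tid,
                resource_type=t["resource_type"],
                fixed_elements=t.get("fixed", {}),
                answer_binding=t.get("binding", {}),
            )
            for tid, t in (doc.get("templates") or {}).items()
        }
        return LogicalModel(
            name=doc.get("name", "unnamed"),
            canonical_base=doc.get(
                "canonical_base", "https://example.org/fhir/geccolink"
            ),
            roots=tuple(_parse_node(n) for n in (doc.get("nodes") or [])),
            templates=templates,
        )
    except ModelError:
        raise
    except KeyError as exc:
        raise ModelError(f"missing required key: {exc}") from exc
    except ValueError as exc:
        raise ModelError(str(exc)) from exc


def mini_gecco() -> LogicalModel:
    """The bundled mini-GECCO fixture: a representative subset of the
    COVID-19 core data set exercising every answer kind, the meta-element
    mechanism and all seven mapped resource types."""
    ref = _ilres.files("geccolink").joinpath("data/mini_gecco.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_model(yaml.safe_load(fh))
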