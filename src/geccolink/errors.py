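"""Exception hierarchy.

Every error raised by this package derives from :class:`GeccoLinkError` so
callers (and the CLI) can catch pipeline failures uniformly.
"""


class GeccoLinkError(Exception):
    """Base class for all package errors."""


# --- logical model -----------------------------------------------------------

class ModelError(GeccoLinkError):
    """Invalid logical-model definition."""


class DuplicatePathError(ModelError):
    """Two nodes share the same logical-model path."""


class DanglingRuleError(ModelError):
    """An enable rule points at a path that does not exist."""


class UnknownTemplateError(ModelError):
    """A node references a template id absent from the registry."""


class CycleError(ModelError):
    """Enable rules form a dependency cycle."""


class ModelConsistencyError(ModelError):
    """A structural invariant of the model is violated (e.g. a meta category
    whose children are not condition-mapped)."""


# --- questionnaire / responses ----------------------------------------------

class InvalidQuestionnaireError(GeccoLinkError):
    """Questionnaire document is structurally unusable."""


class LinkIdMismatchError(GeccoLinkError):
    """A response answers a linkId that the questionnaire does not define
    (typically version skew between response and questionnaire)."""


# --- mapping -----------------------------------------------------------------

class MappingError(GeccoLinkError):
    """Base class for response-to-resource mapping failures."""


class UnmappedItemError(MappingError):
    """An answered item carries no logical-model path annotation."""


class PathKindError(MappingError):
    """An answer's path annotation resolves to a group, not a question."""


class ValueDomainError(MappingError):
    """An answer value is outside the node's declared answer domain."""


class DuplicateAnswerError(MappingError):
    """The same logical-model path is answered more than once; model elements
    may appear only once per questionnaire."""


class UnknownResourceTypeError(MappingError):
    """Resource type is not one of the seven mapped GECCO types."""


class TemplateBindingError(MappingError):
    """A template could not bind the given answer onto its resource."""


# --- conformance -------------------------------------------------------------

class ParseError(GeccoLinkError):
    """Input document (bundle JSON or ODM XML) could not be parsed."""


# --- ODM bridge --------------------------------------------------------------

class OdmReferenceError(GeccoLinkError):
    """An ODM OID reference (code list, condition, item) does not resolve."""


class AmbiguousCodingError(GeccoLinkError):
    """A code-list item carries several codings and no reference
    questionnaire was provided to pick the system."""


class UnsupportedConditionError(GeccoLinkError):
    """A condition expression falls outside the supported single-equality
    grammar."""
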