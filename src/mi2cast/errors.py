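"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`Mi2castError`,
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class Mi2castError(Exception):
    """Base class for all package errors."""


# --- vocabulary layer ---------------------------------------------------


class VocabError(Mi2castError):
    pass


class DuplicateNamespaceError(VocabError):
    pass


class NormalizationError(VocabError):
    pass


class UnknownRoleError(VocabError):
    pass


class ResolutionError(VocabError):
    pass


# --- VSM sentence / template layer --------------------------------------


class VsmError(Mi2castError):
    pass


class FillError(VsmError):
    pass


class UnknownFieldError(VsmError):
    pass


class StructureError(VsmError):
    """A sentence's connector graph cannot be interpreted as a causal statement."""


class VsmJsonError(VsmError):
    pass


class IncompleteSentenceError(VsmError):
    pass


class TemplateError(VsmError):
    pass


class IncompatibleAnchorError(TemplateError):
    pass


class MandatoryFieldError(TemplateError):
    pass


class SelectionError(TemplateError):
    pass


# --- statement model / serialization ------------------------------------


class InvalidStatementError(Mi2castError):
    pass


class CausalJsonError(Mi2castError):
    """Raised with a JSON-path-like locator in the message."""


class ExportError(Mi2castError):
    pass


class MitabError(Mi2castError):
    pass


class MitabParseError(MitabError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
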