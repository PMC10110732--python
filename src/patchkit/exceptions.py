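"""Exception hierarchy shared across the package."""


class PatchkitError(Exception):
    """Base class for all package errors."""


class FormatError(PatchkitError):
    """A file could not be parsed as the expected on-disk format."""


class ConsistencyError(PatchkitError):
    """Sidecar metadata and trace data disagree."""


class InputError(PatchkitError):
    """An operation received a sweep that violates its preconditions."""


class ParameterError(PatchkitError):
    """A simulation or analysis parameter is out of its valid range."""


class EstimationError(PatchkitError):
    """A fit failed to converge; carries diagnostic context."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DesignError(PatchkitError):
    """A statistical design is incomplete (e.g. an empty group cell)."""
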