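"""Exception hierarchy shared across the pipeline."""


class FirePMError(Exception):
    """Base class for all package errors."""


class ParseError(FirePMError):
    """A detection table could not be parsed (e.g. missing column)."""


class ArgumentError(FirePMError, ValueError):
    """An operation received an out-of-range argument."""


class GeometryError(FirePMError):
    """Invalid or unusable geometry."""


class ValidationError(FirePMError):
    """A data table violated its invariants on load."""
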