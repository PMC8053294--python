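"""Exception hierarchy.

``FormatError`` signals malformed input files (wrong columns, bad lines);
``ValidationError`` signals values that parse but violate a domain
invariant (p-value of zero, duplicate identifiers, inconsistent counts).
"""


class DiafluxError(Exception):
    """Base class for all package errors."""


class FormatError(DiafluxError):
    """An input file does not conform to its declared format."""


class ValidationError(DiafluxError):
    """A value violates a domain invariant."""


class PipelineError(DiafluxError):
    """A pipeline stage failed; the message is tagged with the stage name."""
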