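"""Exception hierarchy used across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``ContractError`` (a stage
precondition violated at run time) to exit code 3.
"""


class RejuvseqError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RejuvseqError):
    """A file does not conform to its declared format."""


class DimensionError(FormatError):
    """Matrix header and sidecar identifier lists disagree."""


class ConfigError(RejuvseqError):
    """Invalid user-supplied configuration."""


class ContractError(RejuvseqError):
    """A stage precondition was violated (e.g. an empty contrast group)."""
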