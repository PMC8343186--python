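"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, InputFormatError -> 3,
any other StageError/QuadhetError -> 4.
"""


class QuadhetError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(QuadhetError):
    """Invalid configuration or parameter combination."""


class InputFormatError(QuadhetError):
    """Malformed or inconsistent input file."""


class StageError(QuadhetError):
    """A pipeline stage failed on otherwise well-formed inputs."""


class PedigreeStructureError(InputFormatError):
    """A pedigree references members that are not present."""


class PedigreeAmbiguityError(InputFormatError):
    """Parental roles cannot be resolved uniquely."""
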