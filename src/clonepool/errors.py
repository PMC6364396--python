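"""Exception hierarchy used across the pipeline.

``ValidationError`` covers malformed configuration or arguments (CLI exit
code 2), ``DataError`` covers structurally valid inputs whose content cannot
be processed (CLI exit code 3).
"""


class ClonePoolError(Exception):
    """Base class for all clonepool errors."""


class ValidationError(ClonePoolError):
    """Invalid configuration, parameters, or file references."""


class DataError(ClonePoolError):
    """Input data that cannot be processed (empty samples, missing columns...)."""
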