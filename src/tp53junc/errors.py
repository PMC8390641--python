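"""Exception hierarchy.

Exit codes used by the CLI: 1 internal, 2 configuration, 3 input data.
"""


class Tp53JuncError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(Tp53JuncError):
    """Bad configuration: missing paths, inconsistent parameters, absent catalog roles."""

    exit_code = 2


class InputDataError(Tp53JuncError):
    """Malformed or inconsistent input data (gene model, alignments, annotation tables)."""

    exit_code = 3


class ModelValidationError(InputDataError):
    """A gene model violates a structural invariant (exon order, transcript roles...)."""
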