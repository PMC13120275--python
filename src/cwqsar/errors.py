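"""Exception hierarchy shared across the package.

Exit codes used by the CLI: 2 = malformed input, 3 = bad configuration,
4 = numerically degenerate problem.
"""


class CwqsarError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(CwqsarError):
    """Malformed input data (files, rows, SMILES strings)."""

    exit_code = 2


class FormatError(InputError):
    """A file does not follow the expected layout."""


class TokenizationError(InputError):
    """A SMILES string could not be decomposed into attributes."""


class ConfigurationError(CwqsarError):
    """Inconsistent or unsatisfiable run configuration."""

    exit_code = 3


class DegenerateError(CwqsarError):
    """A quantity is undefined on the given data (e.g. zero variance)."""

    exit_code = 4
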