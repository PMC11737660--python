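"""Typed exceptions shared across the package.

Exit-code mapping used by the CLI: 0 success, 2 insufficient evidence,
3 configuration error, 4 I/O error.
"""


class SitrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SitrError):
    """An option, tokenizer name, or config value is invalid."""

    exit_code = 3


class InsufficientEvidenceError(SitrError):
    """Too few codebook matches to make a reliable inference.

    Mirrors the behaviour of dropping inputs whose token matches fall
    below ``min_matches``; carries the number of distinct matches found.
    """

    exit_code = 2

    def __init__(self, n_matches: int, min_matches: int):
        self.n_matches = n_matches
        self.min_matches = min_matches
        super().__init__(
            f"only {n_matches} distinct matched token(s); "
            f"at least {min_matches} required for a reliable inference"
        )


class CodebookIOError(SitrError):
    """A codebook file is missing, malformed, or schema-incompatible."""

    exit_code = 4


class DegenerateDataError(SitrError):
    """A statistic is undefined on the given data (zero variance etc.)."""

    exit_code = 3


class InvalidSpecError(SitrError):
    """A generator spec fails validation."""

    exit_code = 3
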