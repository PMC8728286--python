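"""Typed exceptions shared across the package."""


class MatchvarError(Exception):
    """Base class for all package errors."""


class DataError(MatchvarError):
    """Malformed or inconsistent user data (bad FASTA, ragged alignment, ...)."""


class HgvsError(DataError):
    """A string is not a parsable protein-substitution notation."""


class UnsupportedKindError(HgvsError):
    """The notation is valid HGVS but not a simple substitution (fs/del/dup/ins)."""
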