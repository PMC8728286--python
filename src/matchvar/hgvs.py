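"""Protein-level HGVS substitution notation (``p.P375S``, ``p.Trp572*``).

Only simple substitutions are modelled: missense (one amino acid replaced by
another) and nonsense (replacement by a stop, written ``*`` or ``Ter``).
Frameshifts, deletions, duplications, insertions and synonymous changes are
rejected with :class:`~matchvar.errors.UnsupportedKindError` /
:class:`~matchvar.errors.HgvsError` rather than silently coerced — a variant
whose kind we cannot compare across species must not enter matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from .errors import HgvsError, UnsupportedKindError

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# one-letter or three-letter residue token
_RES = r"(?:\*|Ter|[A-Z][a-z]{2}|[A-Z])"
_SUB_RE = re.compile(rf"^(?P<ref>{_RES})(?P<pos>\d+)(?P<alt>{_RES}|=)$")
_UNSUPPORTED_RE = re.compile(
    r"(fs|del|dup|ins|ext|\?|_)", re.IGNORECASE
)


@dataclass(frozen=True, order=True)
class ProteinChange:
    """A single amino-acid substitution in 1-based protein coordinates."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in AA1:
            raise HgvsError(f"unknown reference residue {self.ref_aa!r}")
        if self.alt_aa not in AA1 and self.alt_aa != "*":
            raise HgvsError(f"unknown alternate residue {self.alt_aa!r}")
        if self.position < 1:
            raise HgvsError(f"position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise HgvsError(
                f"synonymous change p.{self.ref_aa}{self.position}{self.alt_aa} rejected"
            )

    @property
    def is_nonsense(self) -> bool:
        return self.alt_aa == "*"


def _residue_to_one(token: str) -> str:
    if token == "*":
        return "*"
    if len(token) == 1:
        return token
    try:
        return AA3_TO_1[token]
    except KeyError:
        raise HgvsError(f"unknown residue code {token!r}") from None


def parse(text: str) -> ProteinChange:
    """Parse ``p.P375S`` / ``p.Pro375Ser`` / ``p.(P375S)`` to a :class:`ProteinChange`.

    Raises
    ------
    UnsupportedKindError
        For valid-looking HGVS that is not a substitution (``p.G12fs``,
        ``p.M1del`` ...).
    HgvsError
        For anything else unparsable, synonymous changes (``p.=`` or
        ref == alt), unknown residue codes, or a reference stop codon.
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsError("empty HGVS string")
    body = text.strip()
    if body.startswith("p."):
        body = body[2:]
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    if body == "=":
        raise HgvsError("synonymous change 'p.=' rejected")
    if _UNSUPPORTED_RE.search(body):
        raise UnsupportedKindError(f"{text!r} is not a simple substitution")
    m = _SUB_RE.match(body)
    if m is None:
        raise HgvsError(f"cannot parse {text!r} as a protein substitution")
    ref = _residue_to_one(m.group("ref"))
    alt_tok = m.group("alt")
    if alt_tok == "=":
        raise HgvsError(f"synonymous change {text!r} rejected")
    alt = _residue_to_one(alt_tok)
    if ref == "*":
        raise HgvsError(f"reference residue cannot be a stop codon: {text!r}")
    # mixed one-/three-letter styles ("p.Pro375S") are technically malformed
    # HGVS but unambiguous; accept them.
    return ProteinChange(ref_aa=ref, position=int(m.group("pos")), alt_aa=alt)


def format(change: ProteinChange, style: Literal["one", "three"] = "one") -> str:
    """Render a change as HGVS text; inverse of :func:`parse` for style='one'."""
    if style == "one":
        return f"p.{change.ref_aa}{change.position}{change.alt_aa}"
    if style == "three":
        return (
            f"p.{AA1_TO_3[change.ref_aa]}{change.position}{AA1_TO_3[change.alt_aa]}"
        )
    raise ValueError(f"unknown style {style!r}")


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of checking a change against an actual sequence."""

    valid: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.valid


def validate_against(change: ProteinChange, sequence: str) -> ValidationVerdict:
    """Check that ``sequence`` carries ``change.ref_aa`` at ``change.position`` (1-based)."""
    if change.position > len(sequence):
        return ValidationVerdict(
            False,
            f"position {change.position} out of range for length {len(sequence)}",
        )
    found = sequence[change.position - 1]
    if found != change.ref_aa:
        return ValidationVerdict(
            False,
            f"reference mismatch at {change.position}: "
            f"sequence has {found}, variant says {change.ref_aa}",
        )
    return ValidationVerdict(True)
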