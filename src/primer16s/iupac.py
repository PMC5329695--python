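"""IUPAC nucleotide algebra used throughout the package.

Degenerate PCR primers are written with IUPAC ambiguity codes; a primer
base *matches* a template base when the two codes share at least one
concrete nucleotide.  The internal alphabet is DNA (T, never U); display
layers may render U for rRNA contexts.
"""

from __future__ import annotations

__all__ = [
    "IUPAC_CODES",
    "expand",
    "complement",
    "revcomp",
    "iupac_match",
    "is_valid",
    "normalize",
]

# code -> set of concrete bases
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

GAP = "-"


class InvalidNucleotideError(ValueError):
    """Raised when a character is not a valid IUPAC DNA code."""


def is_valid(seq: str) -> bool:
    """True if every character of ``seq`` is an IUPAC DNA code."""
    return all(c in IUPAC_CODES for c in seq.upper())


def normalize(seq: str) -> str:
    """Upper-case and map U->T; validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in IUPAC_CODES:
            raise InvalidNucleotideError(
                f"invalid nucleotide {c!r} at position {i + 1}"
            )
    return s


def expand(code: str) -> frozenset[str]:
    """The set of concrete bases an IUPAC code stands for."""
    try:
        return IUPAC_CODES[code.upper()]
    except KeyError:
        raise InvalidNucleotideError(f"invalid IUPAC code {code!r}") from None


def complement(code: str) -> str:
    c = code.upper()
    if c not in _COMPLEMENT:
        raise InvalidNucleotideError(f"invalid IUPAC code {code!r}")
    return _COMPLEMENT[c]


def revcomp(seq: str) -> str:
    """Reverse complement under IUPAC complement rules (R<->Y, K<->M, ...)."""
    return "".join(complement(c) for c in reversed(seq.upper()))


def iupac_match(primer_base: str, template_base: str) -> bool:
    """Match iff the expansions of the two codes intersect.

    A gap on the template side is always a mismatch (a primer cannot
    anneal over a missing base).
    """
    if template_base == GAP:
        return False
    return bool(expand(primer_base) & expand(template_base))
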