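"""IUPAC nucleotide alphabet utilities.

Single source of truth for ambiguity-code semantics used by the primer
search, the restriction-site scan and sequence validation.
"""

from __future__ import annotations

# code -> set of unambiguous bases it denotes
IUPAC_SETS: dict[str, frozenset[str]] = {
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

GAP = "-"
IUPAC_CODES = frozenset(IUPAC_SETS)
VALID_CHARS = IUPAC_CODES | {GAP}
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codes_intersect(a: str, b: str) -> bool:
    """True if the base sets denoted by two IUPAC codes overlap.

    This is the 'an ambiguity code matches any base it denotes' rule used
    for primer matching.
    """
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


def code_subset(a: str, b: str) -> bool:
    """True if every base denoted by ``a`` is also denoted by ``b``."""
    return IUPAC_SETS[a] <= IUPAC_SETS[b]


def is_valid_sequence(seq: str) -> bool:
    return bool(seq) and all(c in VALID_CHARS for c in seq.upper())


def first_invalid(seq: str) -> tuple[int, str] | None:
    """Return (0-based position, character) of the first illegal character."""
    for i, c in enumerate(seq.upper()):
        if c not in VALID_CHARS:
            return i, seq[i]
    return None
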