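"""IUPAC nucleotide ambiguity codes and small sequence helpers.

A Sanger trace position showing two peaks is conventionally written as the
single-letter code covering both bases (C/T -> Y, A/G -> R, ...).  These
tables map between codes and base sets and provide IUPAC-aware reverse
complementation and base compatibility tests used throughout the package.
"""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values

#: code -> frozenset of concrete bases it covers ('N' -> {A,C,G,T})
CODE_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

#: frozenset of concrete bases -> minimal covering code
BASES_TO_CODE: dict[frozenset[str], str] = {
    bases: code for code, bases in CODE_TO_BASES.items() if code != "X"
}

CONCRETE = frozenset("ACGT")


def bases_of(code: str) -> frozenset[str]:
    """Concrete bases covered by an IUPAC code."""
    try:
        return CODE_TO_BASES[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(bases) -> str:
    """Minimal IUPAC code covering a set of concrete bases."""
    key = frozenset(b.upper() for b in bases)
    if not key <= CONCRETE:
        raise ValueError(f"not concrete bases: {sorted(key)}")
    if not key:
        raise ValueError("empty base set")
    return BASES_TO_CODE[key]


def is_concrete(code: str) -> bool:
    return code.upper() in CONCRETE


def compatible(x: str, y: str) -> bool:
    """True when two IUPAC codes could derive from the same underlying base."""
    return bool(bases_of(x) & bases_of(y))


def covers(ambiguous: str, concrete: str) -> bool:
    """True when ``ambiguous`` covers every base of ``concrete``."""
    return bases_of(concrete) <= bases_of(ambiguous)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (Y <-> R preserved correctly)."""
    comp = ambiguous_dna_complement
    try:
        return "".join(comp[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"not a nucleotide sequence: bad symbol {exc}") from None
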