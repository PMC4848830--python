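"""Nucleotide alphabet helpers shared across the package.

The canonical internal alphabet for miRNAs is RNA (T is normalized to U on
import, as in miRBase); target sequences may stay in whichever alphabet the
user supplied (DNA or RNA) because all base comparisons go through pairing
and complement tables in which T and U are interchangeable.
"""

from __future__ import annotations

from .errors import SequenceError

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"
VALID_BASES = frozenset("ACGTU")

# Watson-Crick complement, RNA output (used to build miRNA-side bases).
RNA_COMPLEMENT = {"A": "U", "U": "A", "T": "A", "C": "G", "G": "C"}
# Watson-Crick complement, DNA output (used to build mRNA-side bases).
DNA_COMPLEMENT = {"A": "T", "U": "A", "T": "A", "C": "G", "G": "C"}


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def normalize_dna(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


def is_dna(seq: str) -> bool:
    """Guess whether a sequence is written in the DNA alphabet.

    A sequence containing T (or containing neither T nor U) is treated as
    DNA; output alphabets mirror the input.
    """
    up = seq.upper()
    return "T" in up or "U" not in up


def in_alphabet(base: str, dna: bool) -> str:
    """Render a base in the requested alphabet (T<->U)."""
    base = base.upper()
    if dna:
        return "T" if base == "U" else base
    return "U" if base == "T" else base


def validate_sequence(seq: str, what: str = "sequence") -> str:
    """Uppercase ``seq`` and reject anything outside A/C/G/T/U.

    Ambiguity codes (N, R, Y, ...) are rejected rather than treated as
    non-pairing: a silently unmatchable base inside a mutation site would
    be misleading.  The error names the first offending 1-based position.
    """
    up = seq.upper()
    for i, b in enumerate(up, start=1):
        if b not in VALID_BASES:
            raise SequenceError(
                f"invalid character {b!r} at position {i} of {what} "
                "(only A/C/G/T/U are accepted)"
            )
    return up
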