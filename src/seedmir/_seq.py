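"""Nucleotide alphabet helpers.

The package works internally on the DNA alphabet (T, uppercase); RNA input
(U) is accepted everywhere and normalized on entry.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def normalize(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return normalize(seq).translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    s = normalize(seq)
    if not s:
        return 0.0
    return (s.count("G") + s.count("C")) / len(s)


def gc_percent(seq: str) -> float:
    return 100.0 * gc_fraction(seq)


def check_nucleotides(seq: str, *, allow_n: bool = True) -> None:
    bad = set(normalize(seq)) - VALID_BASES
    if not allow_n:
        bad |= set(normalize(seq)) & {"N"}
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
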