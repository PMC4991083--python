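"""Small shared sequence helpers (complementing, IUPAC codes, GC content)."""

from __future__ import annotations

__all__ = ["revcomp", "complement", "gc_fraction", "iupac_code", "DNA_ALPHABET"]

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")

# canonical IUPAC codes for base sets
_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def iupac_code(bases: frozenset | set | str) -> str:
    """IUPAC ambiguity code for a set of unambiguous bases."""
    return _IUPAC[frozenset(bases)]
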