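"""Small shared helpers: DNA alphabet checks and reverse complement."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_BASES = frozenset("ACGT")
READ_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, *, allow_n: bool = False, context: str = "sequence") -> str:
    """Uppercase *seq* and reject characters outside the DNA alphabet."""
    seq = seq.upper()
    allowed = READ_BASES if allow_n else DNA_BASES
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"{context}: invalid base(s) {sorted(bad)!r}; expected only "
            + ("ACGTN" if allow_n else "ACGT")
        )
    return seq
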