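"""Small shared helpers: DNA alphabet, reverse complement, Phred decoding."""

from __future__ import annotations

DNA_ALPHABET = frozenset("ACGTN")
PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def phred_scores(qual: str) -> list[int]:
    """Decode a Phred+33 quality string into integer scores."""
    return [ord(c) - PHRED_OFFSET for c in qual]


def phred_string(scores, offset: int = PHRED_OFFSET) -> str:
    """Encode integer quality scores as a Phred+33 string."""
    return "".join(chr(int(s) + offset) for s in scores)
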