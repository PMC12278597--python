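"""Small sequence helpers used throughout the pipeline."""

from __future__ import annotations

from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_nt(nt: str) -> str:
    """Translate full codons of ``nt`` (trailing partial codon dropped)."""
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    return str(Seq(nt[:usable]).translate())


def hamming(a: str, b: str) -> int:
    """Hamming distance; defined only for equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def hamming_at_most(a: str, b: str, limit: int) -> int | None:
    """Hamming distance if ``<= limit`` else ``None`` (early exit)."""
    if len(a) != len(b):
        return None
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d
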