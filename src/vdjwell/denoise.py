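"""Amplicon sequence variant (ASV) calling by greedy abundance collapse.

A deliberately simple, pluggable stand-in for model-based denoisers: after
exact dereplication, each sequence is absorbed into a more-abundant retained
ASV when it lies within a small Hamming radius of it and its count is at most
``abundance_ratio`` times the parent's -- the UNOISE-style heuristic that a
rare near-neighbour of an abundant sequence is a sequencing error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from vdjwell.sequtil import hamming_at_most

MAX_HAMMING = 2
ABUNDANCE_RATIO = 0.1


@dataclass
class Asv:
    """A denoised unique sequence for one well+chain with read support."""

    seq: str
    count: int
    well: str = ""
    chain: str = ""
    support_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("ASV count must be >= 1")
        if not 0.0 < self.support_fraction <= 1.0:
            raise ValueError("support_fraction must be in (0, 1]")


def derep(seqs: Iterable[str]) -> list[tuple[str, int]]:
    """Exact dereplication: unique sequences with counts, most abundant
    first, ties broken lexicographically."""
    counts = Counter(seqs)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def denoise(
    derep_list: list[tuple[str, int]],
    max_hamming: int = MAX_HAMMING,
    abundance_ratio: float = ABUNDANCE_RATIO,
    well: str = "",
    chain: str = "",
) -> list[Asv]:
    """Greedy absorption over a dereplicated (abundance-sorted) list.

    Each sequence is matched against already-retained ASVs in retention
    order: if within ``max_hamming`` substitutions of one (equal length only;
    Hamming is undefined otherwise) and its count is at most
    ``abundance_ratio`` times the parent's current count, its reads are
    absorbed into the parent.  Otherwise it founds a new ASV.  Support
    fractions are computed over the well+chain read total, so read counts
    are conserved exactly.
    """
    retained: list[Asv] = []
    total = sum(c for _, c in derep_list)
    for seq, count in derep_list:
        parent = None
        for asv in retained:
            if count <= abundance_ratio * asv.count and hamming_at_most(seq, asv.seq, max_hamming) is not None:
                parent = asv
                break
        if parent is not None:
            parent.count += count
        else:
            retained.append(Asv(seq=seq, count=count, well=well, chain=chain))
    for asv in retained:
        asv.support_fraction = asv.count / total
    retained.sort(key=lambda a: (-a.count, a.seq))
    return retained
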