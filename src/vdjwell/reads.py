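"""Read cleaning cascade: pair merging, demultiplexing, primer/TSO excision,
ambiguity and quality filtering, with per-stage read accounting.

The stage order mirrors the upstream protocol: join read pairs, demultiplex
on the 5' well barcode, assign the chain class from the 3' constant-region
primer (excising it), strip the 5' TSO, drop reads containing 'N', trim 3'
bases below q10, and enforce the 385 bp minimum length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from vdjwell.sequtil import hamming_at_most, revcomp

MIN_MERGED_LEN = 385  # minimum retained merged-read length (bp)
QUALITY_FLOOR = 10  # 3' bases below this Phred score are trimmed


@dataclass
class ReadRecord:
    """A read (or merged pair) with per-base qualities and provenance tags."""

    seq: str
    qual: tuple[int, ...]
    read_id: str = ""
    plate: str = ""
    well: str | None = None
    chain: str | None = None
    stage_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.read_id!r}: sequence and quality lengths differ")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class StageLog:
    stage: str
    reads_in: int
    reads_out: int
    reads_discarded: int

    def __post_init__(self) -> None:
        if self.reads_in != self.reads_out + self.reads_discarded:
            raise ValueError(f"stage {self.stage}: accounting violated")


def merge_pairs(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.1,
) -> ReadRecord | None:
    """Merge a read pair by exhaustive 3' overlap scan, or ``None``.

    ``r2`` is reverse-complemented, then every overlap length from full down
    to ``min_overlap`` is scored; the candidate with the most matching bases
    (ties to the longer overlap) wins if its mismatch rate is within
    ``max_mismatch_rate``.  Within the overlap the higher-quality base and
    its quality are kept (ties keep the forward read's call).
    """
    s2 = revcomp(r2.seq)
    q2 = tuple(reversed(r2.qual))
    best = None  # (matches, ov, mismatches)
    max_ov = min(len(r1.seq), len(s2))
    for ov in range(max_ov, min_overlap - 1, -1):
        a = r1.seq[len(r1.seq) - ov :]
        b = s2[:ov]
        mm = sum(x != y for x, y in zip(a, b))
        if mm > max_mismatch_rate * ov:
            continue
        cand = (ov - mm, ov, mm)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        return None
    _, ov, _ = best
    head_len = len(r1.seq) - ov
    seq = [r1.seq[:head_len]]
    qual = list(r1.qual[:head_len])
    for i in range(ov):
        qa, qb = r1.qual[head_len + i], q2[i]
        if qb > qa:
            seq.append(s2[i])
            qual.append(qb)
        else:
            seq.append(r1.seq[head_len + i])
            qual.append(qa)
    seq.append(s2[ov:])
    qual.extend(q2[ov:])
    return ReadRecord(
        seq="".join(seq),
        qual=tuple(qual),
        read_id=r1.read_id,
        plate=r1.plate,
        stage_flags=set(r1.stage_flags) | {"merged"},
    )


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_table: dict[str, str],
    max_mismatches: int = 0,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Assign reads to wells by their 5' barcode and excise it.

    Ambiguous reads (two barcodes tie at the best distance) and non-matching
    reads go to the unassigned pool.  Barcodes must be unique and of equal
    length within a plate.
    """
    barcodes = list(barcode_table.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode in table")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError("barcodes must be equal-length within a plate")
    (blen,) = lengths
    assigned: list[ReadRecord] = []
    unassigned: list[ReadRecord] = []
    for read in reads:
        prefix = read.seq[:blen]
        best_d, best_well, tie = None, None, False
        for well, bc in barcode_table.items():
            d = hamming_at_most(prefix, bc, max_mismatches)
            if d is None:
                continue
            if best_d is None or d < best_d:
                best_d, best_well, tie = d, well, False
            elif d == best_d:
                tie = True
        if best_well is None or tie:
            unassigned.append(read)
        else:
            assigned.append(
                replace(
                    read,
                    seq=read.seq[blen:],
                    qual=read.qual[blen:],
                    well=best_well,
                    stage_flags=set(read.stage_flags) | {"demultiplexed"},
                )
            )
    return assigned, unassigned


def assign_chain_and_excise(
    read: ReadRecord,
    primer_table: dict[str, Sequence[str] | str],
    max_mismatches: int = 2,
) -> ReadRecord | None:
    """Identify the 3' constant-region primer, set the chain class, excise it.

    ``primer_table`` maps chain class to one primer or a cocktail.  The
    best-matching primer within ``max_mismatches`` wins; a tie between two
    different chain classes discards the read (never guess).
    """
    if not primer_table:
        raise ValueError("empty primer table")
    best: tuple[int, str, int] | None = None  # (distance, chain, primer_len)
    tie_other_chain = False
    for chain, primers in primer_table.items():
        if isinstance(primers, str):
            primers = [primers]
        for p in primers:
            if len(p) > len(read.seq):
                continue
            d = hamming_at_most(read.seq[len(read.seq) - len(p) :], p, max_mismatches)
            if d is None:
                continue
            if best is None or d < best[0]:
                best = (d, chain, len(p))
                tie_other_chain = False
            elif d == best[0] and chain != best[1]:
                tie_other_chain = True
    if best is None or tie_other_chain:
        return None
    _, chain, plen = best
    return replace(
        read,
        seq=read.seq[: len(read.seq) - plen],
        qual=read.qual[: len(read.qual) - plen],
        chain=chain,
        stage_flags=set(read.stage_flags) | {"primer_excised"},
    )


def remove_tso(read: ReadRecord, tso: str, max_mismatches: int = 2) -> ReadRecord:
    """Strip a 5' TSO occurrence within tolerance; absent TSO leaves the read unchanged."""
    if not tso:
        raise ValueError("TSO sequence must be non-empty")
    if len(read.seq) >= len(tso) and hamming_at_most(read.seq[: len(tso)], tso, max_mismatches) is not None:
        return replace(
            read,
            seq=read.seq[len(tso) :],
            qual=read.qual[len(tso) :],
            stage_flags=set(read.stage_flags) | {"tso_removed"},
        )
    return read


def filter_n(read: ReadRecord) -> bool:
    """Keep only reads free of ambiguous 'N' calls."""
    return "N" not in read.seq.upper()


def quality_trim_3prime(read: ReadRecord, q_min: int = QUALITY_FLOOR) -> ReadRecord:
    """Trim trailing bases with quality below ``q_min`` from the 3' end."""
    end = len(read.qual)
    while end > 0 and read.qual[end - 1] < q_min:
        end -= 1
    if end == len(read.qual):
        return read
    return replace(read, seq=read.seq[:end], qual=read.qual[:end])


def length_filter(read: ReadRecord, min_len: int = MIN_MERGED_LEN) -> bool:
    return len(read.seq) >= min_len


@dataclass
class CascadeResult:
    """Cleaned reads keyed by (well, chain) plus stage accounting."""

    by_well_chain: dict[tuple[str, str], list[ReadRecord]]
    stage_logs: list[StageLog]


def clean_cascade(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    barcode_table: dict[str, str],
    primer_table: dict[str, Sequence[str] | str],
    tso: str,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.1,
    barcode_mismatches: int = 0,
    primer_mismatches: int = 2,
    tso_mismatches: int = 2,
    q_min: int = QUALITY_FLOOR,
    min_len: int = MIN_MERGED_LEN,
) -> CascadeResult:
    """Run the full cleaning cascade in protocol order with stage logs:
    join -> demux -> primer -> TSO -> N -> 3' q-trim -> length."""
    logs: list[StageLog] = []

    pairs = list(pairs)
    merged = []
    for r1, r2 in pairs:
        m = merge_pairs(r1, r2, min_overlap, max_mismatch_rate)
        if m is not None:
            merged.append(m)
    logs.append(StageLog("join", len(pairs), len(merged), len(pairs) - len(merged)))

    assigned, unassigned = demultiplex(merged, barcode_table, barcode_mismatches)
    logs.append(StageLog("demux", len(merged), len(assigned), len(unassigned)))

    with_chain = []
    for read in assigned:
        out = assign_chain_and_excise(read, primer_table, primer_mismatches)
        if out is not None:
            with_chain.append(out)
    logs.append(StageLog("primer", len(assigned), len(with_chain), len(assigned) - len(with_chain)))

    no_tso = [remove_tso(r, tso, tso_mismatches) for r in with_chain]
    logs.append(StageLog("tso", len(with_chain), len(no_tso), 0))

    no_n = [r for r in no_tso if filter_n(r)]
    logs.append(StageLog("n_filter", len(no_tso), len(no_n), len(no_tso) - len(no_n)))

    trimmed = [quality_trim_3prime(r, q_min) for r in no_n]
    logs.append(StageLog("qtrim", len(no_n), len(trimmed), 0))

    kept = [r for r in trimmed if length_filter(r, min_len)]
    logs.append(StageLog("length", len(trimmed), len(kept), len(trimmed) - len(kept)))

    by_well_chain: dict[tuple[str, str], list[ReadRecord]] = {}
    for read in kept:
        by_well_chain.setdefault((read.well, read.chain), []).append(read)
    return CascadeResult(by_well_chain=by_well_chain, stage_logs=logs)
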