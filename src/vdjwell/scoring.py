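"""Replicate-based "star rating" confidence scoring.

Sample IDs encode the replicate structure (``Project/Parent.subclone``):
biological replicates (BR) are independent subclones of the same parent
line, technical replicates (TR) are independent samples of the same
subclone.  A chain's score combines

* an **ASV score** -- within-well read support, reads-per-sequence over
  reads-per-primer-well, in [0, 1];
* a **match score** -- cross-replicate support,
  ``(BR + nu*TR) - (1 - (BR+TR)/TotalReplicates)`` with the technical
  replicate weight ``nu`` in [0, 1];
* the **total score** -- ``clamp(ln(MatchScore), 0, lambda) + mu*ASVScore``
  with ceilings ``mu + lambda = 5`` (defaults mu=2, lambda=3), a 0-5 scale.

The printed form of the combination uses ``max(lambda, ln(MatchScore))``,
which conflicts with lambda being a ceiling and with the stated 0-5 range
(it would force every total above 3); the default mode therefore clamps the
log-match component into [0, lambda], and ``literal_max_mode`` preserves the
printed formula verbatim for auditing.

Light chains whose amino-acid bin appears in more than half of a run's
samples are flagged as the aberrant myeloma-derived (Sp2/0) light chain and
excluded from reporting and pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from vdjwell.chains import LIGHT_TYPE, chain_type


@dataclass(frozen=True)
class SampleId:
    """``Project/Parent.subclone``; subclone may be absent (``Project/Parent``)."""

    project: str
    parent: str
    subclone: str | None
    raw: str

    @property
    def group_key(self) -> tuple[str, str]:
        """Samples sharing project+parent form one replicate group."""
        return (self.project, self.parent)


def parse_sample_id(raw: str) -> SampleId:
    """Split on the first '/' and the last '.' after it."""
    if "/" not in raw:
        raise ValueError(f"sample ID {raw!r} lacks the 'Project/Parent' separator")
    project, rest = raw.split("/", 1)
    if "." in rest:
        parent, subclone = rest.rsplit(".", 1)
    else:
        parent, subclone = rest, None
    return SampleId(project=project, parent=parent, subclone=subclone, raw=raw)


@dataclass
class ScoringParams:
    mu: float = 2.0
    lam: float = 3.0
    nu: float = 1.0
    high_conf_threshold: float = 4.0
    aberrant_prevalence: float = 0.5
    literal_max_mode: bool = False

    def __post_init__(self) -> None:
        if abs(self.mu + self.lam - 5.0) > 1e-9:
            raise ValueError("score ceilings must satisfy mu + lam == 5")
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("nu must lie in [0, 1]")


def count_replicates(group: Sequence[SampleId], present: Sequence[bool]) -> tuple[int, int, int]:
    """BR/TR counts for one chain bin over one replicate group.

    ``group`` lists every sample *instance* of a project+parent group
    (technical replicates repeat the same sample ID); ``present`` marks the
    instances in which the bin was observed.  BR is the number of distinct
    subclones among supporting instances, TR the remaining supporting
    instances, and the total is the group size.
    """
    if len(group) != len(present):
        raise ValueError("group and presence vectors differ in length")
    supporting = [s for s, p in zip(group, present) if p]
    # subclone-absent samples count as one (empty-string) subclone
    br = len({s.subclone or "" for s in supporting})
    tr = len(supporting) - br
    return br, tr, len(group)


def asv_score(reads_per_sequence: int, reads_per_primer_well: int) -> float:
    """Within-well read support: reads for this sequence over total reads
    assigned to the same chain's primer class in the well."""
    if reads_per_primer_well <= 0:
        raise ValueError("reads_per_primer_well must be positive")
    if not 0 <= reads_per_sequence <= reads_per_primer_well:
        raise ValueError("reads_per_sequence must lie in [0, reads_per_primer_well]")
    return reads_per_sequence / reads_per_primer_well


def match_score(br: int, tr: int, total_replicates: int, nu: float = 1.0) -> float:
    """Cross-replicate support: ``(BR + nu*TR) - (1 - (BR+TR)/Total)``.

    The penalty term (1 minus the supported fraction of the group) is
    unweighted, as printed; ``nu`` only discounts TRs in the support term.
    """
    if total_replicates < 1:
        raise ValueError("total_replicates must be >= 1")
    if br + tr > total_replicates:
        raise ValueError("br + tr cannot exceed total_replicates")
    return (br + nu * tr) - (1.0 - (br + tr) / total_replicates)


def total_score(match: float, asv: float, params: ScoringParams | None = None) -> float:
    """Combine match and ASV components into the 0-5 star rating.

    Default mode clamps ``ln(match)`` into ``[0, lambda]`` (non-positive
    match contributes 0); ``literal_max_mode`` computes the printed
    ``max(lambda, ln(match))`` instead.
    """
    params = params or ScoringParams()
    if params.literal_max_mode:
        log_match = math.log(match) if match > 0 else -math.inf
        component = max(params.lam, log_match)
    elif match <= 0:
        component = 0.0
    else:
        component = min(max(math.log(match), 0.0), params.lam)
    return component + params.mu * asv


@dataclass
class ScoredEntry:
    """One chain bin of one well, with its replicate evidence and scores."""

    sample: SampleId
    chain_class: str
    aa_key: tuple[str, str]
    nt_reported: str
    count: int
    well_key: tuple[str, str] = ("", "")  # (plate_id, well_id)
    br: int = 0
    tr: int = 0
    total_replicates: int = 1
    asv_score: float = 0.0
    match_score: float = 0.0
    total_score: float = 0.0
    percentile: float = 0.0
    aberrant_flag: bool = False
    verified: bool = False
    high_confidence: bool = False
    regions: dict[str, str] = field(default_factory=dict)


def remove_aberrant_light_chains(
    entries: Iterable[ScoredEntry], prevalence_threshold: float = 0.5
) -> list[ScoredEntry]:
    """Flag light-type bins present in strictly more than
    ``prevalence_threshold`` of the run's distinct samples.

    Such run-wide light chains are characteristic of the aberrant
    Sp2/0-derived light chain rather than any hybridoma's true chain.
    Heavy-type chains are never flagged.  Returns the entries with
    ``aberrant_flag`` set; flagged entries are excluded from reporting and
    pairing downstream.
    """
    entries = list(entries)
    all_samples = {e.sample.raw for e in entries}
    n = len(all_samples)
    seen: dict[tuple[str, str], set[str]] = {}
    for e in entries:
        if chain_type(e.chain_class) == "light":
            seen.setdefault(e.aa_key, set()).add(e.sample.raw)
    flagged = {k for k, samples in seen.items() if n > 0 and len(samples) / n > prevalence_threshold}
    for e in entries:
        e.aberrant_flag = e.aa_key in flagged
    return entries


def complexity(sample_entries: Iterable[ScoredEntry]) -> int:
    """Number of possible chain pairings for one sample:
    count(distinct light bins) * count(distinct heavy bins), aberrant bins
    excluded."""
    light = set()
    heavy = set()
    for e in sample_entries:
        if e.aberrant_flag:
            continue
        if chain_type(e.chain_class) == "light":
            light.add(e.aa_key)
        else:
            heavy.add(e.aa_key)
    return len(light) * len(heavy)


def percentile(score: float, population: Sequence[float]) -> float:
    """Empirical percentile: fraction of the population strictly below
    ``score`` (0 for a singleton population)."""
    if not population:
        raise ValueError("population must be non-empty")
    below = sum(1 for s in population if s < score)
    return below / len(population)


def select_high_confidence_pairs(
    entries: Iterable[ScoredEntry], params: ScoringParams | None = None
) -> list[tuple[ScoredEntry, ScoredEntry]]:
    """Pick one light/heavy pair per sample where both chains exceed the
    high-confidence threshold.

    Per sample and chain type the maximum-scoring qualifying entry wins
    (ties: higher ASV score, then lexicographically smaller nucleotide
    sequence).  Entries verified by cloning qualify regardless of score.
    Identical (light aa, heavy aa) pairs arising from replicate samples of
    the same clone collapse into one pair (best-scoring instance kept);
    after that, pairs whose light or heavy amino-acid key also appears in
    another selected pair are dropped: high-confidence pairs must be unique
    sequences across the set.
    """
    params = params or ScoringParams()
    by_sample: dict[str, list[ScoredEntry]] = {}
    for e in entries:
        if e.aberrant_flag:
            continue
        by_sample.setdefault(e.sample.raw, []).append(e)

    def best(cands: list[ScoredEntry]) -> ScoredEntry | None:
        qual = [e for e in cands if e.total_score > params.high_conf_threshold or e.verified]
        if not qual:
            return None
        return min(qual, key=lambda e: (-e.total_score, -e.asv_score, e.nt_reported))

    selected: dict[tuple, tuple[ScoredEntry, ScoredEntry]] = {}
    for sample in sorted(by_sample):
        cands = by_sample[sample]
        vl = best([e for e in cands if chain_type(e.chain_class) == "light"])
        vh = best([e for e in cands if chain_type(e.chain_class) == "heavy"])
        if vl is not None and vh is not None:
            key = (vl.aa_key, vh.aa_key)
            prev = selected.get(key)
            if prev is None or vl.total_score + vh.total_score > prev[0].total_score + prev[1].total_score:
                selected[key] = (vl, vh)
    pairs = [selected[k] for k in sorted(selected)]

    light_counts: dict[tuple[str, str], int] = {}
    heavy_counts: dict[tuple[str, str], int] = {}
    for vl, vh in pairs:
        light_counts[vl.aa_key] = light_counts.get(vl.aa_key, 0) + 1
        heavy_counts[vh.aa_key] = heavy_counts.get(vh.aa_key, 0) + 1
    unique = [
        (vl, vh)
        for vl, vh in pairs
        if light_counts[vl.aa_key] == 1 and heavy_counts[vh.aa_key] == 1
    ]
    for vl, vh in unique:
        vl.high_confidence = True
        vh.high_confidence = True
    return unique
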