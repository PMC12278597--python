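"""Variable-domain annotation: translation, IMGT-style region segmentation,
region-based quality filters, amino-acid binning, and reported-span
extraction.

HMM-based numbering is an external convention, not something this package
re-derives, so segmentation sits behind a small backend interface:

* ``table`` -- looks translated domains up in a table of known region
  boundaries (fed from the simulator's ground truth in tests);
* ``motif`` -- a heuristic locating the two conserved cysteines (IMGT 23 and
  104) and the J-region [WF]GxG anchor.

IMGT positions are handled as a simplified sequential 1..N numbering without
insertion codes.  The exported nucleotide span covers IMGT positions 1-127
for light-type chains (VL, alpha, gamma) and 1-128 for heavy-type chains
(VH, beta, delta); missing leading or trailing positions narrow the span,
never pad it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol

from vdjwell.chains import HEAVY_TYPE, REGION_NAMES, reported_span_end
from vdjwell.denoise import Asv
from vdjwell.sequtil import translate_nt

MIN_SUPPORT = 0.10  # minimum within-well read support for a reported bin
_MIN_DOMAIN_AA = 90  # shortest stop-free stretch accepted as a variable domain


@dataclass
class AnnotatedChain:
    """An annotated variable domain within a translated ASV."""

    aa_seq: str  # full translation of the chosen frame
    chain_class: str
    regions: dict[str, str]  # FR1..FR4 / CDR1..CDR3 -> aa segment
    frame: int = 0
    nt_full: str = ""  # the ASV nucleotide sequence the frame refers to
    domain_start: int = 0  # aa offset of FR1 within aa_seq
    imgt_start: int = 1  # first covered IMGT position (1 unless truncated)
    imgt_numbering: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        domain = self.domain_aa
        if self.aa_seq[self.domain_start : self.domain_start + len(domain)] != domain:
            raise ValueError("regions are not a contiguous segment of aa_seq at domain_start")
        if not self.imgt_numbering:
            self.imgt_numbering = {self.imgt_start + i: aa for i, aa in enumerate(domain)}

    @property
    def domain_aa(self) -> str:
        return "".join(self.regions[r] for r in REGION_NAMES)


class AnnotationBackend(Protocol):
    def segment(self, aa: str, chain_class: str) -> tuple[dict[str, str], int] | None:
        """Return (regions, domain_start) within ``aa`` or None."""


class TableBackend:
    """Segment by exact lookup of known variable-domain amino-acid sequences.

    Built from a table of (chain_class, region segments); a query is placed
    when one of the known domains occurs as a substring of its translation.
    """

    def __init__(self, entries: Iterable[tuple[str, dict[str, str]]]):
        self._by_domain: dict[tuple[str, str], dict[str, str]] = {}
        for chain_class, regions in entries:
            domain = "".join(regions[r] for r in REGION_NAMES)
            self._by_domain[(chain_class, domain)] = dict(regions)

    @classmethod
    def from_clones(cls, clones: Iterable) -> "TableBackend":
        entries = []
        for clone in clones:
            for cc, ct in clone.chains.items():
                entries.append((cc, ct.regions))
        return cls(entries)

    def segment(self, aa: str, chain_class: str) -> tuple[dict[str, str], int] | None:
        for (cc, domain), regions in self._by_domain.items():
            if cc != chain_class:
                continue
            idx = aa.find(domain)
            if idx >= 0:
                return dict(regions), idx
        return None


class MotifBackend:
    """Heuristic segmentation from conserved anchors.

    Finds a Cys pair spaced like IMGT 23/104 under the canonical region
    lengths used across this package (FR1 25, CDR1 8, FR2 17, CDR2 7,
    FR3 38, FR4 11 aa) and a J-region ``[WF]GxG`` anchor 5-25 residues
    downstream delimiting CDR3.  Sequences without that architecture are
    rejected.
    """

    _LENS = {"FR1": 25, "CDR1": 8, "FR2": 17, "CDR2": 7, "FR3": 38, "FR4": 11}
    _CYS_GAP = 72  # aa between Cys23 and Cys104 under the canonical lengths

    def segment(self, aa: str, chain_class: str) -> tuple[dict[str, str], int] | None:
        anchor = "W" if chain_class in HEAVY_TYPE else "F"
        for m in re.finditer("C", aa):
            i = m.start()
            j = i + self._CYS_GAP
            if j >= len(aa) or aa[j] != "C":
                continue
            for cdr3_len in range(5, 26):
                k = j + 1 + cdr3_len  # candidate FR4 start
                if k + self._LENS["FR4"] > len(aa):
                    break
                if aa[k] == anchor and aa[k + 1] == "G" and aa[k + 3] == "G":
                    start = i - 22
                    if start < 0:
                        continue
                    regions = {}
                    pos = start
                    for name in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
                        regions[name] = aa[pos : pos + self._LENS[name]]
                        pos += self._LENS[name]
                    regions["CDR3"] = aa[pos : pos + cdr3_len]
                    pos += cdr3_len
                    regions["FR4"] = aa[pos : pos + self._LENS["FR4"]]
                    return regions, start
        return None


_BACKENDS = {"table": TableBackend, "motif": MotifBackend}


def get_backend(name: str, **kwargs) -> AnnotationBackend:
    """Instantiate a named backend; unknown names are a hard error."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise KeyError(f"unknown annotation backend {name!r}; available: {sorted(_BACKENDS)}") from None
    return cls(**kwargs)


def translate_best_frame(nt: str, min_domain_aa: int = _MIN_DOMAIN_AA) -> tuple[str, int] | None:
    """Pick the forward frame whose translation has the longest stop-free
    stretch; ``None`` when no frame offers a stretch long enough to hold a
    variable domain."""
    best: tuple[int, int, str] | None = None  # (stretch, -frame, aa)
    for frame in range(3):
        aa = translate_nt(nt[frame:])
        stretch = max((len(s) for s in aa.split("*")), default=0)
        if best is None or stretch > best[0]:
            best = (stretch, frame, aa)
    if best is None or best[0] < min_domain_aa:
        return None
    return best[2], best[1]


def annotate(
    aa: str,
    backend: AnnotationBackend,
    chain_class: str,
    nt: str = "",
    frame: int = 0,
) -> AnnotatedChain | None:
    """Segment an amino-acid sequence into FR/CDR regions via ``backend``."""
    placed = backend.segment(aa, chain_class)
    if placed is None:
        return None
    regions, domain_start = placed
    return AnnotatedChain(
        aa_seq=aa,
        chain_class=chain_class,
        regions=regions,
        frame=frame,
        nt_full=nt,
        domain_start=domain_start,
    )


def annotate_nt(nt: str, backend: AnnotationBackend, chain_class: str) -> AnnotatedChain | None:
    """Translate (best frame) then segment a nucleotide sequence."""
    tr = translate_best_frame(nt)
    if tr is None:
        return None
    aa, frame = tr
    return annotate(aa, backend, chain_class, nt=nt, frame=frame)


def filter_zero_length_regions(chain: AnnotatedChain) -> bool:
    """Keep only chains whose seven FR/CDR regions all have length >= 1."""
    return all(len(chain.regions[r]) > 0 for r in REGION_NAMES)


@dataclass
class ChainBin:
    """ASVs sharing one amino-acid region prediction within a well."""

    aa_key: tuple[str, str]  # (chain_class, concatenated region aa)
    member_asvs: list[Asv]
    annotation: AnnotatedChain
    representative_nt: str = ""
    total_count: int = 0

    def __post_init__(self) -> None:
        self.total_count = sum(a.count for a in self.member_asvs)
        if not self.representative_nt:
            top = min(self.member_asvs, key=lambda a: (-a.count, a.seq))
            self.representative_nt = top.seq


def bin_by_aa(annotated_asvs: Iterable[tuple[Asv, AnnotatedChain]]) -> list[ChainBin]:
    """Group ASVs with identical (chain class, region amino acids).

    Distinct nucleotide variants -- typically differing only outside the
    annotated domain or by synonymous edge-trimmed bases -- collapse into one
    bin whose count is the sum of member counts and whose representative is
    the most abundant member (ties to the lexicographically smaller
    sequence).
    """
    groups: dict[tuple[str, str], list[tuple[Asv, AnnotatedChain]]] = {}
    for asv, ann in annotated_asvs:
        key = (ann.chain_class, ann.domain_aa)
        groups.setdefault(key, []).append((asv, ann))
    bins = []
    for key, members in groups.items():
        asvs = [a for a, _ in members]
        top_idx = min(range(len(asvs)), key=lambda i: (-asvs[i].count, asvs[i].seq))
        bins.append(ChainBin(aa_key=key, member_asvs=asvs, annotation=members[top_idx][1]))
    bins.sort(key=lambda b: (-b.total_count, b.aa_key))
    return bins


def asv_support_filter(
    bins: Iterable[ChainBin], well_chain_total: int, min_support: float = MIN_SUPPORT
) -> list[ChainBin]:
    """Retain bins whose read support within the well+chain is at least
    ``min_support`` (inclusive threshold)."""
    if well_chain_total <= 0:
        raise ValueError("well_chain_total must be positive")
    return [b for b in bins if b.total_count / well_chain_total >= min_support]


def extract_reported_nt(chain: AnnotatedChain) -> str:
    """Nucleotides covering IMGT 1-127 (light-type) or 1-128 (heavy-type).

    A domain annotated from IMGT position ``imgt_start`` onward, or ending
    before the span limit, yields a correspondingly narrower span -- the span
    is never padded.
    """
    limit = reported_span_end(chain.chain_class)
    n_aa = min(limit - chain.imgt_start + 1, len(chain.domain_aa))
    if n_aa <= 0:
        return ""
    start_nt = chain.frame + 3 * chain.domain_start
    return chain.nt_full[start_nt : start_nt + 3 * n_aa]
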