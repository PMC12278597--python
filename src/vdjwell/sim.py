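"""Synthetic plate simulator with full ground truth.

Emulates the library structure the pipeline assumes: each clonal well emits
one true light-chain and one true heavy-chain amplicon (plus optional extra
chains for oligoclonal wells), laid out as

    [well barcode] [TSO] [pad .. variable domain .. pad] [constant primer]

Paired 300 nt reads are taken from both ends of the amplicon with a per-cycle
quality profile whose 3' tail decays, and substitution errors applied at a
configurable rate.  Technical/biological replicate structure is encoded in
sample IDs (``Project/Parent.subclone``), and a run-wide aberrant light chain
can be spiked into a majority of samples -- the contamination mode the
aberrant-chain filter downstream is built to remove.

Sequences are random codon strings with conserved Cys / [WF]GxG anchors at
the canonical IMGT positions, not real germlines: annotation downstream is
table-driven, so biological realism is unnecessary for correctness testing.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from vdjwell.chains import HEAVY_TYPE, LIGHT_TYPE, REGION_NAMES, chain_type
from vdjwell.sequtil import revcomp, translate_nt

# Amino acids and a single codon per aa keeps translation round-trips exact
# while the rng still varies codons via synonymous choices below.
_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}

# Fixed region lengths (aa) except CDR3; roughly the canonical IMGT tiling.
_REGION_LEN = {"FR1": 25, "CDR1": 8, "FR2": 17, "CDR2": 7, "FR3": 38, "FR4": 11}
CDR3_MIN, CDR3_MAX = 5, 25

#: aa offset of the conserved FR1 Cys within the domain (IMGT Cys 23).
CYS1_OFFSET = 22
#: aa offset of the conserved FR3-terminal Cys (IMGT Cys 104 analogue).
CYS2_OFFSET = _REGION_LEN["FR1"] + _REGION_LEN["CDR1"] + _REGION_LEN["FR2"] + _REGION_LEN["CDR2"] + _REGION_LEN["FR3"] - 1

PAD_AA = 10  # stop-free codon pad on each side of the domain, 30 nt

DEFAULT_TSO = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
DEFAULT_PRIMERS = {
    "VL": "GATGGTGCAGCCACAGTTCGTTTG",
    "VH": "AGACCGATGGGGCTGTTGTTTTGG",
    "alpha": "CAGCTGGTACACGGCAGGGTCAGG",
    "beta": "TGCTTCTGATGGCTCAAACACAGC",
    "gamma": "GTTGCTCCAGGCCAAGGAAACGTC",
    "delta": "CACTTCCAGAAAGCAGCCATATCC",
}

READ_LEN = 300
BARCODE_LEN = 8


def _random_aa(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_AA) for _ in range(n))


def _encode(rng: random.Random, aa: str) -> str:
    return "".join(rng.choice(_CODONS[c]) for c in aa)


@dataclass(frozen=True)
class ChainTruth:
    """Ground truth for one chain of a clone."""

    chain_class: str
    regions: dict[str, str]  # region name -> aa segment
    domain_nt: str  # nucleotides encoding exactly the concatenated regions
    insert_nt: str  # pad + domain + pad, the post-cleaning amplicon body

    def __post_init__(self) -> None:
        aa = "".join(self.regions[r] for r in REGION_NAMES)
        if any(len(self.regions[r]) == 0 for r in REGION_NAMES):
            raise ValueError("zero-length region in clone truth")
        if translate_nt(self.domain_nt) != aa:
            raise ValueError("domain_nt does not encode the region aa")
        if "*" in translate_nt(self.insert_nt):
            raise ValueError("stop codon in annotated frame of insert")

    @property
    def domain_aa(self) -> str:
        return "".join(self.regions[r] for r in REGION_NAMES)


@dataclass(frozen=True)
class CloneSpec:
    """A clone with ground-truth chain sequences and region segmentation."""

    clone_id: str
    chains: dict[str, ChainTruth]

    def _by_type(self, want: str) -> ChainTruth:
        for ct in self.chains.values():
            if chain_type(ct.chain_class) == want:
                return ct
        raise KeyError(f"clone {self.clone_id} has no {want}-type chain")

    @property
    def light(self) -> ChainTruth:
        return self._by_type("light")

    @property
    def heavy(self) -> ChainTruth:
        return self._by_type("heavy")

    # Convenience aliases for the common BCR case.
    @property
    def vl_nt(self) -> str:
        return self.light.domain_nt

    @property
    def vh_nt(self) -> str:
        return self.heavy.domain_nt

    @property
    def vl_regions(self) -> dict[str, str]:
        return self.light.regions

    @property
    def vh_regions(self) -> dict[str, str]:
        return self.heavy.regions


def _make_regions(rng: random.Random, chain_class: str, cdr3_len: int) -> dict[str, str]:
    regions: dict[str, str] = {}
    for name in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
        regions[name] = _random_aa(rng, _REGION_LEN[name])
    # conserved anchors the motif heuristic relies on
    fr1 = list(regions["FR1"])
    fr1[CYS1_OFFSET] = "C"
    regions["FR1"] = "".join(fr1)
    regions["FR3"] = regions["FR3"][:-1] + "C"
    regions["CDR3"] = _random_aa(rng, cdr3_len)
    j_anchor = "WGQG" if chain_class in HEAVY_TYPE else "FGGG"
    regions["FR4"] = j_anchor + _random_aa(rng, _REGION_LEN["FR4"] - len(j_anchor))
    return regions


def generate_clone(
    seed: int,
    chain_classes: tuple[str, ...] = ("VL", "VH"),
    cdr3_len: dict[str, int] | None = None,
) -> CloneSpec:
    """Generate a clone with one chain per requested class, deterministically.

    The light- and heavy-chain CDR3 lengths are correlated (heavy six
    residues longer than light), giving true pairings a planted covariate
    that scrambled pairings usually lack.  ``cdr3_len`` overrides the drawn
    length per chain class.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = random.Random(seed)
    light_cdr3 = rng.randint(CDR3_MIN, CDR3_MAX - 8)
    chains: dict[str, ChainTruth] = {}
    for cc in chain_classes:
        if chain_type(cc) == "light":
            n3 = light_cdr3
        else:
            n3 = light_cdr3 + 6
        if cdr3_len and cc in cdr3_len:
            n3 = cdr3_len[cc]
        regions = _make_regions(rng, cc, n3)
        domain_aa = "".join(regions[r] for r in REGION_NAMES)
        domain_nt = _encode(rng, domain_aa)
        pre = _encode(rng, _random_aa(rng, PAD_AA))
        post = _encode(rng, _random_aa(rng, PAD_AA))
        chains[cc] = ChainTruth(cc, regions, domain_nt, pre + domain_nt + post)
    return CloneSpec(clone_id=f"clone{seed}", chains=chains)


@dataclass(frozen=True)
class QualityProfile:
    """Per-cycle mean quality: flat then linear decay over the last cycles."""

    q_high: int = 37
    q_low: int = 8
    tail_len: int = 30

    def quals(self, read_len: int) -> tuple[int, ...]:
        out = []
        for i in range(read_len):
            k = i - (read_len - self.tail_len)
            if k < 0:
                out.append(self.q_high)
            else:
                out.append(int(self.q_high - (self.q_high - self.q_low) * (k + 1) / self.tail_len))
        return tuple(out)


@dataclass(frozen=True)
class WellSpec:
    """One well: sample identity, barcode, and its clone mixture.

    ``clone_mixture`` entries are ``(clone_id, fraction)`` or
    ``(clone_id, fraction, chains)`` where ``chains`` restricts which of the
    clone's chains the component emits (used to spike a bare aberrant VL).
    """

    well_id: str
    sample_id: str
    barcode: str
    clone_mixture: tuple[tuple, ...]

    def components(self) -> list[tuple[str, float, tuple[str, ...] | None]]:
        out = []
        for entry in self.clone_mixture:
            if len(entry) == 2:
                out.append((entry[0], float(entry[1]), None))
            else:
                out.append((entry[0], float(entry[1]), tuple(entry[2])))
        return out


@dataclass(frozen=True)
class PlateSpec:
    plate_id: str
    wells: tuple[WellSpec, ...]
    primer_set: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PRIMERS))
    tso: str = DEFAULT_TSO
    error_rate: float = 0.0
    quality_profile: QualityProfile = field(default_factory=QualityProfile)
    reads_per_well: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        barcodes = [w.barcode for w in self.wells]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError(f"duplicate barcode within plate {self.plate_id}")
        if self.reads_per_well <= 0:
            raise ValueError("reads_per_well must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        for w in self.wells:
            total = sum(c[1] for c in w.components())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"well {w.well_id}: mixture fractions sum to {total}, not 1")


def _largest_remainder(weights: list[float], total: int) -> list[int]:
    raw = [w * total for w in weights]
    counts = [int(math.floor(x)) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    bases = "ACGT"
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([x for x in bases if x != b])
    return "".join(out)


def generate_plate(
    plate: PlateSpec, clones: dict[str, CloneSpec]
) -> tuple[list[tuple[str, str, tuple[int, ...]]], list[tuple[str, str, tuple[int, ...]]], pd.DataFrame]:
    """Simulate one plate of paired-end reads.

    Returns ``(r1, r2, truth)`` where each read list holds
    ``(read_id, sequence, qualities)`` tuples and ``truth`` maps each well to
    its true chain insert sequences and mixture fractions.  Deterministic for
    a fixed :class:`PlateSpec`.
    """
    rng = random.Random(plate.seed)
    quals = plate.quality_profile.quals(READ_LEN)
    r1_out: list[tuple[str, str, tuple[int, ...]]] = []
    r2_out: list[tuple[str, str, tuple[int, ...]]] = []
    truth_rows = []
    for well in plate.wells:
        amplicons: list[tuple[str, str, float]] = []  # (chain_class, amplicon, weight)
        for clone_id, fraction, chains in well.components():
            if clone_id not in clones:
                raise KeyError(f"well {well.well_id} references unknown clone {clone_id!r}")
            clone = clones[clone_id]
            use = chains if chains is not None else tuple(clone.chains)
            per_chain = fraction / len(use)
            for cc in use:
                ct = clone.chains[cc]
                primer = plate.primer_set[cc]
                amplicon = well.barcode + plate.tso + ct.insert_nt + primer
                amplicons.append((cc, amplicon, per_chain))
                truth_rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "well_id": well.well_id,
                        "sample_id": well.sample_id,
                        "clone_id": clone_id,
                        "chain": cc,
                        "sequence": ct.insert_nt,
                        "fraction": per_chain,
                    }
                )
        counts = _largest_remainder([a[2] for a in amplicons], plate.reads_per_well)
        idx = 0
        for (cc, amplicon, _), n in zip(amplicons, counts):
            for _ in range(n):
                rid = f"{plate.plate_id}:{well.well_id}:{idx}"
                idx += 1
                r1 = _mutate(rng, amplicon[:READ_LEN], plate.error_rate)
                r2 = _mutate(rng, revcomp(amplicon[-READ_LEN:]), plate.error_rate)
                r1_out.append((rid, r1, quals))
                r2_out.append((rid, r2, quals))
    truth = pd.DataFrame(truth_rows)
    return r1_out, r2_out, truth


def write_fastq(reads: list[tuple[str, str, tuple[int, ...]]], path: str | Path) -> None:
    """Write Phred+33 FASTQ; plain text for byte-stable output."""
    with open(path, "w") as fh:
        for rid, seq, quals in reads:
            fh.write(f"@{rid}\n{seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in quals[: len(seq)]) + "\n")


def _random_barcodes(rng: random.Random, n: int) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = "".join(rng.choice("ACGT") for _ in range(BARCODE_LEN))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _well_ids(n: int) -> list[str]:
    ids = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]
    return ids[:n]


@dataclass
class RunTruth:
    """Paths and ground truth for a simulated run directory."""

    outdir: Path
    plates: list[PlateSpec]
    clones: dict[str, CloneSpec]
    truth: pd.DataFrame
    sample_sheet: pd.DataFrame
    aberrant_clone_id: str | None


def _expand_design(replicate_design: dict) -> list[tuple[str, str, int]]:
    """Normalise ``parent -> subclone -> n_samples`` into (parent, subclone, n)."""
    out = []
    for parent, sub in replicate_design.items():
        if not isinstance(parent, str) or "/" not in parent:
            raise ValueError(f"replicate_design key {parent!r} must look like 'Project/Parent'")
        if isinstance(sub, int):
            if sub < 1:
                raise ValueError(f"replicate_design[{parent!r}] must be >= 1 subclone")
            for i in range(1, sub + 1):
                out.append((parent, str(i), 1))
        elif isinstance(sub, dict):
            for sc, n in sub.items():
                if not isinstance(n, int) or n < 1:
                    raise ValueError(f"replicate_design[{parent!r}][{sc!r}] must be a positive count")
                out.append((parent, str(sc), n))
        else:
            raise ValueError(f"replicate_design[{parent!r}] must be an int or a subclone map")
    return out


def generate_run(
    outdir: str | Path,
    replicate_design: dict,
    n_plates: int = 1,
    aberrant_chain: CloneSpec | None = None,
    aberrant_prevalence: float = 0.0,
    aberrant_fraction: float = 0.3,
    seed: int = 0,
    reads_per_well: int = 200,
    error_rate: float = 0.0,
    chain_classes: tuple[str, ...] = ("VL", "VH"),
    wells_per_plate: int = 96,
) -> RunTruth:
    """Simulate a full multi-plate run and write its input files.

    Sample IDs follow ``Project/Parent.subclone``; technical replicates are
    extra wells carrying the same full sample ID.  When ``aberrant_chain`` is
    given, its light chain is spiked as a secondary light chain (at
    ``aberrant_fraction`` of the well mixture) into
    ``ceil(aberrant_prevalence * n_samples)`` distinct samples.

    Writes per-plate ``<plate>_R1.fastq``/``_R2.fastq``, ``samples.csv``
    (plate_id,well_id,sample_id,barcode), ``primers.fasta``, ``tso.txt``,
    ``truth.tsv`` and ``clone_regions.tsv`` under ``outdir``.
    """
    if not 0.0 <= aberrant_prevalence <= 1.0:
        raise ValueError("aberrant_prevalence must be in [0, 1]")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    design = _expand_design(replicate_design)
    clones: dict[str, CloneSpec] = {}
    parent_clone: dict[str, str] = {}
    for i, parent in enumerate(dict.fromkeys(p for p, _, _ in design)):
        clone = generate_clone(seed=seed * 10007 + i + 1, chain_classes=chain_classes)
        clones[clone.clone_id] = clone
        parent_clone[parent] = clone.clone_id

    sample_instances: list[str] = []  # one entry per well, TRs repeat the ID
    for parent, subclone, n in design:
        for _ in range(n):
            sample_instances.append(f"{parent}.{subclone}")

    distinct = list(dict.fromkeys(sample_instances))
    spiked: set[str] = set()
    if aberrant_chain is not None and aberrant_prevalence > 0:
        k = math.ceil(aberrant_prevalence * len(distinct))
        spiked = set(distinct[:k])
        ab_id = aberrant_chain.clone_id
        light_cc = aberrant_chain.light.chain_class
        clones[ab_id] = aberrant_chain

    per_plate = min(wells_per_plate, 96)
    if len(sample_instances) > n_plates * per_plate:
        raise ValueError("replicate design does not fit on the requested plates")

    plates: list[PlateSpec] = []
    sheet_rows = []
    truths = []
    cursor = 0
    for p in range(n_plates):
        chunk = sample_instances[cursor : cursor + per_plate]
        cursor += per_plate
        if not chunk:
            break
        barcodes = _random_barcodes(rng, len(chunk))
        wells = []
        for wid, sid, bc in zip(_well_ids(len(chunk)), chunk, barcodes):
            parent = sid.rsplit(".", 1)[0]
            cid = parent_clone[parent]
            if sid in spiked:
                mixture = (
                    (cid, 1.0 - aberrant_fraction),
                    (aberrant_chain.clone_id, aberrant_fraction, (light_cc,)),
                )
            else:
                mixture = ((cid, 1.0),)
            wells.append(WellSpec(wid, sid, bc, mixture))
            sheet_rows.append({"plate_id": f"plate{p + 1}", "well_id": wid, "sample_id": sid, "barcode": bc})
        plate = PlateSpec(
            plate_id=f"plate{p + 1}",
            wells=tuple(wells),
            error_rate=error_rate,
            reads_per_well=reads_per_well,
            seed=(seed * 1009 + p) % (2**31),
        )
        plates.append(plate)
        r1, r2, truth = generate_plate(plate, clones)
        write_fastq(r1, outdir / f"{plate.plate_id}_R1.fastq")
        write_fastq(r2, outdir / f"{plate.plate_id}_R2.fastq")
        truths.append(truth)

    truth = pd.concat(truths, ignore_index=True)
    sample_sheet = pd.DataFrame(sheet_rows)
    sample_sheet.to_csv(outdir / "samples.csv", index=False)
    truth[["sample_id", "chain", "sequence", "fraction"]].to_csv(outdir / "truth.tsv", sep="\t", index=False)

    with open(outdir / "primers.fasta", "w") as fh:
        for cc in chain_classes:
            fh.write(f">{cc}|const_{cc.lower()}\n{DEFAULT_PRIMERS[cc]}\n")
    (outdir / "tso.txt").write_text(DEFAULT_TSO + "\n")

    region_rows = []
    for clone in clones.values():
        for cc, ct in clone.chains.items():
            row = {"clone_id": clone.clone_id, "chain": cc}
            row.update({r: ct.regions[r] for r in REGION_NAMES})
            region_rows.append(row)
    pd.DataFrame(region_rows).to_csv(outdir / "clone_regions.tsv", sep="\t", index=False)

    return RunTruth(
        outdir=outdir,
        plates=plates,
        clones=clones,
        truth=truth,
        sample_sheet=sample_sheet,
        aberrant_clone_id=aberrant_chain.clone_id if aberrant_chain is not None else None,
    )
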