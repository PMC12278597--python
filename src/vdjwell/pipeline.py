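"""End-to-end orchestration: FASTQ pairs -> cleaned reads -> ASVs -> annotated
chain bins -> scored entries -> high-confidence pairs."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from vdjwell.annotate import (
    AnnotationBackend,
    annotate_nt,
    asv_support_filter,
    bin_by_aa,
    filter_zero_length_regions,
    extract_reported_nt,
    MIN_SUPPORT,
)
from vdjwell.chains import REGION_NAMES
from vdjwell.denoise import ABUNDANCE_RATIO, MAX_HAMMING, denoise, derep
from vdjwell.reads import MIN_MERGED_LEN, QUALITY_FLOOR, CascadeResult, ReadRecord, StageLog, clean_cascade
from vdjwell.scoring import (
    ScoredEntry,
    ScoringParams,
    asv_score,
    complexity,
    count_replicates,
    match_score,
    parse_sample_id,
    percentile,
    remove_aberrant_light_chains,
    select_high_confidence_pairs,
    total_score,
)

WellKey = tuple[str, str]  # (plate_id, well_id)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path, plate_id: str = "") -> list[tuple[ReadRecord, ReadRecord]]:
    """Load a pair of (optionally gzipped) FASTQ files into read-pair records."""

    def load(path):
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        out = []
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline().rstrip("\n")
                if not header:
                    break
                seq = fh.readline().rstrip("\n")
                fh.readline()
                qual = fh.readline().rstrip("\n")
                out.append(
                    ReadRecord(
                        seq=seq,
                        qual=tuple(ord(c) - 33 for c in qual),
                        read_id=header[1:].split()[0],
                        plate=plate_id,
                    )
                )
        return out

    r1, r2 = load(r1_path), load(r2_path)
    if len(r1) != len(r2):
        raise ValueError("R1 and R2 files hold different read counts")
    return list(zip(r1, r2))


def read_primer_fasta(path: str | Path) -> dict[str, list[str]]:
    """Primer FASTA with headers ``>CHAINCLASS|name``; cocktails allowed."""
    table: dict[str, list[str]] = {}
    chain = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            chain = line[1:].split("|")[0]
        else:
            table.setdefault(chain, []).append(line)
    return table


@dataclass
class RunResult:
    """Everything one processed run produces, in memory."""

    stage_logs: dict[str, list[StageLog]]  # plate_id -> logs
    sample_by_well: dict[WellKey, str]
    well_chain_totals: dict[tuple[WellKey, str], int]
    asvs: dict[tuple[WellKey, str], list] = field(default_factory=dict)
    bins: dict[tuple[WellKey, str], list] = field(default_factory=dict)
    entries: list[ScoredEntry] = field(default_factory=list)
    pairs: list[tuple[ScoredEntry, ScoredEntry]] = field(default_factory=list)
    complexity_by_sample: dict[str, int] = field(default_factory=dict)

    def asv_table(self) -> pd.DataFrame:
        rows = []
        for ((plate, well), chain), asvs in sorted(self.asvs.items()):
            for a in asvs:
                rows.append(
                    {
                        "plate_id": plate,
                        "well_id": well,
                        "sample_id": self.sample_by_well[(plate, well)],
                        "chain": chain,
                        "sequence": a.seq,
                        "count": a.count,
                        "support_fraction": a.support_fraction,
                    }
                )
        return pd.DataFrame(rows)

    def scored_table(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {
                "sample_id": e.sample.raw,
                "plate_id": e.well_key[0],
                "well_id": e.well_key[1],
                "chain": e.chain_class,
                "aa": e.aa_key[1],
                "nt_reported": e.nt_reported,
                "count": e.count,
                "asv_score": e.asv_score,
                "br": e.br,
                "tr": e.tr,
                "total_replicates": e.total_replicates,
                "match_score": e.match_score,
                "total_score": e.total_score,
                "percentile": e.percentile,
                "aberrant_flag": e.aberrant_flag,
                "high_confidence": e.high_confidence,
            }
            for r in REGION_NAMES:
                row[r] = e.regions.get(r, "")
            rows.append(row)
        return pd.DataFrame(rows)

    def stage_log_table(self) -> pd.DataFrame:
        rows = []
        for plate, logs in sorted(self.stage_logs.items()):
            for log in logs:
                rows.append(
                    {
                        "plate_id": plate,
                        "stage": log.stage,
                        "reads_in": log.reads_in,
                        "reads_out": log.reads_out,
                        "reads_discarded": log.reads_discarded,
                    }
                )
        return pd.DataFrame(rows)


def process_plate(
    plate_id: str,
    pairs,
    barcode_table: dict[str, str],
    primer_table,
    tso: str,
    min_len: int = MIN_MERGED_LEN,
    q_min: int = QUALITY_FLOOR,
    max_hamming: int = MAX_HAMMING,
    abundance_ratio: float = ABUNDANCE_RATIO,
) -> tuple[CascadeResult, dict[tuple[str, str], list]]:
    """Clean one plate and call ASVs per well+chain."""
    cascade = clean_cascade(pairs, barcode_table, primer_table, tso, q_min=q_min, min_len=min_len)
    asvs = {}
    for (well, chain), reads in sorted(cascade.by_well_chain.items()):
        dr = derep(r.seq for r in reads)
        asvs[(well, chain)] = denoise(dr, max_hamming, abundance_ratio, well=well, chain=chain)
    return cascade, asvs


def process_run(
    run_dir: str | Path,
    backend: AnnotationBackend,
    min_support: float = MIN_SUPPORT,
    min_len: int = MIN_MERGED_LEN,
    q_min: int = QUALITY_FLOOR,
) -> RunResult:
    """Process a simulated-run directory (as written by ``generate_run``)."""
    run_dir = Path(run_dir)
    sheet = pd.read_csv(run_dir / "samples.csv")
    primer_table = read_primer_fasta(run_dir / "primers.fasta")
    tso = (run_dir / "tso.txt").read_text().strip()

    stage_logs: dict[str, list[StageLog]] = {}
    sample_by_well: dict[WellKey, str] = {}
    totals: dict[tuple[WellKey, str], int] = {}
    all_asvs: dict[tuple[WellKey, str], list] = {}
    all_bins: dict[tuple[WellKey, str], list] = {}

    for plate_id, plate_sheet in sheet.groupby("plate_id"):
        barcode_table = dict(zip(plate_sheet["well_id"], plate_sheet["barcode"]))
        for _, row in plate_sheet.iterrows():
            sample_by_well[(plate_id, row["well_id"])] = row["sample_id"]
        pairs = read_fastq_pairs(run_dir / f"{plate_id}_R1.fastq", run_dir / f"{plate_id}_R2.fastq", plate_id)
        cascade, asvs = process_plate(plate_id, pairs, barcode_table, primer_table, tso, min_len=min_len, q_min=q_min)
        stage_logs[plate_id] = cascade.stage_logs
        for (well, chain), asv_list in asvs.items():
            key = ((plate_id, well), chain)
            all_asvs[key] = asv_list
            total = sum(a.count for a in asv_list)
            totals[key] = total
            annotated = []
            for a in asv_list:
                ann = annotate_nt(a.seq, backend, chain)
                if ann is not None and filter_zero_length_regions(ann):
                    annotated.append((a, ann))
            bins = bin_by_aa(annotated)
            all_bins[key] = asv_support_filter(bins, total, min_support)

    return RunResult(
        stage_logs=stage_logs,
        sample_by_well=sample_by_well,
        well_chain_totals=totals,
        asvs=all_asvs,
        bins=all_bins,
    )


def score_run(result: RunResult, params: ScoringParams | None = None) -> RunResult:
    """Score every retained bin of a processed run in place.

    Replicate groups are the sample instances (wells) sharing project and
    parent; a bin's supporting instances are the wells of the group whose
    retained bins contain the same (chain class, amino acid) key.
    """
    params = params or ScoringParams()
    sample_ids = {wk: parse_sample_id(sid) for wk, sid in result.sample_by_well.items()}

    groups: dict[tuple[str, str], list[WellKey]] = {}
    for wk, sid in sample_ids.items():
        groups.setdefault(sid.group_key, []).append(wk)
    for wells in groups.values():
        wells.sort()

    # (well, chain) -> set of aa keys present after filtering
    present: dict[WellKey, set] = {}
    for ((wk), chain), bins in result.bins.items():
        present.setdefault(wk, set()).update(b.aa_key for b in bins)

    entries: list[ScoredEntry] = []
    for (wk, chain), bins in sorted(result.bins.items()):
        sid = sample_ids[wk]
        group_wells = groups[sid.group_key]
        group_sids = [sample_ids[w] for w in group_wells]
        total = result.well_chain_totals[(wk, chain)]
        for b in bins:
            flags = [b.aa_key in present.get(w, set()) for w in group_wells]
            br, tr, total_reps = count_replicates(group_sids, flags)
            a_score = asv_score(b.total_count, total)
            m_score = match_score(br, tr, total_reps, params.nu)
            t_score = total_score(m_score, a_score, params)
            entries.append(
                ScoredEntry(
                    sample=sid,
                    chain_class=chain,
                    aa_key=b.aa_key,
                    nt_reported=extract_reported_nt(b.annotation),
                    count=b.total_count,
                    well_key=wk,
                    br=br,
                    tr=tr,
                    total_replicates=total_reps,
                    asv_score=a_score,
                    match_score=m_score,
                    total_score=t_score,
                    regions=dict(b.annotation.regions),
                )
            )

    entries = remove_aberrant_light_chains(entries, params.aberrant_prevalence)

    by_class: dict[str, list[float]] = {}
    for e in entries:
        by_class.setdefault(e.chain_class, []).append(e.total_score)
    for e in entries:
        e.percentile = percentile(e.total_score, by_class[e.chain_class])

    by_sample: dict[str, list[ScoredEntry]] = {}
    for e in entries:
        by_sample.setdefault(e.sample.raw, []).append(e)
    result.complexity_by_sample = {s: complexity(es) for s, es in sorted(by_sample.items())}

    result.entries = entries
    result.pairs = select_high_confidence_pairs(entries, params)
    return result
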