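"""Report writing and SQLite export.

Every TSV artifact opens with a schema-version comment line
(``# vdjwell-table v1``); readers reject tables with unknown versions.  The
SQLite schema mirrors the database entries a consolidated run feeds: per
sample, the chain sequences (reported nucleotide span, amino acids, FR/CDR
breakdown) and the scoring evidence (ASV/match/total score, percentile).
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path

import pandas as pd

from vdjwell.chains import REGION_NAMES
from vdjwell.pipeline import RunResult

TABLE_SCHEMA_LINE = "# vdjwell-table v1"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(TABLE_SCHEMA_LINE + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != TABLE_SCHEMA_LINE:
            raise ValueError(f"{path}: unknown table schema line {first!r}")
        return pd.read_csv(fh, sep="\t")


def write_reports(result: RunResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-plate stage logs, ASV and scored tables, the
    high-confidence pair FASTA, and a run-summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stage_logs": outdir / "stage_logs.tsv",
        "asv_table": outdir / "asv_table.tsv",
        "scored_table": outdir / "scored_table.tsv",
        "pairs_fasta": outdir / "high_confidence_pairs.fasta",
        "summary": outdir / "run_summary.json",
    }
    write_table(result.stage_log_table(), paths["stage_logs"])
    write_table(result.asv_table(), paths["asv_table"])
    write_table(result.scored_table(), paths["scored_table"])

    with open(paths["pairs_fasta"], "w") as fh:
        for vl, vh in result.pairs:
            for e in (vl, vh):
                fh.write(f">{e.sample.raw}|{e.chain_class}|{e.total_score:.3f}\n{e.nt_reported}\n")

    logs = result.stage_log_table()
    summary = {
        "reads_per_stage": {
            stage: int(sub["reads_out"].sum()) for stage, sub in logs.groupby("stage")
        },
        "input_read_pairs": int(logs.loc[logs["stage"] == "join", "reads_in"].sum()),
        "bins_per_sample": {
            sid: int(n)
            for sid, n in result.scored_table().groupby("sample_id").size().items()
        }
        if result.entries
        else {},
        "complexity_by_sample": result.complexity_by_sample,
        "n_high_confidence_pairs": len(result.pairs),
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return paths


_SCHEMA = """
CREATE TABLE IF NOT EXISTS run_metadata (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS samples (
    sample_id TEXT PRIMARY KEY,
    project TEXT, parent TEXT, subclone TEXT,
    complexity INTEGER
);
CREATE TABLE IF NOT EXISTS chains (
    chain_id INTEGER PRIMARY KEY AUTOINCREMENT,
    sample_id TEXT REFERENCES samples(sample_id),
    plate_id TEXT, well_id TEXT,
    chain_class TEXT, aa TEXT, nt_reported TEXT,
    FR1 TEXT, CDR1 TEXT, FR2 TEXT, CDR2 TEXT, FR3 TEXT, CDR3 TEXT, FR4 TEXT
);
CREATE TABLE IF NOT EXISTS scores (
    chain_id INTEGER REFERENCES chains(chain_id),
    read_count INTEGER, asv_score REAL, br INTEGER, tr INTEGER,
    total_replicates INTEGER, match_score REAL, total_score REAL,
    percentile REAL, aberrant_flag INTEGER, high_confidence INTEGER
);
"""


def export_sqlite(result: RunResult, path: str | Path, run_meta: dict | None = None) -> None:
    """Export a scored run to SQLite; re-export over the same path is
    idempotent (tables are rebuilt)."""
    con = sqlite3.connect(path)
    try:
        con.executescript("DROP TABLE IF EXISTS scores; DROP TABLE IF EXISTS chains; DROP TABLE IF EXISTS samples; DROP TABLE IF EXISTS run_metadata;")
        con.executescript(_SCHEMA)
        for key, value in (run_meta or {}).items():
            con.execute("INSERT INTO run_metadata VALUES (?, ?)", (key, str(value)))
        seen = set()
        for e in sorted(result.entries, key=lambda e: (e.sample.raw, e.well_key, e.chain_class, e.aa_key)):
            if e.sample.raw not in seen:
                seen.add(e.sample.raw)
                con.execute(
                    "INSERT INTO samples VALUES (?, ?, ?, ?, ?)",
                    (
                        e.sample.raw,
                        e.sample.project,
                        e.sample.parent,
                        e.sample.subclone,
                        result.complexity_by_sample.get(e.sample.raw),
                    ),
                )
            cur = con.execute(
                "INSERT INTO chains (sample_id, plate_id, well_id, chain_class, aa, nt_reported, "
                "FR1, CDR1, FR2, CDR2, FR3, CDR3, FR4) VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)",
                (e.sample.raw, e.well_key[0], e.well_key[1], e.chain_class, e.aa_key[1], e.nt_reported)
                + tuple(e.regions.get(r, "") for r in REGION_NAMES),
            )
            con.execute(
                "INSERT INTO scores VALUES (?,?,?,?,?,?,?,?,?,?,?)",
                (
                    cur.lastrowid,
                    e.count,
                    e.asv_score,
                    e.br,
                    e.tr,
                    e.total_replicates,
                    e.match_score,
                    e.total_score,
                    e.percentile,
                    int(e.aberrant_flag),
                    int(e.high_confidence),
                ),
            )
        con.commit()
    finally:
        con.close()


def read_sqlite_scores(path: str | Path) -> pd.DataFrame:
    con = sqlite3.connect(path)
    try:
        return pd.read_sql_query(
            "SELECT c.sample_id, c.chain_class, c.aa, c.nt_reported, s.* FROM chains c JOIN scores s USING (chain_id)",
            con,
        )
    finally:
        con.close()
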