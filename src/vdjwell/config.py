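"""Run configuration loading and validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from vdjwell.annotate import MIN_SUPPORT
from vdjwell.reads import MIN_MERGED_LEN, QUALITY_FLOOR
from vdjwell.scoring import ScoringParams


class ConfigError(ValueError):
    """All validation problems of a config file, reported together."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid run configuration:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass
class RunConfig:
    run_dir: Path
    out_dir: Path
    backend: str = "motif"
    min_len: int = MIN_MERGED_LEN
    q_min: int = QUALITY_FLOOR
    min_support: float = MIN_SUPPORT
    scoring: ScoringParams = field(default_factory=ScoringParams)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config, inject defaults, and validate.

    Validation problems are aggregated into one :class:`ConfigError` rather
    than reported one at a time.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    problems: list[str] = []

    run_dir = Path(raw.get("run_dir", "."))
    if not run_dir.exists():
        problems.append(f"run_dir does not exist: {run_dir}")
    else:
        for name in ("samples.csv", "primers.fasta", "tso.txt"):
            if not (run_dir / name).exists():
                problems.append(f"missing input file: {run_dir / name}")

    min_len = int(raw.get("min_len", MIN_MERGED_LEN))
    if min_len < 1:
        problems.append(f"min_len must be >= 1, got {min_len}")
    q_min = int(raw.get("q_min", QUALITY_FLOOR))
    if not 0 <= q_min <= 60:
        problems.append(f"q_min must lie in [0, 60], got {q_min}")
    min_support = float(raw.get("min_support", MIN_SUPPORT))
    if not 0.0 <= min_support <= 1.0:
        problems.append(f"min_support must lie in [0, 1], got {min_support}")

    scoring_raw = raw.get("scoring", {})
    scoring = ScoringParams()
    try:
        scoring = ScoringParams(**scoring_raw)
    except (TypeError, ValueError) as exc:
        problems.append(f"scoring parameters: {exc}")

    backend = raw.get("backend", "motif")
    if backend not in ("table", "motif"):
        problems.append(f"unknown annotation backend: {backend!r}")

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        run_dir=run_dir,
        out_dir=Path(raw.get("out_dir", run_dir / "out")),
        backend=backend,
        min_len=min_len,
        q_min=q_min,
        min_support=min_support,
        scoring=scoring,
        seed=int(raw.get("seed", 0)),
    )
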