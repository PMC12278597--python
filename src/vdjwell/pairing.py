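"""Heavy/light pairing classification: high-confidence vs scrambled pairs.

The training set mirrors how a consolidated run is turned into labelled
data: each high-confidence light/heavy pair is a positive, and a seeded
derangement of the heavy-chain assignments over the same light chains gives
the scrambled negatives.  Because negatives reuse the positive chains,
cross-validation is grouped by chain identity (connected components of
shared sequences) so no amino-acid sequence appears in both a training and
a held-out fold.

Features are chain-derived only -- region lengths, chain-class indicators,
length differences, and a pluggable germline-similarity stub -- never the
replicate-based star score, so the classifier provides evidence independent
of across-sample support.
"""

from __future__ import annotations

import pickle
import random
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from vdjwell.chains import CHAIN_CLASSES, REGION_NAMES

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ChainSummary:
    """The per-chain information the featurizer consumes."""

    aa: str
    chain_class: str
    region_lengths: dict[str, int]
    germline_identity: float = 0.0


@dataclass
class PairCandidate:
    vl: ChainSummary
    vh: ChainSummary
    label: str = "unknown"  # high_confidence | scrambled | unknown
    features: dict[str, float] = field(default_factory=dict)
    probability: float | None = None


class SyntheticGermlineProvider:
    """Germline-similarity stub scoring identity against a sequence pool.

    Stands in for germline assignment tools: the similarity of a chain to
    its nearest pool member (here, the simulator's clone domains) plays the
    role of percent identity to the assigned germline.
    """

    def __init__(self, pool: Sequence[str]):
        if not pool:
            raise ValueError("germline pool must be non-empty")
        self.pool = list(pool)

    def identity(self, aa: str) -> float:
        return max(SequenceMatcher(None, aa, g).ratio() for g in self.pool)


def summarize_chain(annotation, germline_provider=None) -> ChainSummary:
    """Build a :class:`ChainSummary` from an :class:`AnnotatedChain`."""
    aa = annotation.domain_aa
    return ChainSummary(
        aa=aa,
        chain_class=annotation.chain_class,
        region_lengths={r: len(annotation.regions[r]) for r in REGION_NAMES},
        germline_identity=germline_provider.identity(aa) if germline_provider else 0.0,
    )


def scramble_pairs(pairs: Sequence[PairCandidate], seed: int) -> list[PairCandidate]:
    """Deranged heavy-chain reassignment over the light chains of ``pairs``.

    The derangement is built as a product of disjoint transpositions over a
    seeded shuffle (one 3-cycle absorbs the leftover when the count is odd),
    so no light chain keeps its original heavy partner and the
    positive+scrambled candidate graph decomposes into small connected
    components -- a prerequisite for leakage-free grouped cross-validation.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs to build a derangement")
    rng = random.Random(seed)
    order = list(range(n))
    rng.shuffle(order)
    target = list(range(n))  # target[i] = index whose VH pair i receives
    i = 0
    while i + 1 < len(order):
        a, b = order[i], order[i + 1]
        target[a], target[b] = b, a
        i += 2
    if n % 2 == 1:
        # rotate the last shuffled trio so the odd one out moves too
        a, b, c = order[-3], order[-2], order[-1]
        target[a], target[b], target[c] = b, c, a
    out = []
    for i, p in enumerate(pairs):
        assert target[i] != i
        out.append(PairCandidate(vl=p.vl, vh=pairs[target[i]].vh, label="scrambled"))
    return out


FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"vl_{r.lower()}_len" for r in REGION_NAMES]
    + [f"vh_{r.lower()}_len" for r in REGION_NAMES]
    + [f"vl_is_{c}" for c in CHAIN_CLASSES]
    + [f"vh_is_{c}" for c in CHAIN_CLASSES]
    + ["vl_germline_identity", "vh_germline_identity"]
    + ["cdr3_len_diff", "domain_len_diff"]
)


def featurize_pair(vl: ChainSummary, vh: ChainSummary) -> dict[str, float]:
    """Fixed-length, order-stable feature vector for one light/heavy pair."""
    if vl is None or vh is None:
        raise ValueError("both chains must carry an annotation to featurize")
    f: dict[str, float] = {}
    for prefix, ch in (("vl", vl), ("vh", vh)):
        for r in REGION_NAMES:
            f[f"{prefix}_{r.lower()}_len"] = float(ch.region_lengths[r])
    for c in CHAIN_CLASSES:
        f[f"vl_is_{c}"] = 1.0 if vl.chain_class == c else 0.0
        f[f"vh_is_{c}"] = 1.0 if vh.chain_class == c else 0.0
    f["vl_germline_identity"] = vl.germline_identity
    f["vh_germline_identity"] = vh.germline_identity
    f["cdr3_len_diff"] = f["vh_cdr3_len"] - f["vl_cdr3_len"]
    f["domain_len_diff"] = float(sum(vh.region_lengths.values()) - sum(vl.region_lengths.values()))
    return {name: f[name] for name in FEATURE_NAMES}


def chain_groups(candidates: Sequence[PairCandidate]) -> np.ndarray:
    """Connected-component group ids over shared chain sequences.

    Two candidates sharing any amino-acid sequence (light or heavy) land in
    the same group, so grouped CV never splits a sequence across folds.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    for c in candidates:
        union("L:" + c.vl.aa, "H:" + c.vh.aa)
    roots = {}
    out = []
    for c in candidates:
        r = find("L:" + c.vl.aa)
        out.append(roots.setdefault(r, len(roots)))
    return np.asarray(out)


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float
    folds: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "folds": self.folds,
            "seed": self.seed,
        }


def train_eval(
    candidates: Sequence[PairCandidate], folds: int = 5, seed: int = 0
) -> tuple[EvalReport, GradientBoostingClassifier]:
    """Grouped, stratified k-fold evaluation of a gradient-boosted classifier.

    Metrics are computed on pooled held-out predictions only; the returned
    model is refit on the full data.  Deterministic for a fixed seed.
    """
    labels = {c.label for c in candidates}
    if not labels <= {"high_confidence", "scrambled"}:
        raise ValueError(f"candidates must be labelled high_confidence/scrambled, got {labels}")
    if len(labels) < 2:
        raise ValueError("training requires both classes")
    X = np.array([[ (c.features or featurize_pair(c.vl, c.vh))[n] for n in FEATURE_NAMES] for c in candidates])
    y = np.array([1 if c.label == "high_confidence" else 0 for c in candidates])
    groups = chain_groups(candidates)

    cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.zeros(len(y), dtype=int)
    prob = np.zeros(len(y))
    for train_idx, test_idx in cv.split(X, y, groups):
        clf = GradientBoostingClassifier(random_state=seed)
        clf.fit(X[train_idx], y[train_idx])
        prob[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
        pred[test_idx] = (prob[test_idx] >= 0.5).astype(int)
    for c, p in zip(candidates, prob):
        c.probability = float(p)
    report = EvalReport(
        accuracy=float(accuracy_score(y, pred)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        roc_auc=float(roc_auc_score(y, prob)),
        folds=folds,
        seed=seed,
    )
    final = GradientBoostingClassifier(random_state=seed)
    final.fit(X, y)
    return report, final


def save_model(model, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"schema_version": MODEL_SCHEMA_VERSION, "feature_names": FEATURE_NAMES, "model": model}, fh)


def load_model(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version: {payload.get('schema_version')}")
    return payload["model"]
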