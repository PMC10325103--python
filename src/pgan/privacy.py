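"""Membership-attack simulation against a shared synthetic dataset.

An attacker holding a candidate image and the released synthetic dataset
can try two things:

* **pairwise attack** — score each candidate by its minimum Euclidean
  distance to any synthetic sample (an unusually small distance suggests
  the candidate was a training member);
* **distribution attack** — count the synthetic samples inside the
  candidate's neighbourhood, the neighbour threshold being the 1st
  percentile of the pooled candidate-to-synthetic distance distribution
  (a large cluster around a candidate suggests membership).

Both run in pixel space (flattened images) and, optionally, in a 64-feature
embedding space fitted on real data. Candidates are drawn in equal thirds
from the train/validation/test splits; the attack's discriminative power is
summarized as the ROC AUC of separating train-origin from validation- or
test-origin candidates, plus cut-off curves giving the origin composition
of the most suspicious candidates. The verdict is PASS when training
members are indistinguishable from validation members under every attack.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datasets import LabeledImageSet
from .embedding import EmbeddingModel
from .metrics import binary_auc
from .synthesis import SyntheticDataset

ORIGINS = ("train", "validation", "test")
DEFAULT_LEAK_THRESHOLD = 0.6
DEFAULT_CUTOFFS = (10, 50, 100, 333)


@dataclass
class CandidateSet:
    """Images with ground-truth origin labels drawn from the real splits."""

    images: np.ndarray
    origins: np.ndarray           # str per candidate in ORIGINS
    indices: np.ndarray | None = None   # positions in the source dataset

    def __len__(self) -> int:
        return len(self.images)

    def counts(self) -> dict[str, int]:
        return {o: int((self.origins == o).sum()) for o in ORIGINS}


def build_candidate_set(real: LabeledImageSet, n_per_origin: int, seed: int,
                        total: int | None = None) -> CandidateSet:
    """Draw candidates uniformly without replacement from each split.

    Each origin contributes ``n_per_origin`` candidates. If ``total``
    exceeds ``3 * n_per_origin``, the remainder is assigned one extra
    candidate per origin in the order train, validation, test (so
    ``n_per_origin=333, total=1000`` gives counts (334, 333, 333)).
    """
    if n_per_origin < 1:
        raise ValueError("n_per_origin must be >= 1")
    counts = {o: n_per_origin for o in ORIGINS}
    if total is not None:
        extra = total - 3 * n_per_origin
        if extra < 0 or extra > 3:
            raise ValueError("total must be within 3 of 3 * n_per_origin")
        for o in ORIGINS[:extra]:
            counts[o] += 1
    rng = np.random.default_rng(seed)
    images, origins, indices = [], [], []
    for o in ORIGINS:
        mask = np.flatnonzero(real.split == o)
        if len(mask) < counts[o]:
            raise ValueError(
                f"split {o!r} has {len(mask)} samples, {counts[o]} requested")
        pick = np.sort(rng.choice(mask, size=counts[o], replace=False))
        images.append(real.images[pick])
        origins.extend([o] * counts[o])
        indices.append(pick)
    return CandidateSet(images=np.concatenate(images),
                        origins=np.array(origins, dtype=object),
                        indices=np.concatenate(indices))


@dataclass
class AttackScoreTable:
    """Per-candidate attack statistic with its ground-truth origin."""

    scores: np.ndarray
    origins: np.ndarray
    attack: str                   # "pairwise" or "distribution"
    space: str                    # "pixel" or "embedding"
    threshold: float | None = None  # neighbour threshold (distribution only)

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "origin": self.origins,
                             "attack": self.attack, "space": self.space})


def _features(images: np.ndarray, space: str,
              embedding: EmbeddingModel | None) -> np.ndarray:
    if space == "pixel":
        return np.asarray(images, dtype=np.float64).reshape(len(images), -1)
    if space == "embedding":
        if embedding is None:
            raise ValueError("embedding space requires a fitted EmbeddingModel")
        return embedding.transform(images)
    raise ValueError(f"unknown space {space!r}")


def candidate_synthetic_distances(candidates: CandidateSet,
                                  synthetic: SyntheticDataset,
                                  space: str = "pixel",
                                  embedding: EmbeddingModel | None = None,
                                  chunk: int = 128) -> np.ndarray:
    """Full (n_candidates, n_synthetic) Euclidean distance matrix."""
    if len(synthetic) == 0:
        raise ValueError("empty synthetic dataset")
    cf = _features(candidates.images, space, embedding)
    sf = _features(synthetic.images, space, embedding)
    out = np.empty((len(cf), len(sf)), dtype=np.float64)
    for i in range(0, len(cf), chunk):
        out[i:i + chunk] = cdist(cf[i:i + chunk], sf)
    return out


def pairwise_attack(candidates: CandidateSet, synthetic: SyntheticDataset,
                    space: str = "pixel",
                    embedding: EmbeddingModel | None = None,
                    distances: np.ndarray | None = None) -> AttackScoreTable:
    """Minimum candidate-to-synthetic distance per candidate."""
    if distances is None:
        distances = candidate_synthetic_distances(candidates, synthetic,
                                                  space, embedding)
    return AttackScoreTable(scores=distances.min(axis=1),
                            origins=candidates.origins,
                            attack="pairwise", space=space)


def distribution_attack(candidates: CandidateSet, synthetic: SyntheticDataset,
                        space: str = "pixel",
                        embedding: EmbeddingModel | None = None,
                        percentile: float = 1.0,
                        distances: np.ndarray | None = None) -> AttackScoreTable:
    """Synthetic-neighbour count per candidate.

    The neighbour threshold is the given percentile (default 1st) of the
    pooled candidate-to-synthetic distance distribution; a synthetic sample
    is a neighbour when its distance is <= the threshold.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    if distances is None:
        distances = candidate_synthetic_distances(candidates, synthetic,
                                                  space, embedding)
    threshold = float(np.percentile(distances, percentile))
    counts = (distances <= threshold).sum(axis=1)
    return AttackScoreTable(scores=counts.astype(np.int64),
                            origins=candidates.origins,
                            attack="distribution", space=space,
                            threshold=threshold)


def attack_roc(table: AttackScoreTable, positive_origin: str = "train",
               negative_origin: str = "validation") -> float:
    """AUC of identifying ``positive_origin`` candidates from the scores.

    Small distances rank positive for pairwise attacks; large neighbour
    counts rank positive for distribution attacks.
    """
    for o in (positive_origin, negative_origin):
        if not (table.origins == o).any():
            raise ValueError(f"origin {o!r} absent from the score table")
    mask = np.isin(table.origins, (positive_origin, negative_origin))
    scores = table.scores[mask].astype(float)
    if table.attack == "pairwise":
        scores = -scores
    positive = table.origins[mask] == positive_origin
    return binary_auc(scores, positive)


def cutoff_analysis(table: AttackScoreTable,
                    cutoffs: list[int]) -> pd.DataFrame:
    """Origin proportions among the top-``cutoff`` most suspicious candidates.

    "Most suspicious" means smallest distances (pairwise) or largest
    neighbour counts (distribution); ties are broken by candidate index.
    """
    if len(cutoffs) == 0:
        raise ValueError("cutoffs must be non-empty")
    if max(cutoffs) > len(table):
        raise ValueError("cutoff exceeds table size")
    key = table.scores if table.attack == "pairwise" else -table.scores.astype(float)
    order = np.argsort(key, kind="stable")
    rows = []
    for c in cutoffs:
        flagged = table.origins[order[:c]]
        row = {"cutoff": c}
        for o in ORIGINS:
            row[o] = float((flagged == o).sum() / c) if c else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PrivacyReport:
    """Evidence bundle and verdict of the membership-attack simulation."""

    tables: dict[tuple[str, str], AttackScoreTable]
    aucs: dict[tuple[str, str, str], float]   # (attack, space, neg origin) -> AUC
    cutoff_tables: dict[tuple[str, str], pd.DataFrame]
    leak_threshold: float
    verdict: str = field(init=False)
    offending: list[tuple[str, str, str]] = field(init=False)

    def __post_init__(self) -> None:
        self.offending = [k for k, v in self.aucs.items()
                          if k[2] == "validation" and v >= self.leak_threshold]
        self.verdict = "FAIL" if self.offending else "PASS"

    def summary(self) -> str:
        lines = ["Privacy attack simulation",
                 "=" * 48,
                 f"verdict: {self.verdict} "
                 f"(leak threshold: train-vs-validation AUC >= {self.leak_threshold})"]
        for (attack, space, neg), v in sorted(self.aucs.items()):
            flag = "  <-- leak" if (attack, space, neg) in self.offending else ""
            lines.append(f"{attack:>12} attack, {space:>9} space, "
                         f"train vs {neg:<10} AUC = {v:.3f}{flag}")
        for (attack, space), df in self.cutoff_tables.items():
            lines.append(f"cut-off origin proportions ({attack}, {space}):")
            lines.append(df.to_string(index=False,
                                      float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "verdict": self.verdict,
            "leak_threshold": self.leak_threshold,
            "aucs": {f"{a}/{s}/train_vs_{n}": v
                     for (a, s, n), v in self.aucs.items()},
            "cutoffs": {f"{a}/{s}": df.to_dict(orient="records")
                        for (a, s), df in self.cutoff_tables.items()},
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    def save_score_tables(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (attack, space), table in self.tables.items():
            table.to_frame().to_csv(directory / f"scores_{attack}_{space}.csv",
                                    index=False)


class PrivacyAudit:
    """Run the full attack battery against a released synthetic dataset."""

    def __init__(self, real: LabeledImageSet, synthetic: SyntheticDataset,
                 embedding: EmbeddingModel | None = None,
                 n_per_origin: int = 333, total: int | None = 1000,
                 percentile: float = 1.0,
                 leak_threshold: float = DEFAULT_LEAK_THRESHOLD,
                 cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS, seed: int = 0):
        if len(synthetic) == 0:
            raise ValueError("empty synthetic dataset")
        self.real = real
        self.synthetic = synthetic
        self.embedding = embedding
        self.n_per_origin = n_per_origin
        self.total = total
        self.percentile = percentile
        self.leak_threshold = leak_threshold
        self.cutoffs = cutoffs
        self.seed = seed

    def run(self, candidates: CandidateSet | None = None) -> PrivacyReport:
        if candidates is None:
            candidates = build_candidate_set(self.real, self.n_per_origin,
                                             self.seed, total=self.total)
        spaces = ["pixel"] + (["embedding"] if self.embedding is not None else [])
        tables: dict[tuple[str, str], AttackScoreTable] = {}
        aucs: dict[tuple[str, str, str], float] = {}
        cutoff_tables: dict[tuple[str, str], pd.DataFrame] = {}
        cutoffs = [c for c in self.cutoffs if c <= len(candidates)]
        for space in spaces:
            dist = candidate_synthetic_distances(candidates, self.synthetic,
                                                 space, self.embedding)
            tables[("pairwise", space)] = pairwise_attack(
                candidates, self.synthetic, space, self.embedding, distances=dist)
            tables[("distribution", space)] = distribution_attack(
                candidates, self.synthetic, space, self.embedding,
                percentile=self.percentile, distances=dist)
            for attack in ("pairwise", "distribution"):
                t = tables[(attack, space)]
                for neg in ("validation", "test"):
                    aucs[(attack, space, neg)] = attack_roc(t, "train", neg)
                if cutoffs:
                    cutoff_tables[(attack, space)] = cutoff_analysis(t, cutoffs)
        return PrivacyReport(tables=tables, aucs=aucs,
                             cutoff_tables=cutoff_tables,
                             leak_threshold=self.leak_threshold)
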