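"""Local read-across predictor (lazar-style k-nearest-neighbor).

For a query structure the engine searches the training database for
neighbors above a similarity threshold, excludes database entries with the
query's own canonical structure, and predicts by a similarity-weighted
majority vote over the neighbors' experimental outcomes:

    p_c = sum(sim_n for neighbors of class c) / sum(sim_n over all neighbors)

A tiered applicability domain governs confidence: neighbors are first
sought at a high threshold (high-confidence prediction); if that fails the
search is repeated at a low threshold and the prediction is flagged
low-confidence; if both fail, the engine abstains.  Contradictory training
compounds contribute one vote per retained measurement.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import MUTAGENIC, NON_MUTAGENIC
from .dataset import MutagenicityDataset
from .similarity import cosine, tanimoto


@dataclass(frozen=True)
class TierPolicy:
    """High/low similarity thresholds of the tiered applicability domain."""

    high: float
    low: float

    def __post_init__(self) -> None:
        if not (self.high > self.low > 0):
            raise ValueError("tier thresholds must satisfy high > low > 0")


#: Default tiers: fingerprint/Tanimoto kernel.
MP2D_TIERS = TierPolicy(high=0.5, low=0.2)
#: Default tiers: descriptor/cosine kernel.
CDK_TIERS = TierPolicy(high=0.9, low=0.7)


@dataclass(frozen=True)
class Neighbor:
    key: str
    similarity: float
    outcome: str


@dataclass
class LazarPrediction:
    query_key: str | None
    predicted: str | None
    p_mutagenic: float | None
    p_nonmutagenic: float | None
    confidence: str  # "high" | "low" | "none"
    neighbors: list[Neighbor] = field(default_factory=list)
    tier_used: float | None = None
    reason: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def weighted_vote(neighbors: Sequence[Neighbor]) -> tuple[float, float]:
    """Class probabilities from the similarity-weighted neighbor vote.

    Returns ``(p_mutagenic, p_nonmutagenic)``; the two sum to 1.  Raises on
    an empty neighbor list (the caller's tier logic handles that case).
    """
    if not neighbors:
        raise ValueError("weighted vote requires at least one neighbor")
    if any(n.similarity <= 0 for n in neighbors):
        raise ValueError("neighbor similarities must be positive")
    total = sum(n.similarity for n in neighbors)
    s_mut = sum(n.similarity for n in neighbors if n.outcome == MUTAGENIC)
    return s_mut / total, (total - s_mut) / total


class LazarModel:
    """Read-across database: one representation per unique structure plus
    one vote per retained measurement.

    ``kernel`` is ``"tanimoto"`` (representations are feature sets) or
    ``"cosine"`` (representations are numeric vectors).
    """

    def __init__(
        self,
        representations: Mapping[str, object],
        measurements: Sequence[tuple[str, str]],
        kernel: str = "tanimoto",
        tiers: TierPolicy | None = None,
        min_neighbors: int = 1,
    ):
        if kernel not in ("tanimoto", "cosine"):
            raise ValueError(f"unknown kernel: {kernel!r}")
        missing = {k for k, _ in measurements} - set(representations)
        if missing:
            raise ValueError(f"measurements without representation: {sorted(missing)[:3]}")
        self.representations = dict(representations)
        self.measurements = list(measurements)
        self.kernel = kernel
        self.tiers = tiers or (MP2D_TIERS if kernel == "tanimoto" else CDK_TIERS)
        self.min_neighbors = min_neighbors
        self._sim = tanimoto if kernel == "tanimoto" else cosine

    @classmethod
    def from_dataset(
        cls,
        dataset: MutagenicityDataset,
        representations: Mapping[str, object],
        kernel: str = "tanimoto",
        tiers: TierPolicy | None = None,
        min_neighbors: int = 1,
    ) -> "LazarModel":
        measurements = list(dataset.measurement_rows())
        reps = {k: representations[k] for k, _ in measurements}
        return cls(reps, measurements, kernel=kernel, tiers=tiers, min_neighbors=min_neighbors)

    def find_neighbors(
        self, query_repr, threshold: float, exclude_key: str | None = None
    ) -> list[Neighbor]:
        """All training measurements with similarity >= threshold, excluding
        entries whose canonical key equals the query's.  Sorted by
        descending similarity, ties broken by key."""
        sims: dict[str, float] = {}
        neighbors = []
        for key, outcome in self.measurements:
            if exclude_key is not None and key == exclude_key:
                continue
            if key not in sims:
                sims[key] = self._sim(query_repr, self.representations[key])
            if sims[key] >= threshold:
                neighbors.append(Neighbor(key, sims[key], outcome))
        neighbors.sort(key=lambda n: (-n.similarity, n.key, n.outcome))
        return neighbors

    def _try_tier(
        self, query_repr, threshold: float, exclude_key: str | None
    ) -> tuple[list[Neighbor], tuple[float, float] | None, str | None]:
        neighbors = self.find_neighbors(query_repr, threshold, exclude_key)
        if len(neighbors) < self.min_neighbors:
            return neighbors, None, "no neighbors above threshold"
        if any(n.similarity <= 0 for n in neighbors):
            return neighbors, None, "non-positive neighbor similarity"
        probs = weighted_vote(neighbors)
        if probs[0] == probs[1]:
            # Tied vote: the class argmax is undefined; abstention is the
            # conservative read-across outcome, so the tier fails and the
            # next (wider) tier may break the tie with more neighbors.
            return neighbors, None, "tie"
        return neighbors, probs, None

    def predict(self, query_repr, query_key: str | None = None) -> LazarPrediction:
        """Tiered prediction: high threshold first, low on failure, abstain
        if both fail."""
        last_reason = None
        for threshold, confidence in (
            (self.tiers.high, "high"),
            (self.tiers.low, "low"),
        ):
            neighbors, probs, reason = self._try_tier(query_repr, threshold, query_key)
            if probs is not None:
                p_mut, p_non = probs
                predicted = MUTAGENIC if p_mut > p_non else NON_MUTAGENIC
                return LazarPrediction(
                    query_key=query_key,
                    predicted=predicted,
                    p_mutagenic=p_mut,
                    p_nonmutagenic=p_non,
                    confidence=confidence,
                    neighbors=neighbors,
                    tier_used=threshold,
                )
            last_reason = reason
        return LazarPrediction(
            query_key=query_key,
            predicted=None,
            p_mutagenic=None,
            p_nonmutagenic=None,
            confidence="none",
            neighbors=[],
            tier_used=None,
            reason=last_reason,
        )

    def predict_smiles_batch(
        self, representations: Mapping[str, object]
    ) -> list[LazarPrediction]:
        return [self.predict(rep, query_key=key) for key, rep in representations.items()]


def write_predictions_csv(
    predictions: Sequence[LazarPrediction], path: str | Path
) -> None:
    """Prediction report:
    ``key,predicted,p_mutagenic,confidence,n_neighbors,max_similarity``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["key", "predicted", "p_mutagenic", "confidence", "n_neighbors", "max_similarity"]
        )
        for p in predictions:
            writer.writerow(
                [
                    p.query_key,
                    p.predicted or "",
                    "" if p.p_mutagenic is None else f"{p.p_mutagenic:.6f}",
                    p.confidence,
                    len(p.neighbors),
                    f"{p.neighbors[0].similarity:.6f}" if p.neighbors else "",
                ]
            )


def write_predictions_json(
    predictions: Sequence[LazarPrediction], path: str | Path
) -> None:
    """Full rationale export: every prediction with its neighbor list."""
    Path(path).write_text(
        json.dumps([p.to_dict() for p in predictions], indent=2, default=float)
    )
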