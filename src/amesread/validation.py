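"""10-fold crossvalidation harness and the confusion-matrix metric panel.

Folds are drawn over unique structures so contradictory duplicates never
straddle folds.  The read-across driver scores every held-out measurement
and may abstain (tiered applicability domain); the global-model driver
excludes contradictory compounds and predicts everything.  Reports carry
per-fold and pooled confusion matrices; accuracy/TPR/TNR/PPV/NPV are
computed from pooled counts and reported as percentages, with undefined
metrics (zero denominator) reported as None rather than 0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import MUTAGENIC, NON_MUTAGENIC
from .baselines import ModelSpec, train
from .dataset import MutagenicityDataset, drop_for_descriptor_path
from .fingerprints import expand_to_matrix
from .lazar import LazarModel, TierPolicy
from .preprocessing import apply as apply_preprocess
from .preprocessing import fit_nzv_corr_scale, fit_quantile_uniform


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    def add_prediction(self, actual: str, predicted: str) -> None:
        if actual == MUTAGENIC:
            if predicted == MUTAGENIC:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if predicted == MUTAGENIC:
                self.fp += 1
            else:
                self.tn += 1


def _pct(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, TPR (sensitivity), TNR (specificity), PPV, NPV — as
    percentages; None where the denominator is zero."""
    return {
        "accuracy": _pct(cm.tp + cm.tn, cm.total),
        "tpr": _pct(cm.tp, cm.tp + cm.fn),
        "tnr": _pct(cm.tn, cm.tn + cm.fp),
        "ppv": _pct(cm.tp, cm.tp + cm.fp),
        "npv": _pct(cm.tn, cm.tn + cm.fn),
    }


def roc_point(cm: ConfusionMatrix) -> tuple[float, float]:
    """(false positive rate, true positive rate) in [0,1]^2."""
    tnr = cm.tn / (cm.tn + cm.fp)
    tpr = cm.tp / (cm.tp + cm.fn)
    return 1.0 - tnr, tpr


def mcnemar(predicted: Sequence[int], actual: Sequence[int]) -> tuple[float, float]:
    """McNemar's test of paired classifier-vs-experiment concordance.

    Discordant counts b (predicted positive, observed negative) and c
    (predicted negative, observed positive) drive the test: exact binomial
    when b + c < 25, continuity-corrected chi-squared otherwise.  Returns
    ``(statistic, two_sided_p)``; b + c = 0 gives p = 1 by convention.
    """
    predicted = np.asarray(predicted, dtype=int)
    actual = np.asarray(actual, dtype=int)
    if predicted.shape != actual.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum((predicted == 1) & (actual == 0)))
    c = int(np.sum((predicted == 0) & (actual == 1)))
    n = b + c
    if n == 0:
        return 0.0, 1.0
    if n < 25:
        statistic = float(min(b, c))
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return statistic, float(p)
    statistic = (abs(b - c) - 1) ** 2 / n
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def kfold_split(keys: Sequence[str], k: int = 10, seed: int = 0) -> list[list[str]]:
    """Partition keys into k folds of near-equal size (differ by <= 1),
    deterministic given the seed."""
    keys = list(keys)
    if k > len(keys):
        raise ValueError(f"cannot make {k} folds from {len(keys)} keys")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    return [[keys[i] for i in chunk] for chunk in np.array_split(order, k)]


@dataclass
class PredictionOutcome:
    """One scored held-out measurement."""

    key: str
    fold: int
    actual: str
    predicted: str | None
    p_mutagenic: float | None
    confidence: str  # "high" | "low" | "none" (global models: "high")


@dataclass
class CVReport:
    """Per-fold and pooled confusion matrices plus the metric panel."""

    model: str
    per_fold: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    n_predictions: int
    n_total: int

    @property
    def panel(self) -> dict[str, float | None]:
        return metrics(self.pooled)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "per_fold": [asdict(cm) for cm in self.per_fold],
            "pooled": asdict(self.pooled),
            "metrics": self.panel,
            "roc_point": roc_point(self.pooled) if self.pooled.total else None,
            "n_predictions": self.n_predictions,
            "n_total": self.n_total,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def build_report(
    rows: Sequence[PredictionOutcome], model: str, confidence: str | None = None
) -> CVReport:
    """Reduce prediction rows to a CVReport.

    ``confidence="high"`` restricts to high-confidence predictions (the
    lazar-HC view); None keeps every non-abstained prediction (lazar-all /
    global models).  Abstentions count toward n_total only.
    """
    folds = sorted({r.fold for r in rows})
    per_fold = []
    for f in folds:
        cm = ConfusionMatrix()
        for r in rows:
            if r.fold != f or r.predicted is None:
                continue
            if confidence is not None and r.confidence != confidence:
                continue
            cm.add_prediction(r.actual, r.predicted)
        per_fold.append(cm)
    pooled = sum(per_fold, ConfusionMatrix())
    return CVReport(
        model=model,
        per_fold=per_fold,
        pooled=pooled,
        n_predictions=pooled.total,
        n_total=len(rows),
    )


def _labels_of(dataset: MutagenicityDataset, keys: Sequence[str]) -> np.ndarray:
    return np.array(
        [1 if dataset[k].measurements[0].outcome == MUTAGENIC else 0 for k in keys]
    )


def crossvalidate_lazar(
    dataset: MutagenicityDataset,
    fingerprints: dict | None = None,
    descriptors: pd.DataFrame | None = None,
    tiers: TierPolicy | None = None,
    k: int = 10,
    seed: int = 0,
    min_neighbors: int = 1,
) -> list[PredictionOutcome]:
    """Crossvalidate the read-across engine.

    Fingerprint path: pass ``fingerprints`` (key -> feature set); every
    measurement of every structure is scored, contradictions included.
    Descriptor path: pass ``descriptors``; contradictory compounds and
    compounds without a descriptor row are dropped, and the
    nzv/corr/center/scale preprocessing is fit on each fold's training rows
    only before cosine similarities are computed.
    """
    if (fingerprints is None) == (descriptors is None):
        raise ValueError("pass exactly one of fingerprints or descriptors")
    if descriptors is not None:
        dataset, _ = drop_for_descriptor_path(dataset, descriptors.index)
    keys = dataset.keys()
    folds = kfold_split(keys, k=k, seed=seed)
    rows: list[PredictionOutcome] = []
    for fold_idx, test_keys in enumerate(folds):
        test_set = set(test_keys)
        train_keys = [key for key in keys if key not in test_set]
        train_measurements = [
            (key, m.outcome) for key in train_keys for m in dataset[key].measurements
        ]
        if fingerprints is not None:
            reps = fingerprints
            test_reps = {key: fingerprints[key] for key in test_keys}
            kernel = "tanimoto"
        else:
            spec = fit_nzv_corr_scale(descriptors.loc[train_keys])
            transformed = apply_preprocess(spec, descriptors.loc[keys])
            reps = {key: transformed.loc[key].to_numpy() for key in keys}
            test_reps = {key: reps[key] for key in test_keys}
            kernel = "cosine"
        model = LazarModel(
            {key: reps[key] for key in train_keys},
            train_measurements,
            kernel=kernel,
            tiers=tiers,
            min_neighbors=min_neighbors,
        )
        for key in test_keys:
            pred = model.predict(test_reps[key], query_key=key)
            for m in dataset[key].measurements:
                rows.append(
                    PredictionOutcome(
                        key=key,
                        fold=fold_idx,
                        actual=m.outcome,
                        predicted=pred.predicted,
                        p_mutagenic=pred.p_mutagenic,
                        confidence=pred.confidence,
                    )
                )
    return rows


def crossvalidate_global(
    spec: ModelSpec,
    dataset: MutagenicityDataset,
    fingerprints: dict | None = None,
    descriptors: pd.DataFrame | None = None,
    k: int = 10,
    seed: int = 0,
) -> list[PredictionOutcome]:
    """Crossvalidate a global baseline family.

    Contradictory compounds are excluded (a global fit needs one label per
    structure).  Fingerprint features are expanded against a vocabulary
    built from each fold's training set only; held-out features outside it
    are dropped (intersection semantics).  Descriptor features go through
    the quantile-to-uniform map fit on the training fold.
    """
    if (fingerprints is None) == (descriptors is None):
        raise ValueError("pass exactly one of fingerprints or descriptors")
    if descriptors is not None:
        dataset, _ = drop_for_descriptor_path(dataset, descriptors.index)
    else:
        dataset, _ = drop_for_descriptor_path(dataset, dataset.keys())
    keys = dataset.keys()
    folds = kfold_split(keys, k=k, seed=seed)
    rows: list[PredictionOutcome] = []
    for fold_idx, test_keys in enumerate(folds):
        test_set = set(test_keys)
        train_keys = [key for key in keys if key not in test_set]
        if fingerprints is not None:
            x_train, vocab = expand_to_matrix({k_: fingerprints[k_] for k_ in train_keys})
            x_test, _ = expand_to_matrix(
                {k_: fingerprints[k_] for k_ in test_keys}, vocabulary=vocab
            )
        else:
            pspec = fit_quantile_uniform(descriptors.loc[train_keys])
            x_train = apply_preprocess(pspec, descriptors.loc[train_keys])
            x_test = apply_preprocess(pspec, descriptors.loc[test_keys])
        fitted = train(spec, x_train, _labels_of(dataset, train_keys))
        probs = fitted.predict_proba(x_test)
        for key, p in zip(test_keys, probs):
            predicted = MUTAGENIC if p >= 0.5 else NON_MUTAGENIC
            rows.append(
                PredictionOutcome(
                    key=key,
                    fold=fold_idx,
                    actual=dataset[key].measurements[0].outcome,
                    predicted=predicted,
                    p_mutagenic=float(p),
                    confidence="high",
                )
            )
    return rows


def write_prediction_rows_csv(
    rows: Sequence[PredictionOutcome], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["key", "fold", "actual", "predicted", "p_mutagenic", "confidence"])
        for r in rows:
            writer.writerow(
                [
                    r.key,
                    r.fold,
                    r.actual,
                    r.predicted or "",
                    "" if r.p_mutagenic is None else f"{r.p_mutagenic:.6f}",
                    r.confidence,
                ]
            )


def write_confusion_csv(report: CVReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fold", "tp", "fp", "tn", "fn"])
        for i, cm in enumerate(report.per_fold):
            writer.writerow([i, cm.tp, cm.fp, cm.tn, cm.fn])
        p = report.pooled
        writer.writerow(["pooled", p.tp, p.fp, p.tn, p.fn])
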