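"""Fit-and-apply preprocessing for numeric descriptor matrices.

Two modes, each fit on training data only and serializable to JSON:

* ``nzv_corr_scale`` — near-zero-variance filtering, pairwise-correlation
  filtering, then centering/scaling of the survivors (the read-across
  descriptor path).
* ``quantile_uniform`` — per-feature monotone map onto [0, 1] based on the
  training empirical CDF (the global-model path).

The filter constants (frequency ratio 95/5, percent-unique 10, |r| 0.90)
are the documented defaults of the caret ``preProcess`` nzv/corr filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_FREQ_CUT = 95 / 5
DEFAULT_UNIQUE_CUT = 10.0
DEFAULT_CORR_CUT = 0.90


@dataclass
class PreprocessSpec:
    """Frozen preprocessing parameters, fit on training data only."""

    mode: str  # "nzv_corr_scale" | "quantile_uniform"
    kept_features: list[str]
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    # quantile mode: per-feature sorted reference values + shared uniform grid
    quantile_tables: dict[str, list[float]] = field(default_factory=dict)
    quantile_grid: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessSpec":
        return cls(**json.loads(Path(path).read_text()))


def _near_zero_variance(
    matrix: pd.DataFrame, freq_cut: float, unique_cut: float
) -> list[str]:
    """Features to drop: (top/second frequency ratio > freq_cut AND percent
    unique < unique_cut); constant columns always drop."""
    drop = []
    n = len(matrix)
    for col in matrix.columns:
        counts = matrix[col].value_counts()
        if len(counts) == 1:
            drop.append(col)
            continue
        freq_ratio = counts.iloc[0] / counts.iloc[1]
        pct_unique = 100.0 * len(counts) / n
        if freq_ratio > freq_cut and pct_unique < unique_cut:
            drop.append(col)
    return drop


def _correlation_filter(matrix: pd.DataFrame, corr_cut: float) -> list[str]:
    """Greedy pairwise filter: visit pairs by descending |r|; within a pair
    drop the feature with the larger mean absolute correlation to all
    others.  Deterministic given column order."""
    cols = list(matrix.columns)
    corr = matrix.corr().abs().fillna(0.0)
    mean_abs = corr.mean()
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if r > corr_cut:
                pairs.append((r, a, b))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    dropped: set[str] = set()
    for _r, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        if mean_abs[a] > mean_abs[b]:
            dropped.add(a)
        elif mean_abs[b] > mean_abs[a]:
            dropped.add(b)
        else:  # tie: drop the later column
            dropped.add(b if cols.index(b) > cols.index(a) else a)
    return [c for c in cols if c in dropped]


def fit_nzv_corr_scale(
    train: pd.DataFrame,
    freq_cut: float = DEFAULT_FREQ_CUT,
    unique_cut: float = DEFAULT_UNIQUE_CUT,
    corr_cut: float = DEFAULT_CORR_CUT,
) -> PreprocessSpec:
    """Fit the nzv → corr → center/scale pipeline on a training matrix."""
    if len(train) < 2:
        raise ValueError("need at least 2 rows to fit preprocessing")
    nzv_drop = set(_near_zero_variance(train, freq_cut, unique_cut))
    survivors = [c for c in train.columns if c not in nzv_drop]
    corr_drop = set(_correlation_filter(train[survivors], corr_cut))
    kept = [c for c in survivors if c not in corr_drop]
    if not kept:
        raise ValueError("all features removed by nzv/corr filtering")
    center = train[kept].mean()
    scale = train[kept].std(ddof=1)  # R/caret convention
    if (scale <= 0).any():
        bad = scale.index[scale <= 0].tolist()
        raise ValueError(f"zero variance survived filtering: {bad}")
    return PreprocessSpec(
        mode="nzv_corr_scale",
        kept_features=kept,
        center={c: float(center[c]) for c in kept},
        scale={c: float(scale[c]) for c in kept},
    )


def fit_quantile_uniform(train: pd.DataFrame, n_quantiles: int = 1000) -> PreprocessSpec:
    """Fit a per-feature empirical-CDF map to the uniform [0, 1].

    The reference grid holds min(n_quantiles, n_rows) evenly spaced
    quantiles of each training column; application interpolates linearly
    between references and clips outside the training range.
    """
    n_ref = min(n_quantiles, len(train))
    grid = np.linspace(0.0, 1.0, n_ref)
    tables = {
        c: np.quantile(train[c].to_numpy(dtype=float), grid).tolist()
        for c in train.columns
    }
    return PreprocessSpec(
        mode="quantile_uniform",
        kept_features=list(train.columns),
        quantile_tables=tables,
        quantile_grid=grid.tolist(),
    )


def apply(spec: PreprocessSpec, matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted spec; columns come out in ``kept_features`` order."""
    missing = [c for c in spec.kept_features if c not in matrix.columns]
    if missing:
        raise KeyError(f"matrix is missing required features: {missing}")
    sub = matrix[spec.kept_features]
    if spec.mode == "nzv_corr_scale":
        center = pd.Series(spec.center)[spec.kept_features]
        scale = pd.Series(spec.scale)[spec.kept_features]
        return (sub - center) / scale
    if spec.mode == "quantile_uniform":
        grid = np.asarray(spec.quantile_grid)
        out = {}
        for c in spec.kept_features:
            refs = np.asarray(spec.quantile_tables[c])
            x = sub[c].to_numpy(dtype=float)
            if refs[0] == refs[-1]:  # constant training column
                out[c] = np.full(len(x), 0.5)
            else:
                out[c] = np.clip(np.interp(x, refs, grid), 0.0, 1.0)
        return pd.DataFrame(out, index=matrix.index)[spec.kept_features]
    raise ValueError(f"unknown preprocessing mode: {spec.mode!r}")


def intersect_features(
    train_features: list[str], predict_features: list[str]
) -> list[str]:
    """Features usable for an external prediction set: the intersection, in
    training order.  An empty intersection is an error — nothing could be
    predicted."""
    predict_set = set(predict_features)
    common = [f for f in train_features if f in predict_set]
    if not common:
        raise ValueError("no common features between training and prediction sets")
    return common


def read_descriptor_csv(path: str | Path) -> pd.DataFrame:
    """Descriptor matrix CSV: first column compound key, header row feature
    names.  Gzip-transparent via pandas."""
    return pd.read_csv(path, index_col=0)


def write_descriptor_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index_label="canonical_smiles")
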