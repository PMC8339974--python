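"""Chemical similarity kernels for neighbor identification.

Two kernels: Tanimoto/Jaccard over atom-environment feature sets and
cosine over numeric descriptor vectors.  Cosine is not clamped — centered
descriptors can legitimately produce negative values, and the tier
thresholds compare against the raw kernel output.
"""

from __future__ import annotations

import numpy as np


def tanimoto(a: set[str], b: set[str]) -> float:
    """Jaccard/Tanimoto index |A ∩ B| / |A ∪ B| over feature sets."""
    if not a or not b:
        raise ValueError("tanimoto requires non-empty feature sets")
    intersection = len(a & b)
    union = len(a) + len(b) - intersection
    return intersection / union


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity A·B / (|A||B|) between descriptor vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    norm_a = np.linalg.norm(a)
    norm_b = np.linalg.norm(b)
    if norm_a == 0.0 or norm_b == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(a, b) / (norm_a * norm_b))
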