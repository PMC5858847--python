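"""Spatial-spectral KNN filtering of per-pixel class probabilities.

Each pixel i carries the feature vector

    F(i) = (I(i), lambda * l(i), lambda * h(i))

where I is the one-band guidance image in [0, 1] and l, h are the pixel's
column (longitude) and row (latitude) normalized to [0, 1].  The filtered
probability of pixel i is the mean probability of its K nearest neighbors
in this feature space (the pixel itself included, so K = 1 is the
identity).  lambda = 0 removes all spatial information; large K or lambda
oversmooth the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, DimensionError
from .hsdata import LabelMap, ProbabilityMap


@dataclass
class KnnFilterParams:
    K: int = 40
    lam: float = 1.0


def build_features(guidance: np.ndarray, lam: float = 1.0) -> np.ndarray:
    """``H x W x 3`` feature field (I, lambda*l, lambda*h).

    Normalized coordinates use ``col/(W-1)`` and ``row/(H-1)``; a
    single-row or single-column image gets coordinate 0 on that axis.
    """
    I = np.asarray(guidance, dtype=np.float64)
    if I.ndim != 2:
        raise DimensionError("guidance image must be 2-D")
    H, W = I.shape
    rows = np.arange(H) / (H - 1) if H > 1 else np.zeros(H)
    cols = np.arange(W) / (W - 1) if W > 1 else np.zeros(W)
    h, l = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([I, lam * l, lam * h], axis=2)


def knn_filter(P: ProbabilityMap, F: np.ndarray, K: int = 40) -> ProbabilityMap:
    """Average each pixel's probability vector over its K nearest neighbors
    in feature space (Euclidean; self-inclusive; distance ties at the K-th
    neighbor broken by raster index)."""
    H, W, C = P.probs.shape
    if F.shape[:2] != (H, W):
        raise DimensionError("feature field and probability map grids differ")
    n = H * W
    if not (1 <= K <= n):
        raise ConfigError(f"K={K} outside [1, {n}]")
    feats = F.reshape(n, -1)
    tree = cKDTree(feats)
    _, idx = tree.query(feats, k=K)
    idx = idx.reshape(n, K)
    flat = P.probs.reshape(n, C)
    out = flat[idx].mean(axis=1)
    # mean of simplex points can drift by eps; renormalize exactly
    out /= out.sum(axis=1, keepdims=True)
    return ProbabilityMap(out.reshape(H, W, C), class_order=P.class_order)


def filtered_class_map(O: ProbabilityMap) -> LabelMap:
    """Hard labels from the filtered probabilities (ties -> lowest class id)."""
    return O.argmax_labels()


def knn_filter_bruteforce(P: ProbabilityMap, F: np.ndarray, K: int) -> ProbabilityMap:
    """O(n^2) exhaustive-distance reference implementation (small images).

    Kept as an independent oracle for the tree-based path; ties at the K-th
    neighbor broken by raster index, matching the main implementation.
    """
    H, W, C = P.probs.shape
    n = H * W
    feats = F.reshape(n, -1)
    flat = P.probs.reshape(n, C)
    d = np.linalg.norm(feats[:, None, :] - feats[None, :, :], axis=2)
    out = np.empty((n, C))
    for i in range(n):
        order = np.argsort(d[i], kind="stable")[:K]
        out[i] = flat[order].mean(axis=0)
    out /= out.sum(axis=1, keepdims=True)
    return ProbabilityMap(out.reshape(H, W, C), class_order=P.class_order)
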