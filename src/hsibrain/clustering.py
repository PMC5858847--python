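"""Hierarchical (bisecting) K-means segmentation of a pre-processed cube.

All pixels start in one node; the leaf with the largest within-cluster sum
of squared deviations is repeatedly split by 2-means (k-means++ seeding,
several restarts, best inertia kept) until the requested number of leaves
is reached.  Leaves partition the pixels and total within-cluster SSE is
non-increasing with every split.  Each leaf centroid is a spectrum
representing one material or tissue in the scene; with enough clusters the
scene is deliberately oversegmented, which the downstream majority-voting
fusion tolerates (several clusters may map to the same class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import ConfigError
from .hsdata import HSCube, SegmentationMap


@dataclass(eq=False)
class HkmNode:
    pixel_idx: np.ndarray          # flat raster indices of member pixels
    centroid: np.ndarray
    sse: float
    children: list = field(default_factory=list)
    leaf_id: int | None = None     # assigned to final leaves only

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class HkmTree:
    root: HkmNode
    leaves: list[HkmNode]
    n_pixels: int
    sse_path: list[float] = field(default_factory=list)  # total SSE after each split


def _node_stats(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, float]:
    pts = X[idx]
    c = pts.mean(axis=0)
    return c, float(np.sum((pts - c) ** 2))


def hkm_segment(cube: HSCube, n_clusters: int = 24,
                seed: int = 0, n_restarts: int = 5) -> tuple[SegmentationMap, HkmTree]:
    """Segment the cube's pixels into exactly *n_clusters* nonempty clusters."""
    H, W, B = cube.shape
    n = H * W
    if not (1 <= n_clusters <= n):
        raise ConfigError(f"n_clusters={n_clusters} outside [1, {n}]")
    X = cube.pixels()
    rng = np.random.default_rng(seed)
    c0, s0 = _node_stats(X, np.arange(n))
    root = HkmNode(np.arange(n), c0, s0)
    leaves = [root]
    sse_path = [s0]
    while len(leaves) < n_clusters:
        # largest-SSE splittable leaf; ties by node creation order
        candidates = [nd for nd in leaves if nd.pixel_idx.size >= 2 and nd.sse > 0]
        if not candidates:
            candidates = [nd for nd in leaves if nd.pixel_idx.size >= 2]
        if not candidates:
            raise ConfigError("no splittable leaf left; too many clusters for the data")
        node = max(candidates, key=lambda nd: nd.sse)
        pts = X[node.pixel_idx]
        km = KMeans(n_clusters=2, n_init=n_restarts,
                    random_state=int(rng.integers(2**31 - 1))).fit(pts)
        lab = km.labels_
        if lab.min() == lab.max():  # degenerate: force a 1-vs-rest split
            lab = np.zeros(len(pts), dtype=int)
            lab[0] = 1
        kids = []
        for side in (0, 1):
            idx = node.pixel_idx[lab == side]
            c, s = _node_stats(X, idx)
            kids.append(HkmNode(idx, c, s))
        node.children = kids
        leaves.remove(node)
        leaves.extend(kids)
        sse_path.append(total_sse(leaves))
    ids = np.empty(n, dtype=np.int32)
    for i, leaf in enumerate(leaves):
        leaf.leaf_id = i
        ids[leaf.pixel_idx] = i
    seg = SegmentationMap(ids.reshape(H, W), n_clusters=len(leaves))
    return seg, HkmTree(root=root, leaves=leaves, n_pixels=n, sse_path=sse_path)


def cluster_centroids(tree: HkmTree) -> np.ndarray:
    """Per-leaf mean spectrum, ``n_leaves x B``, in leaf-id order."""
    return np.vstack([leaf.centroid for leaf in tree.leaves])


def total_sse(leaves) -> float:
    return float(sum(nd.sse for nd in leaves))
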