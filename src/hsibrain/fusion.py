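"""Majority-voting fusion of supervised and unsupervised maps.

The unsupervised segmentation delineates spatially coherent regions but
carries no tissue identity; the (filtered) supervised classification
carries identity but ragged borders.  Fusion assigns every pixel of a
cluster the cluster's most frequent supervised class (majority voting,
MV) and renders three maps:

* MV  — each cluster painted the full palette color of its winning class
        (tumor red, normal green, vessel blue, background black);
* OMD — One Maximum Density: the winning class's color scaled by its
        fraction (a cluster 80% tumor renders RGB (0.8, 0, 0));
        background is never degraded;
* TMD — Three Maximum Density: the colors of the three largest class
        fractions mixed by their fractions (60% tumor / 10% normal /
        30% vessel renders (0.6, 0.1, 0.3)); mixed tumor+vessel clusters
        come out purple — hypervascularized tissue with tumor infiltration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError
from .hsdata import CLASS_COLORS, CLASS_NAMES, LabelMap, SegmentationMap

#: class order used in every profile vector
PROFILE_ORDER = (1, 2, 3, 4)  # normal, tumor, vessel, background
BACKGROUND_ID = 4


@dataclass
class ClusterProfile:
    """Per-cluster class-frequency fractions in PROFILE_ORDER plus size."""

    fractions: np.ndarray   # (n_clusters, 4), rows sum to 1
    counts: np.ndarray      # (n_clusters,) pixel counts

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.fractions < 0):
            raise DimensionError("negative class fraction")
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise DimensionError("cluster fractions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions,
                          columns=[CLASS_NAMES[c] for c in PROFILE_ORDER])
        df.insert(0, "cluster", np.arange(len(self.counts)))
        df["pixels"] = self.counts
        return df


def compute_profiles(seg: SegmentationMap, classes: LabelMap) -> ClusterProfile:
    """Normalized class histogram of the supervised map within each cluster."""
    if seg.cluster_ids.shape != classes.labels.shape:
        raise DimensionError("segmentation and class maps must share a grid")
    n = seg.n_clusters
    fr = np.zeros((n, len(PROFILE_ORDER)))
    counts = np.bincount(seg.cluster_ids.ravel(), minlength=n)
    for j, cid in enumerate(PROFILE_ORDER):
        sel = classes.labels.ravel() == cid
        fr[:, j] = np.bincount(seg.cluster_ids.ravel()[sel], minlength=n)
    with np.errstate(invalid="ignore"):
        fr = fr / counts[:, None]
    fr[counts == 0] = np.array([0, 0, 0, 1.0])  # empty cluster: background
    return ClusterProfile(fractions=fr, counts=counts)


def mv_map(profiles: ClusterProfile, seg: SegmentationMap,
           palette=CLASS_COLORS) -> tuple[LabelMap, np.ndarray, list[int]]:
    """Majority-vote map: full-color label raster.

    Returns (label map, RGB image, list of tied cluster ids).  Exact vote
    ties resolve to the lowest class id and are reported.
    """
    win_idx = np.argmax(profiles.fractions, axis=1)   # first max -> lowest id
    winners = np.asarray(PROFILE_ORDER, dtype=np.int32)[win_idx]
    maxfrac = profiles.fractions[np.arange(len(winners)), win_idx]
    ties = [int(k) for k in range(len(winners))
            if np.sum(np.isclose(profiles.fractions[k], maxfrac[k])) > 1]
    labels = winners[seg.cluster_ids]
    lmap = LabelMap(labels)
    rgb = np.zeros(labels.shape + (3,))
    for cid in PROFILE_ORDER:
        rgb[labels == cid] = palette[cid]
    return lmap, rgb, ties


def omd_map(profiles: ClusterProfile, seg: SegmentationMap,
            palette=CLASS_COLORS) -> np.ndarray:
    """One Maximum Density: winner's color scaled by the winning fraction.

    A cluster whose winner is background stays pure black (not degraded).
    """
    win_idx = np.argmax(profiles.fractions, axis=1)
    maxfrac = profiles.fractions[np.arange(len(win_idx)), win_idx]
    colors = np.zeros((len(win_idx), 3))
    for k, (j, f) in enumerate(zip(win_idx, maxfrac)):
        cid = PROFILE_ORDER[j]
        scale = 1.0 if cid == BACKGROUND_ID else f
        colors[k] = np.asarray(palette[cid]) * scale
    return colors[seg.cluster_ids]


def tmd_map(profiles: ClusterProfile, seg: SegmentationMap,
            palette=CLASS_COLORS) -> np.ndarray:
    """Three Maximum Density: mix the three largest fractions' colors.

    The smallest fraction is dropped without renormalizing; the mix is
    clipped to [0, 1].  Background contributes black, darkening mixes.
    """
    colors = np.zeros((profiles.fractions.shape[0], 3))
    pal = np.array([palette[c] for c in PROFILE_ORDER])
    for k, fr in enumerate(profiles.fractions):
        top3 = np.argsort(fr, kind="stable")[::-1][:3]
        colors[k] = np.clip((fr[top3, None] * pal[top3]).sum(axis=0), 0.0, 1.0)
    return colors[seg.cluster_ids]
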