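"""Fixed-reference one-band embedding of a hyperspectral cube.

A 1-D stochastic-neighbor embedding (t-SNE) is trained once on a fixed set
of reference spectra; its learned coordinates are frozen into a lookup
table.  New pixels are mapped by finding their nearest reference spectra
and averaging those references' coordinates, which keeps the coordinate
system consistent across cubes (unlike re-running t-SNE per cube).  The
resulting one-band image, min-max normalized to [0, 1], serves as the
guidance image of the spatial-spectral KNN filter.

A PCA first-component guidance image is available as a closed-form
fallback for regression testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .errors import DegenerateInputError, DimensionError
from .hsdata import HSCube, SignatureDataset


@dataclass
class ReferenceEmbedding:
    """Frozen lookup table: reference spectra and their learned coordinates."""

    ref_spectra: np.ndarray   # (N, B)
    ref_coords: np.ndarray    # (N,)
    lookup_k: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.ref_spectra = np.atleast_2d(np.asarray(self.ref_spectra, dtype=np.float64))
        self.ref_coords = np.asarray(self.ref_coords, dtype=np.float64).ravel()
        if self.ref_spectra.shape[0] != self.ref_coords.shape[0]:
            raise DimensionError("one coordinate per reference spectrum required")
        if not np.all(np.isfinite(self.ref_coords)):
            raise DimensionError("non-finite reference coordinates")


def subsample_references(dataset: SignatureDataset, max_refs: int = 2000,
                         seed: int = 0) -> np.ndarray:
    """Class-balanced subsample of labeled spectra, at most *max_refs* rows."""
    rng = np.random.default_rng(seed)
    classes = np.unique(dataset.class_ids)
    per_class = max(1, max_refs // max(len(classes), 1))
    picks = []
    for c in classes:
        idx = np.flatnonzero(dataset.class_ids == c)
        take = min(per_class, idx.size)
        picks.append(rng.choice(idx, size=take, replace=False))
    return dataset.spectra[np.sort(np.concatenate(picks))]


def fit_reference(spectra, dim: int = 1, seed: int = 0, perplexity: float = 30.0,
                  lookup_k: int = 1, method: str = "tsne") -> ReferenceEmbedding:
    """Learn the fixed reference embedding on *spectra* (array or dataset).

    ``method="pca"`` substitutes the first principal component as the
    coordinate, a deterministic closed form useful for testing.
    """
    if isinstance(spectra, SignatureDataset):
        spectra = subsample_references(spectra, seed=seed)
    X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    N = X.shape[0]
    if N < 10:
        raise DegenerateInputError(f"need >= 10 reference spectra, got {N}")
    if method == "pca":
        coords = PCA(n_components=dim, random_state=seed).fit_transform(X)[:, 0]
    else:
        # degenerate all-identical input has no neighbor structure; map to 0
        if np.allclose(X, X[0]):
            coords = np.zeros(N)
        else:
            eff_perp = min(perplexity, (N - 1) / 3)
            ts = TSNE(n_components=dim, perplexity=eff_perp, random_state=seed,
                      init="pca", max_iter=1000)
            coords = ts.fit_transform(X)[:, 0]
    return ReferenceEmbedding(ref_spectra=X, ref_coords=coords,
                              lookup_k=lookup_k, seed=seed)


def embed_cube(cube: HSCube, ref: ReferenceEmbedding) -> np.ndarray:
    """One-band guidance image: per pixel, the mean learned coordinate of its
    ``lookup_k`` nearest reference spectra, min-max normalized to [0, 1].

    A constant embedding (all pixels hit the same coordinate) maps to all
    zeros.
    """
    H, W, B = cube.shape
    if B != ref.ref_spectra.shape[1]:
        raise DimensionError(
            f"cube has {B} bands but reference spectra have {ref.ref_spectra.shape[1]}")
    nn = NearestNeighbors(n_neighbors=ref.lookup_k, algorithm="brute").fit(ref.ref_spectra)
    _, idx = nn.kneighbors(cube.pixels())
    img = ref.ref_coords[idx].mean(axis=1).reshape(H, W)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros((H, W))
    return (img - lo) / (hi - lo)
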