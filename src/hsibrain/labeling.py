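"""Semi-automatic gold-standard construction with the Spectral Angle Mapper.

A surgeon-chosen reference pixel seeds each class: every pixel whose
spectral angle to the reference falls below a threshold is selected and
assigned that class.  SAM is invariant to multiplicative brightness, so the
selection ignores illumination differences across the brain surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (ConfigError, DimensionError, InvalidClassError,
                     UndefinedAngleError)
from .hsdata import HSCube, LabelMap, SignatureDataset


@dataclass
class SamSelection:
    reference_pixel: tuple[int, int]
    threshold_deg: float
    mask: np.ndarray
    assigned_class: int = 0


def sam_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral angle between two spectra, in degrees (0..180)."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise DimensionError(f"spectra lengths differ: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedAngleError("spectral angle undefined for a zero spectrum")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def sam_select(cube: HSCube, reference_pixel: tuple[int, int],
               threshold_deg: float = 0.08, unit: str = "deg") -> SamSelection:
    """Mask of pixels with spectral angle strictly below the threshold.

    The threshold is in degrees by default; ``unit="rad"`` interprets the
    same number as radians.  Zero-spectrum pixels are never selected.
    """
    r, c = reference_pixel
    H, W, _ = cube.shape
    if not (0 <= r < H and 0 <= c < W):
        raise IndexError(f"reference pixel {reference_pixel} outside {H}x{W} grid")
    thr = threshold_deg if unit == "deg" else float(np.degrees(threshold_deg))
    ref = cube.data[r, c]
    nref = np.linalg.norm(ref)
    if nref == 0:
        raise UndefinedAngleError("reference pixel has a zero spectrum")
    X = cube.pixels()
    norms = np.linalg.norm(X, axis=1)
    cos = np.zeros(X.shape[0])
    nz = norms > 0
    cos[nz] = np.clip((X[nz] @ ref) / (norms[nz] * nref), -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    mask = np.where(nz, ang < thr, False).reshape(H, W)
    return SamSelection(reference_pixel=(r, c), threshold_deg=thr, mask=mask)


def assign_selection(label_map: LabelMap, selection: SamSelection, class_id: int,
                     policy: str = "keep-first") -> tuple[LabelMap, int]:
    """Assign the selected pixels to *class_id*.

    Conflicts with already-labeled pixels are resolved per *policy*
    (``keep-first`` default, ``overwrite``, ``error``).  Returns the updated
    map and the conflict count.
    """
    if class_id == 0:
        raise InvalidClassError("cannot assign the unlabeled id 0")
    if class_id not in label_map.class_names:
        raise InvalidClassError(f"unknown class id {class_id}")
    if selection.mask.shape != label_map.labels.shape:
        raise DimensionError("selection mask and label map shapes differ")
    labels = label_map.labels.copy()
    conflict = selection.mask & (labels != 0) & (labels != class_id)
    n_conflicts = int(conflict.sum())
    if policy == "keep-first":
        target = selection.mask & (labels == 0)
    elif policy == "overwrite":
        target = selection.mask
    elif policy == "error":
        if n_conflicts:
            raise ConfigError(f"{n_conflicts} conflicting labels under policy 'error'")
        target = selection.mask
    else:
        raise ConfigError(f"unknown conflict policy {policy!r}")
    labels[target] = class_id
    return LabelMap(labels, label_map.class_names, label_map.class_colors), n_conflicts


def extract_dataset(cubes_and_maps: list[tuple[HSCube, LabelMap]],
                    patient_ids: list | None = None) -> SignatureDataset:
    """Collect one row per labeled pixel across (cube, label map) pairs."""
    pids, cids, spectra = [], [], []
    for k, (cube, lmap) in enumerate(cubes_and_maps):
        if cube.data.shape[:2] != lmap.labels.shape:
            raise DimensionError("label map does not match cube spatial grid")
        pid = patient_ids[k] if patient_ids else f"P{k + 1}"
        rows, cols = np.nonzero(lmap.labels)
        pids.extend([pid] * rows.size)
        cids.append(lmap.labels[rows, cols])
        spectra.append(cube.data[rows, cols])
    if not cids or sum(c.size for c in cids) == 0:
        B = cubes_and_maps[0][0].n_bands if cubes_and_maps else 0
        return SignatureDataset(np.array([], dtype=object), np.array([], dtype=np.int32),
                                np.empty((0, B)))
    return SignatureDataset(np.array(pids), np.concatenate(cids), np.vstack(spectra))
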