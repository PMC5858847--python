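"""Core data model and I/O for intraoperative hyperspectral cubes.

A cube is an ``H x W x B`` array of non-negative reals (raw radiance counts
or, after calibration, unitless reflectance) with one wavelength per band.
The spatial convention is 0-based ``(row, col)`` everywhere in the package:
row is the latitude axis, col the longitude axis.

Two on-disk representations are supported:

* the classic ENVI header + raw binary pair (BIL / BIP / BSQ interleaves),
  the native ecosystem of pushbroom VNIR cameras, and
* a lossless NPZ container that also carries the processing stage and
  label dictionaries, used between pipeline stages.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import imageio.v3 as iio

from .errors import DimensionError, FormatError, PaletteError

# Processing stages in their only legal order.
STAGES = ("raw", "calibrated", "denoised", "cropped", "reduced", "normalized")

#: Fixed class-id order reused for probability vectors everywhere.
CLASS_IDS = {"normal": 1, "tumor": 2, "vessel": 3, "background": 4}
CLASS_NAMES = {1: "normal", 2: "tumor", 3: "vessel", 4: "background"}
#: Rendering palette: tumor red, normal green, vessel blue, background black.
CLASS_COLORS = {
    1: (0.0, 1.0, 0.0),
    2: (1.0, 0.0, 0.0),
    3: (0.0, 0.0, 1.0),
    4: (0.0, 0.0, 0.0),
}

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}


@dataclass
class HSCube:
    """Hyperspectral cube: ``data[row, col, band]`` plus band wavelengths."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    stage: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError(f"cube data must be H x W x B, got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths_nm.shape[0]:
            raise DimensionError(
                f"{self.data.shape[2]} bands but {self.wavelengths_nm.shape[0]} wavelengths")
        if self.wavelengths_nm.size > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise DimensionError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise DimensionError("cube data must be finite")
        if self.stage not in STAGES:
            raise FormatError(f"unknown stage {self.stage!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def pixels(self) -> np.ndarray:
        """Flattened ``(H*W) x B`` view in raster (row-major) order."""
        return self.data.reshape(-1, self.n_bands)

    def with_stage(self, stage: str) -> "HSCube":
        """Return a copy advanced to *stage*; transitions only move forward."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise FormatError(f"stage cannot move backwards: {self.stage} -> {stage}")
        return replace(self, stage=stage)


@dataclass
class ReferenceFrames:
    """White-tile and closed-shutter (dark) calibration frames."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.white.shape != self.dark.shape:
            raise DimensionError("white and dark frames must share a shape")
        # tolerate a little sensor noise: white below dark on <1% of entries
        frac_bad = np.mean(self.white < self.dark)
        if frac_bad > 0.01:
            raise DimensionError(
                f"white < dark on {frac_bad:.1%} of entries; references look swapped")


@dataclass
class LabelMap:
    """Integer class raster: 0 = unlabeled, then the fixed class dictionary."""

    labels: np.ndarray
    class_names: Mapping[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))
    class_colors: Mapping[int, tuple] = field(default_factory=lambda: dict(CLASS_COLORS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise DimensionError("label map must be 2-D")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.class_names)
        if missing:
            from .errors import InvalidClassError
            raise InvalidClassError(f"label ids {sorted(missing)} missing from class_names")

    def counts(self) -> dict[int, int]:
        ids, n = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, n) if i != 0}


@dataclass
class SignatureDataset:
    """Labeled spectra: one row per gold-standard pixel."""

    patient_ids: np.ndarray   # (N,) strings or ints
    class_ids: np.ndarray     # (N,) ints, nonzero
    spectra: np.ndarray       # (N, B)

    def __post_init__(self) -> None:
        self.class_ids = np.asarray(self.class_ids, dtype=np.int32)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))
        self.patient_ids = np.asarray(self.patient_ids)
        if self.spectra.shape[0] != self.class_ids.shape[0]:
            raise DimensionError("one class id per spectrum required")
        if np.any(self.class_ids == 0):
            from .errors import InvalidClassError
            raise InvalidClassError("class_id 0 (unlabeled) not allowed in a dataset")

    def __len__(self) -> int:
        return int(self.class_ids.shape[0])

    def summary(self) -> "pd.DataFrame":
        """Per-patient, per-class pixel counts with totals (gold-standard table)."""
        import pandas as pd
        df = pd.DataFrame({"patient": self.patient_ids, "class_id": self.class_ids})
        df["class"] = df["class_id"].map(CLASS_NAMES)
        table = df.pivot_table(index="patient", columns="class", values="class_id",
                               aggfunc="count", fill_value=0)
        for name in CLASS_IDS:
            if name not in table.columns:
                table[name] = 0
        table = table[list(CLASS_IDS)]
        table.loc["Total"] = table.sum()
        table["Total"] = table.sum(axis=1)
        return table

    def to_csv(self, path: str) -> None:
        import pandas as pd
        cols = {f"b{j}": self.spectra[:, j] for j in range(self.spectra.shape[1])}
        pd.DataFrame({"patient": self.patient_ids, "class_id": self.class_ids, **cols}
                     ).to_csv(path, index=False)


@dataclass
class ProbabilityMap:
    """Per-pixel class-probability vectors (``H x W x C``) on the simplex."""

    probs: np.ndarray
    class_order: tuple = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] != len(self.class_order):
            raise DimensionError("probability map must be H x W x C matching class order")
        if np.any(self.probs < -1e-12):
            raise DimensionError("negative probabilities")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise DimensionError("pixel probabilities must sum to 1")

    def argmax_labels(self) -> LabelMap:
        """Hard map; exact ties go to the lowest class id (argmax's first hit
        matches because class_order is ascending)."""
        idx = np.argmax(self.probs, axis=2)
        labels = np.asarray(self.class_order, dtype=np.int32)[idx]
        return LabelMap(labels)


@dataclass
class SegmentationMap:
    """Per-pixel cluster identifiers in ``[0, n_clusters)``."""

    cluster_ids: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=np.int32)
        if self.cluster_ids.ndim != 2:
            raise DimensionError("segmentation map must be 2-D")
        if self.cluster_ids.size and self.cluster_ids.max() >= self.n_clusters:
            raise DimensionError("cluster id beyond n_clusters")
        if self.cluster_ids.size and self.cluster_ids.min() < 0:
            raise DimensionError("negative cluster id")


# ---------------------------------------------------------------------------
# container (NPZ) I/O — lossless round trip including stage and metadata
# ---------------------------------------------------------------------------

def write_cube(cube: HSCube, path: str) -> None:
    """Write *cube* to the NPZ container; bit-exact round trip with read_cube."""
    np.savez(path,
             data=cube.data,
             wavelengths_nm=cube.wavelengths_nm,
             stage=np.array(cube.stage),
             metadata=np.array(json.dumps(cube.metadata)))


def _read_container(path: str) -> HSCube:
    with np.load(path, allow_pickle=False) as z:
        return HSCube(data=z["data"],
                      wavelengths_nm=z["wavelengths_nm"],
                      stage=str(z["stage"]),
                      metadata=json.loads(str(z["metadata"])))


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

def _parse_envi_header(path: str) -> dict:
    with open(path, "r") as fh:
        text = fh.read()
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("missing ENVI magic line in header")
    body = text.split("\n", 1)[1] if "\n" in text else ""
    # brace-valued fields may span lines; normalise them first
    fields: dict[str, str] = {}
    buf = ""
    key = None
    for line in body.splitlines():
        if key is None:
            if "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            key = key.lower()
            if val.startswith("{") and "}" not in val:
                buf = val
                continue
            fields[key] = val.strip("{} ")
            key = None
        else:
            buf += " " + line.strip()
            if "}" in buf:
                fields[key] = buf.strip("{} ")
                key = None
                buf = ""
    out: dict = {}
    for name in ("samples", "lines", "bands", "data type", "byte order", "header offset"):
        if name in fields:
            try:
                out[name] = int(fields[name])
            except ValueError as exc:
                raise FormatError(f"ENVI header field {name!r} is not an integer: "
                                  f"{fields[name]!r}") from exc
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields and req not in out:
            raise FormatError(f"ENVI header missing required field {req!r}")
    out["interleave"] = fields["interleave"].lower()
    if out["interleave"] not in ("bil", "bip", "bsq"):
        raise FormatError(f"ENVI header field 'interleave' invalid: {out['interleave']!r}")
    if out["data type"] not in _ENVI_DTYPES:
        raise FormatError(f"ENVI header field 'data type' unsupported: {out['data type']}")
    if "wavelength" in fields:
        out["wavelength"] = np.array(
            [float(x) for x in fields["wavelength"].split(",") if x.strip()])
    return out


def read_cube(path: str, format: str = "container") -> HSCube:
    """Read a cube from the NPZ container or an ENVI header+binary pair.

    For ENVI, *path* is the header file; the binary is the same path without
    the ``.hdr`` suffix (or ``path + '.dat'``).
    """
    if format == "container":
        return _read_container(path)
    if format != "envi":
        raise FormatError(f"unknown format {format!r}")
    hdr = _parse_envi_header(path)
    base = path[:-4] if path.endswith(".hdr") else path
    binpath = base if os.path.exists(base) and base != path else base + ".dat"
    if not os.path.exists(binpath):
        raise FormatError(f"ENVI binary not found next to header: {binpath}")
    dtype = np.dtype(_ENVI_DTYPES[hdr["data type"]])
    if hdr.get("byte order", 0) == 1:
        dtype = dtype.newbyteorder(">")
    raw = np.fromfile(binpath, dtype=dtype, offset=hdr.get("header offset", 0))
    H, W, B = hdr["lines"], hdr["samples"], hdr["bands"]
    if raw.size != H * W * B:
        raise DimensionError(
            f"ENVI binary holds {raw.size} values but header declares {H}x{W}x{B}")
    il = hdr["interleave"]
    if il == "bsq":
        data = raw.reshape(B, H, W).transpose(1, 2, 0)
    elif il == "bil":
        data = raw.reshape(H, B, W).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(H, W, B)
    wl = hdr.get("wavelength")
    if wl is None:
        wl = np.arange(B, dtype=float)
    elif wl.shape[0] != B:
        raise DimensionError(f"{wl.shape[0]} wavelengths for {B} bands in ENVI header")
    return HSCube(data=np.ascontiguousarray(data, dtype=np.float64),
                  wavelengths_nm=wl, stage="raw")


def write_envi(cube: HSCube, path: str, interleave: str = "bil") -> None:
    """Write an ENVI float32 header+binary pair; *path* is the header path."""
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unknown interleave {interleave!r}")
    H, W, B = cube.shape
    base = path[:-4] if path.endswith(".hdr") else path
    binpath = base + ".dat"
    if interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    else:
        arr = cube.data
    np.ascontiguousarray(arr, dtype=np.float32).tofile(binpath)
    wl = ", ".join(f"{x:.6f}" for x in cube.wavelengths_nm)
    with open(path, "w") as fh:
        fh.write("ENVI\n"
                 f"samples = {W}\nlines = {H}\nbands = {B}\n"
                 "header offset = 0\ndata type = 4\n"
                 f"interleave = {interleave}\nbyte order = 0\n"
                 f"wavelength = {{ {wl} }}\n")


# ---------------------------------------------------------------------------
# rendered-map output
# ---------------------------------------------------------------------------

def write_map_png(map_obj, path: str, palette: Mapping[int, tuple] | None = None) -> None:
    """Render a LabelMap / SegmentationMap / RGB float array as an 8-bit PNG.

    The id -> color mapping is recorded in a sidecar CSV next to the PNG.
    """
    if isinstance(map_obj, LabelMap):
        pal = dict(palette or map_obj.class_colors)
        pal.setdefault(0, (0.0, 0.0, 0.0))
        ids = map_obj.labels
    elif isinstance(map_obj, SegmentationMap):
        if palette is None:
            raise PaletteError("segmentation maps need an explicit palette")
        pal = dict(palette)
        ids = map_obj.cluster_ids
    else:
        rgb = np.asarray(map_obj, dtype=np.float64)
        if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.size == 0:
            raise DimensionError("rendered map must be a nonempty H x W x 3 array")
        iio.imwrite(path, np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8))
        return
    if ids.size == 0:
        raise DimensionError("empty map")
    missing = set(np.unique(ids)) - set(pal)
    if missing:
        raise PaletteError(f"no palette entry for ids {sorted(missing)}")
    rgb = np.zeros(ids.shape + (3,), dtype=np.uint8)
    for cid, color in pal.items():
        rgb[ids == cid] = np.clip(np.round(np.asarray(color) * 255), 0, 255).astype(np.uint8)
    iio.imwrite(path, rgb)
    with open(os.path.splitext(path)[0] + "_palette.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "r", "g", "b"])
        for cid in sorted(pal):
            w.writerow([cid, *pal[cid]])


def categorical_palette(n: int, seed: int = 0) -> dict[int, tuple]:
    """Seeded random categorical palette for segmentation maps."""
    rng = np.random.default_rng(seed)
    hues = rng.permutation(n) / max(n, 1)
    out = {}
    for i, h in enumerate(hues):
        # simple HSV->RGB with full saturation/value
        x = h * 6.0
        k = int(x) % 6
        f = x - int(x)
        v, p, q, t = 1.0, 0.15, 1 - 0.85 * f, 0.15 + 0.85 * f
        out[i] = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][k]
    return out
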