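"""Synthetic intraoperative hyperspectral phantom.

Generates a raw pushbroom cube with white/dark reference frames and a
fully known ground-truth label map, so every pipeline stage can be tested
without patient data.  The scene mimics an exposed-brain capture:

* four spectral classes — normal parenchyma, tumor, blood vessel /
  hypervascularized tissue, and background (drapes, instruments) — with
  smooth band-correlated endmember spectra (low in the blue, rising
  through red/NIR for tissue; a hemoglobin-like dip for vessels);
* the vessel endmember is deliberately the spectrally closest class to
  tumor, the known source of tumor/vessel false positives;
* a smooth multiplicative illumination field (the brain surface is not
  flat) in a configurable range;
* additive band-dependent Gaussian sensor noise that grows toward the
  spectral extremes, motivating the extreme-band removal step;
* geometry: a background border, a central tumor ellipse, vessel
  polylines, normal tissue elsewhere.

``calibrate(raw, refs)`` recovers ``reflectance * illumination + noise``
exactly, because the raw counts are synthesized by inverting the
calibration equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from .hsdata import HSCube, LabelMap, ReferenceFrames
from .labeling import sam_angle


@dataclass
class PhantomSpec:
    H: int = 128
    W: int = 128
    B: int = 826
    wavelength_range_nm: tuple = (400.0, 1000.0)
    tumor_vessel_angle_deg: float = 15.0   # closest pair by design
    min_interclass_angle_deg: float = 20.0
    illumination_range: tuple = (0.6, 1.4)
    noise_sd: float = 0.01
    tumor_center: tuple = (0.45, 0.58)     # fractional (row, col)
    tumor_axes: tuple = (0.18, 0.15)       # fractional semi-axes
    border_frac: float = 0.09              # background border width
    vessel_width_frac: float = 0.02
    label_fraction: float = 0.15
    seed: int = 0


CLASS_ORDER = ("normal", "tumor", "vessel", "background")
CLASS_ID = {"normal": 1, "tumor": 2, "vessel": 3, "background": 4}

#: per-class brightness (spectrum norm scale); SAM ignores it, k-means sees it
_AMPLITUDE = {"normal": 0.9, "tumor": 1.0, "vessel": 0.5, "background": 0.15}


def _smooth_basis(B: int) -> tuple[np.ndarray, np.ndarray]:
    """Positive mean tissue shape m (unit norm) plus four smooth orthonormal
    perturbation directions, each weighted by m so that perturbed spectra
    stay (nearly) positive."""
    x = np.linspace(0.0, 1.0, B)
    # generic tissue envelope: dim blue end, rising through red/NIR
    mean_shape = CubicSpline([0.0, 0.15, 0.3, 0.5, 0.7, 0.9, 1.0],
                             [0.30, 0.38, 0.55, 0.78, 0.92, 1.0, 1.0])(x)
    m = mean_shape / np.linalg.norm(mean_shape)
    waves = [np.sin(np.pi * x), np.cos(2 * np.pi * x),
             np.sin(3 * np.pi * x), np.cos(4 * np.pi * x)]
    basis = [m]
    out = []
    for w in waves:
        v = mean_shape * w
        for b in basis:
            v = v - (v @ b) * b
        v /= np.linalg.norm(v)
        basis.append(v)
        out.append(v)
    return m, np.array(out)


def endmember_spectra(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Class endmembers over ``spec.B`` bands with a controlled angular
    structure.

    Tumor, vessel and normal are unit rotations of a shared positive tissue
    shape along mutually orthogonal smooth directions: vessel sits exactly
    ``tumor_vessel_angle_deg`` from tumor (the closest pair, by design),
    normal exactly ``min_interclass_angle_deg`` from tumor (and therefore
    farther from vessel: the orthogonal perturbations compound), and
    background is rotated well beyond the minimum and kept dark.  A final
    nonnegativity clip can move angles by a fraction of a degree, so they
    are re-measured rather than assumed downstream.
    """
    m, u = _smooth_basis(spec.B)

    def rot(anchor: np.ndarray, direction: np.ndarray, deg: float) -> np.ndarray:
        th = np.radians(deg)
        return np.cos(th) * anchor + np.sin(th) * direction

    tumor = rot(m, u[0], 10.0)
    vessel = rot(tumor, u[1], spec.tumor_vessel_angle_deg)
    normal = rot(tumor, u[2], spec.min_interclass_angle_deg)
    background = rot(m, u[3], spec.min_interclass_angle_deg + 18.0)
    em = {"normal": normal, "tumor": tumor, "vessel": vessel,
          "background": background}
    return {k: np.clip(v * _AMPLITUDE[k] / np.max(np.abs(v)), 1e-4, None)
            for k, v in em.items()}


def _truth_layout(spec: PhantomSpec) -> np.ndarray:
    H, W = spec.H, spec.W
    labels = np.full((H, W), CLASS_ID["normal"], dtype=np.int32)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    # tumor ellipse
    r0, c0 = spec.tumor_center[0] * H, spec.tumor_center[1] * W
    ra, ca = spec.tumor_axes[0] * H, spec.tumor_axes[1] * W
    if ra < 1 or ca < 1 or not (0 <= r0 < H and 0 <= c0 < W):
        raise ConfigError("tumor ellipse lies outside the grid")
    labels[((rr - r0) / ra) ** 2 + ((cc - c0) / ca) ** 2 <= 1.0] = CLASS_ID["tumor"]
    # vessels: two polylines crossing the scene
    width = max(1.0, spec.vessel_width_frac * min(H, W))
    for segs in (
        [((0.15, 0.2), (0.45, 0.3)), ((0.45, 0.3), (0.8, 0.25))],
        [((0.2, 0.85), (0.55, 0.75)), ((0.55, 0.75), (0.85, 0.9))],
    ):
        for (r1, c1), (r2, c2) in segs:
            p1 = np.array([r1 * H, c1 * W])
            p2 = np.array([r2 * H, c2 * W])
            d = p2 - p1
            t = np.clip(((rr - p1[0]) * d[0] + (cc - p1[1]) * d[1]) / (d @ d), 0, 1)
            dist = np.hypot(rr - (p1[0] + t * d[0]), cc - (p1[1] + t * d[1]))
            labels[dist <= width] = CLASS_ID["vessel"]
    # background border drawn last, on top of everything
    b = int(round(spec.border_frac * min(H, W)))
    if b > 0:
        labels[:b, :] = labels[-b:, :] = CLASS_ID["background"]
        labels[:, :b] = labels[:, -b:] = CLASS_ID["background"]
    return labels


def make_phantom(spec: PhantomSpec | None = None
                 ) -> tuple[HSCube, ReferenceFrames, LabelMap]:
    """Build (raw cube, reference frames, full-truth label map).

    Deterministic under ``spec.seed``; ``noise_sd=0`` with a flat
    illumination range recovers the endmembers exactly after calibration.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    H, W, B = spec.H, spec.W, spec.B
    em = endmember_spectra(spec)
    labels = _truth_layout(spec)
    wl = np.linspace(*spec.wavelength_range_nm, B)

    refl = np.empty((H, W, B))
    for name, cid in CLASS_ID.items():
        refl[labels == cid] = em[name]

    lo, hi = spec.illumination_range
    if hi > lo:
        field_ = gaussian_filter(rng.standard_normal((H, W)), sigma=max(H, W) / 8)
        fmin, fmax = field_.min(), field_.max()
        illum = lo + (field_ - fmin) / (fmax - fmin) * (hi - lo) if fmax > fmin \
            else np.full((H, W), (lo + hi) / 2)
    else:
        illum = np.full((H, W), lo)
    signal = refl * illum[:, :, None]

    if spec.noise_sd > 0:
        # band-dependent sd, rising steeply at the CCD extremes
        pos = np.linspace(-1, 1, B)
        sd = spec.noise_sd * (1.0 + 3.0 * pos ** 8)
        signal = signal + rng.standard_normal((H, W, B)) * sd
    np.clip(signal, 0.0, None, out=signal)

    # lamp spectrum: QTH-like, dim in the blue, bright in red/NIR
    lamp = 1200.0 + 2800.0 / (1.0 + np.exp(-6.0 * (np.linspace(0, 1, B) - 0.35)))
    dark = np.full((H, W, B), 100.0)
    white = dark + lamp[None, None, :]
    raw = signal * (white - dark) + dark

    cube = HSCube(raw, wl, stage="raw",
                  metadata={"phantom_seed": spec.seed, "phantom": True})
    return cube, ReferenceFrames(white=white, dark=dark), LabelMap(labels)


def sample_gold_standard(truth: LabelMap, label_fraction: float = 0.15,
                         seed: int = 0) -> LabelMap:
    """Class-stratified sparse labeling of *truth*.

    The total labeled count is ``round(label_fraction * n_pixels)``,
    apportioned to classes by the largest-remainder method, so it lands
    within one pixel of the exact product.
    """
    if not (0 < label_fraction <= 1):
        raise ConfigError("label_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    flat = truth.labels.ravel()
    N = flat.size
    target = int(round(label_fraction * N))
    classes, counts = np.unique(flat[flat != 0], return_counts=True)
    quotas = label_fraction * counts
    base = np.floor(quotas).astype(int)
    rem = target - base.sum()
    if rem > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:rem]] += 1
    base = np.minimum(base, counts)
    out = np.zeros(N, dtype=np.int32)
    for cid, take in zip(classes, base):
        idx = np.flatnonzero(flat == cid)
        pick = rng.choice(idx, size=int(take), replace=False)
        out[pick] = cid
    return LabelMap(out.reshape(truth.labels.shape),
                    truth.class_names, truth.class_colors)
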