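"""Five-step pre-processing chain for raw VNIR pushbroom cubes.

The chain turns raw radiance counts into per-pixel unit-norm reflectance
spectra suitable for classification:

1. radiometric calibration against white-tile and dark (closed-shutter)
   reference frames,
2. noise filtering by per-band linear regression on the remaining bands
   (the noise-estimation stage of HySIME),
3. removal of the low-SNR extreme bands at both ends of the CCD range,
4. spectral averaging of contiguous band groups down to a fixed band count
   (contiguous bands are highly redundant),
5. per-pixel normalization, removing the multiplicative illumination
   differences produced by the non-flat brain surface.

Two outputs are produced: the reduced cube (classification input) and a
full-band cropped cube that skips the averaging step (embedding input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import ConfigError, DegenerateInputError, DimensionError
from .hsdata import HSCube, ReferenceFrames


@dataclass
class PreprocessConfig:
    """Defaults follow the VNIR 826-band configuration: bands up to 50 and
    from 750 on are dropped, the rest averaged down to 129 bands."""

    crop_low: int = 50
    crop_high: int = 750
    target_bands: int = 129
    normalization: str = "l2"      # l2 | max | minmax
    noise_filter: bool = True
    clip_max: float = 1.5


def calibrate(raw: HSCube, refs: ReferenceFrames, clip_max: float = 1.5) -> HSCube:
    """Per pixel-band reflectance ``(raw - dark) / (white - dark)``.

    Bands where white == dark (dead sensor columns) produce 0 with a warning
    counter in the cube metadata instead of dividing by zero.  Output is
    clipped to ``[0, clip_max]``; specular pixels can exceed the white tile.
    """
    if raw.data.shape != refs.white.shape:
        raise DimensionError(
            f"cube shape {raw.data.shape} != reference shape {refs.white.shape}")
    if raw.stage != "raw":
        raise DimensionError(f"calibrate expects a raw cube, got stage {raw.stage!r}")
    denom = refs.white - refs.dark
    dead = denom == 0
    n_dead = int(dead.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data - refs.dark) / denom
    refl[dead] = 0.0
    np.clip(refl, 0.0, clip_max, out=refl)
    if n_dead:
        warnings.warn(f"{n_dead} white==dark entries set to 0 during calibration")
    meta = dict(raw.metadata, dead_reference_entries=n_dead)
    return HSCube(refl, raw.wavelengths_nm, stage="calibrated", metadata=meta)


def estimate_and_filter_noise(cube: HSCube) -> tuple[HSCube, np.ndarray]:
    """Estimate per-pixel noise by modelling each band as a linear
    regression on all remaining bands, and return the fitted (denoised)
    cube plus the residual noise array.

    The residual of regressing band ``i`` on the others is computed through
    the precision matrix ``G = (X'X)^-1`` as ``X G[:, i] / G[i, i]``, which
    evaluates all bands at once.  If ``X'X`` is singular (exactly
    linearly-dependent bands) the regression falls back to per-band
    least squares.
    """
    if cube.stage not in ("calibrated", "raw"):
        raise DimensionError(f"noise filter expects calibrated data, got {cube.stage!r}")
    H, W, B = cube.shape
    N = H * W
    if N < 2:
        raise DegenerateInputError("need at least 2 pixels to fit the noise regression")
    X = cube.pixels()
    ridge = (N <= B)
    R = X.T @ X
    if ridge:
        # under-determined: a small ridge keeps the system solvable
        R = R + 1e-6 * np.trace(R) / B * np.eye(B)
    try:
        c, low = linalg.cho_factor(R, check_finite=False)
        G = linalg.cho_solve((c, low), np.eye(B), check_finite=False)
        noise = (X @ G) / np.diag(G)
    except linalg.LinAlgError:
        noise = np.empty_like(X)
        for i in range(B):
            others = np.delete(X, i, axis=1)
            beta, *_ = np.linalg.lstsq(others, X[:, i], rcond=None)
            noise[:, i] = X[:, i] - others @ beta
    denoised = X - noise
    out = HSCube(denoised.reshape(H, W, B), cube.wavelengths_nm,
                 stage="denoised", metadata=dict(cube.metadata))
    return out, noise.reshape(H, W, B)


def crop_bands(cube: HSCube, crop_low: int = 50, crop_high: int = 750) -> HSCube:
    """Keep bands with 0-based index strictly between *crop_low* and
    *crop_high* (the stated limits themselves are removed)."""
    B = cube.n_bands
    lo, hi = crop_low, min(crop_high, B)
    keep = np.arange(max(lo + 1, 0), hi)
    if keep.size == 0:
        raise ConfigError(f"crop ({crop_low}, {crop_high}) leaves no bands of {B}")
    return HSCube(cube.data[:, :, keep], cube.wavelengths_nm[keep],
                  stage="cropped", metadata=dict(cube.metadata))


def average_bands(cube: HSCube, target_bands: int = 129) -> HSCube:
    """Average contiguous band groups down to *target_bands* outputs.

    Groups are as equal as possible (sizes differ by at most one, larger
    groups first); each output band is the mean of its group, its
    wavelength the mean group wavelength.
    """
    if target_bands < 1:
        raise ConfigError("target_bands must be >= 1")
    B = cube.n_bands
    if target_bands > B:
        raise ConfigError(f"target_bands {target_bands} exceeds band count {B}")
    sizes = np.full(target_bands, B // target_bands)
    sizes[: B % target_bands] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    data = np.stack([cube.data[:, :, edges[g]:edges[g + 1]].mean(axis=2)
                     for g in range(target_bands)], axis=2)
    wl = np.array([cube.wavelengths_nm[edges[g]:edges[g + 1]].mean()
                   for g in range(target_bands)])
    return HSCube(data, wl, stage="reduced", metadata=dict(cube.metadata))


def normalize_pixels(cube: HSCube, mode: str = "l2") -> HSCube:
    """Normalize each pixel spectrum; zero spectra are left at zero."""
    X = cube.pixels()
    if mode == "l2":
        scale = np.linalg.norm(X, axis=1, keepdims=True)
    elif mode == "max":
        scale = np.abs(X).max(axis=1, keepdims=True)
    elif mode == "minmax":
        lo = X.min(axis=1, keepdims=True)
        scale = X.max(axis=1, keepdims=True) - lo
        X = X - lo
    else:
        raise ConfigError(f"unknown normalization mode {mode!r}")
    safe = np.where(scale == 0, 1.0, scale)
    out = (X / safe).reshape(cube.shape)
    return HSCube(out, cube.wavelengths_nm, stage="normalized",
                  metadata=dict(cube.metadata))


def run_chain(raw: HSCube, refs: ReferenceFrames,
              config: PreprocessConfig | None = None) -> tuple[HSCube, HSCube]:
    """Run the full chain; returns ``(reduced_normalized, fullband_cropped_normalized)``.

    The second output skips only the band-averaging step and feeds the
    one-band embedding; the first is the classification input.
    """
    cfg = config or PreprocessConfig()
    cal = calibrate(raw, refs, clip_max=cfg.clip_max)
    if cfg.noise_filter:
        cal, _ = estimate_and_filter_noise(cal)
    cropped = crop_bands(cal, cfg.crop_low, cfg.crop_high)
    reduced = average_bands(cropped, cfg.target_bands)
    return (normalize_pixels(reduced, cfg.normalization),
            normalize_pixels(cropped, cfg.normalization))
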