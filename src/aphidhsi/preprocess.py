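"""Raw cube -> analysis views: calibrated reflectance, 3-D Savitzky-Golay
smoothing, band trimming, mean ROI spectra with first derivatives (1-D view),
synthesized RGB frames (2-D view), and spatial resizing (3-D view).

Calibration follows the two-point gray-panel model

    I_c = I_r / (2 * I_g)

where ``I_r`` is the raw radiance cube and ``I_g`` the radiance of a
50%-reflectance gray panel, so a pixel matching the panel maps to 0.5.

The Savitzky-Golay smoother fits, in a k x k x k neighbourhood of every voxel,
the least-squares trivariate polynomial of total degree <= p and keeps its
value at the centre voxel; because that estimate is linear in the data it is
precomputed once as a convolution stencil.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _skimage_resize

from .synthetic import RawHSI, WavelengthGrid

logger = logging.getLogger(__name__)

#: Wavelengths (nm) of the synthesized RGB planes, in (R, G, B) order.
RGB_WAVELENGTHS_NM = (698.0, 548.0, 461.0)
TRIM_LO_NM, TRIM_HI_NM = 461.0, 988.0


@dataclass
class ReflectanceHSI:
    """Calibrated reflectance cube (bands, H, W) with its wavelength grid."""

    cube: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        if self.cube.shape[0] != len(self.grid):
            raise ValueError("band count must match the wavelength grid")


@dataclass
class SpectrumSample:
    """First-derivative mean ROI spectrum of one leaf (reflectance per nm)."""

    values: np.ndarray
    grid: WavelengthGrid
    class_label: int
    session: int
    id: str

    def __post_init__(self):
        if self.values.shape != (len(self.grid),):
            raise ValueError("spectrum length must equal the grid length")


@dataclass
class RGBSample:
    """Synthesized RGB frame (H, W, 3) with intensities in [0, 1]."""

    pixels: np.ndarray
    class_label: int
    session: int
    id: str

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RGB pixels must have shape (H, W, 3)")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_reflectance(raw: RawHSI) -> ReflectanceHSI:
    """Two-point reflectance calibration ``I_c = I_r / (2 I_g)``."""
    if np.any(raw.gray_reference <= 0):
        raise ValueError("gray reference must be strictly positive")
    cube = raw.cube / (2.0 * raw.gray_reference)
    return ReflectanceHSI(cube=cube, grid=raw.grid)


# ---------------------------------------------------------------------------
# Savitzky-Golay 3-D smoothing
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def sg3d_stencil(kernel_size: int = 5, poly_order: int = 3) -> np.ndarray:
    """Centre-value stencil of the trivariate least-squares polynomial fit.

    Weights w solve: fitted value at the kernel centre = sum(w * data) for the
    polynomial basis {b^a i^b j^c : a+b+c <= poly_order} over the cubic
    neighbourhood of half-width (kernel_size-1)/2.
    """
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel size must be odd and positive")
    if poly_order >= kernel_size:
        raise ValueError("polynomial order must be below the kernel size")
    half = kernel_size // 2
    offsets = np.array(list(product(range(-half, half + 1), repeat=3)), dtype=float)
    exps = [(a, b, c)
            for a in range(poly_order + 1)
            for b in range(poly_order + 1 - a)
            for c in range(poly_order + 1 - a - b)]
    X = np.stack([offsets[:, 0] ** a * offsets[:, 1] ** b * offsets[:, 2] ** c
                  for (a, b, c) in exps], axis=1)
    # centre value = basis(0) @ pinv(X) @ y ; basis(0) selects the constant term
    e0 = np.zeros(len(exps))
    e0[exps.index((0, 0, 0))] = 1.0
    weights = e0 @ np.linalg.pinv(X)
    return weights.reshape(kernel_size, kernel_size, kernel_size)


def sg_smooth_3d(cube: np.ndarray, kernel_size: int = 5, poly_order: int = 3) -> np.ndarray:
    """Smooth a (bands, H, W) cube with the 3-D Savitzky-Golay stencil.

    Boundary voxels use reflect padding so the cube keeps its shape.
    """
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("expected a 3-D cube (bands, H, W)")
    if any(s < kernel_size for s in cube.shape):
        raise ValueError("cube must be at least kernel_size along every axis")
    w = sg3d_stencil(kernel_size, poly_order)
    return ndimage.correlate(cube.astype(np.float64), w, mode="reflect")


# ---------------------------------------------------------------------------
# band trimming, ROI spectra, derivatives
# ---------------------------------------------------------------------------

def trim_bands(hsi: ReflectanceHSI, lo_nm: float = TRIM_LO_NM,
               hi_nm: float = TRIM_HI_NM) -> ReflectanceHSI:
    """Keep exactly the bands whose centres fall in the closed [lo, hi] nm."""
    keep = hsi.grid.indices_in(lo_nm, hi_nm)
    if keep.size == 0:
        raise ValueError(f"no band centres in [{lo_nm}, {hi_nm}] nm")
    return ReflectanceHSI(cube=hsi.cube[keep],
                          grid=WavelengthGrid(hsi.grid.centers[keep]))


def mean_roi_spectrum(hsi: ReflectanceHSI | np.ndarray, leaf_mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean over the ROI (leaf) pixels."""
    cube = hsi.cube if isinstance(hsi, ReflectanceHSI) else np.asarray(hsi)
    mask = np.asarray(leaf_mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return cube[:, mask].mean(axis=1)


def first_derivative(spectrum: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    """d(reflectance)/d(wavelength): central differences on the interior,
    one-sided at the two ends; same length as the input."""
    values = np.asarray(spectrum, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 bands for a derivative")
    if values.size != len(grid):
        raise ValueError("spectrum length must match the grid")
    return np.gradient(values, grid.centers, edge_order=2)


# ---------------------------------------------------------------------------
# RGB synthesis and resizing
# ---------------------------------------------------------------------------

def synthesize_rgb(hsi: ReflectanceHSI, leaf_mask: np.ndarray | None = None,
                   class_label: int = 0, session: int = 0,
                   sample_id: str = "") -> RGBSample:
    """Pick the bands nearest 698/548/461 nm as R/G/B planes and min-max
    scale each channel to [0, 1] over the leaf pixels (whole frame if no
    mask is given)."""
    planes = []
    for nm in RGB_WAVELENGTHS_NM:
        idx = hsi.grid.band_index(nm)   # raises beyond half a band spacing
        planes.append(hsi.cube[idx])
    img = np.stack(planes, axis=-1).astype(float)
    region = (np.asarray(leaf_mask, dtype=bool)
              if leaf_mask is not None else np.ones(img.shape[:2], dtype=bool))
    out = np.empty_like(img)
    for ch in range(3):
        vals = img[..., ch][region]
        lo, hi = vals.min(), vals.max()
        span = hi - lo if hi > lo else 1.0
        out[..., ch] = np.clip((img[..., ch] - lo) / span, 0.0, 1.0)
    return RGBSample(pixels=out, class_label=class_label, session=session,
                     id=sample_id)


def resize_sample(sample, target: int = 160):
    """Bilinear spatial resize to ``target x target``; spectral axis untouched.

    Accepts an ``RGBSample`` (H, W, 3), a ``ReflectanceHSI``, or a bare
    (bands, H, W) array, and returns the same type.
    """
    if isinstance(sample, RGBSample):
        px = _resize_array(sample.pixels, (target, target, 3), sample.pixels.shape[:2])
        return RGBSample(pixels=px, class_label=sample.class_label,
                         session=sample.session, id=sample.id)
    if isinstance(sample, ReflectanceHSI):
        cube = _resize_array(sample.cube, (sample.cube.shape[0], target, target),
                             sample.cube.shape[1:])
        return ReflectanceHSI(cube=cube, grid=sample.grid)
    arr = np.asarray(sample)
    if arr.ndim != 3:
        raise ValueError("expected (bands, H, W) array")
    return _resize_array(arr, (arr.shape[0], target, target), arr.shape[1:])


def _resize_array(arr: np.ndarray, shape: tuple, spatial: tuple) -> np.ndarray:
    if min(spatial) < 2:
        raise ValueError("spatial dimensions must be at least 2")
    if arr.shape == shape:
        return arr.astype(float, copy=True)
    return _skimage_resize(arr.astype(float), shape, order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)


# ---------------------------------------------------------------------------
# feature standardization
# ---------------------------------------------------------------------------

def standardize_sets(train: np.ndarray, validation: np.ndarray, test: np.ndarray,
                     eps: float = 1e-8):
    """Standardize every feature to zero mean / unit sd using *training*
    statistics only; the same statistics are applied to validation and test.

    Zero-variance features have their sd floored at ``eps`` (logged).
    Returns ``(train, validation, test, (mean, sd))``.
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] == 0:
        raise ValueError("training set is empty")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    n_floored = int(np.sum(sd < eps))
    if n_floored:
        logger.warning("standardize_sets: %d feature(s) with sd < %g floored",
                       n_floored, eps)
    sd = np.maximum(sd, eps)
    out = tuple((np.asarray(s, dtype=float) - mean) / sd
                for s in (train, validation, test))
    return (*out, (mean, sd))
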