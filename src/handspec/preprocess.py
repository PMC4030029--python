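"""Calibration, denoising, normalisation and illumination flattening.

Produces the two working products of the pipeline: the measurable image
L_P (calibrated, median-filtered, normalised per band so that 1.0 means
100% emission) and the segmentation image L_C (L_P minus its local moving
average, which suppresses smooth illumination gradients).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .envi import SpectralCube

__all__ = [
    "FilterConfig",
    "calibrate",
    "median_filter",
    "normalize",
    "normalize_cube",
    "remove_illumination",
    "valid_region",
]

_BORDER_MODES = {"replicate": "nearest", "zero": "constant"}


@dataclass
class FilterConfig:
    """Spatial filter sizes.

    ``median_size`` is the square median mask (odd, default 3 px, sized to
    reject optical-path contamination without erasing small real features);
    ``mean_size`` is the square moving-average mask subtracted to remove
    uneven illumination (default 30 px, twice the largest small-object
    size); ``border_mode`` controls padding outside the frame.
    """

    median_size: int = 3
    mean_size: int = 30
    border_mode: str = "replicate"

    def __post_init__(self) -> None:
        if self.median_size < 1 or self.median_size % 2 == 0:
            raise ValueError("median_size must be an odd integer >= 1")
        if self.mean_size < 2:
            raise ValueError("mean_size must be >= 2")
        if self.border_mode not in _BORDER_MODES:
            raise ValueError(f"border_mode must be one of {sorted(_BORDER_MODES)}")


def calibrate(cube: SpectralCube, floor_rel: float = 1e-6) -> SpectralCube:
    """Divide each band, per column, by the mean of its white-reference rows.

    Push-broom frames carry leading rows imaging a 100%-emission reference;
    dividing by their per-column, per-band mean removes both the lamp
    spectrum and the across-track (column-wise) illumination profile.  The
    dark reference is taken as zero.  Reference rows are retained in the
    output (still flagged by ``calib_rows``).  Near-zero reference values
    are floored at ``floor_rel`` times the reference maximum to guard the
    division.

    With ``calib_rows == 0`` calibration is skipped with a warning.
    """
    if cube.calib_rows == 0:
        warnings.warn("cube has no reference rows; calibration skipped")
        return SpectralCube(cube.values.copy(), cube.wavelengths_nm.copy(), 0)
    ref = cube.values[: cube.calib_rows].mean(axis=0)  # (N, bands)
    floor = max(float(np.abs(ref).max()) * floor_rel, np.finfo(float).tiny)
    denom = np.maximum(ref, floor)
    values = cube.values / denom[np.newaxis, :, :]
    return SpectralCube(values, cube.wavelengths_nm.copy(), cube.calib_rows)


def median_filter(
    image: np.ndarray, size: int = 3, border_mode: str = "replicate"
) -> np.ndarray:
    """Square median filter (each pixel replaced by the median of its
    ``size x size`` neighbourhood).  Accepts a 2-D image or a 3-D cube
    (filtered band by band)."""
    if size % 2 == 0:
        raise ValueError(f"median mask size must be odd, got {size}")
    image = np.asarray(image)
    mode = _BORDER_MODES[border_mode]
    if image.ndim == 3:
        return ndimage.median_filter(image, size=(size, size, 1), mode=mode)
    return ndimage.median_filter(image, size=size, mode=mode)


def normalize(image: np.ndarray) -> np.ndarray:
    """Stretch the image to the full [0, 1] brightness range:
    ``(x - min) / (max - min)``.

    A constant image is an error (a dead band should surface, not silently
    become zeros).
    """
    x = np.asarray(image, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("cannot normalize a constant image (max == min)")
    return (x - lo) / (hi - lo)


def normalize_cube(cube: SpectralCube) -> SpectralCube:
    """Apply :func:`normalize` independently to every band.

    The reference rows take part in the stretch, so value 1 corresponds to
    100% emission at each wavelength.
    """
    out = np.empty_like(cube.values, dtype=float)
    for k in range(cube.shape[2]):
        out[:, :, k] = normalize(cube.values[:, :, k])
    return SpectralCube(out, cube.wavelengths_nm.copy(), cube.calib_rows)


def _mean_origin(size: int) -> int:
    # The moving-average window of an even-sized mask spans
    # [i - size/2 + 1, i + size/2]; scipy's default even-size window sits
    # one pixel earlier, hence the origin shift (scipy shifts the window by
    # -origin).
    return -1 if size % 2 == 0 else 0


def remove_illumination(
    image: np.ndarray, mean_size: int = 30, border_mode: str = "replicate"
) -> np.ndarray:
    """Subtract the ``mean_size x mean_size`` moving average from the image.

    Smooth (low-frequency) illumination gradients survive the averaging and
    cancel in the subtraction; structures smaller than the mask are kept.
    The output covers the full frame using the requested padding; inside
    :func:`valid_region` it equals the padless double sum exactly.  Accepts
    a 2-D image or a 3-D cube (per-band).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3):
        raise ValueError("expected a 2-D image or 3-D cube")
    if min(image.shape[:2]) <= mean_size:
        raise ValueError(
            f"image {image.shape[:2]} must be larger than the {mean_size} mask"
        )
    mode = _BORDER_MODES[border_mode]
    o = _mean_origin(mean_size)
    if image.ndim == 3:
        local_mean = ndimage.uniform_filter(
            image, size=(mean_size, mean_size, 1), mode=mode, origin=(o, o, 0)
        )
    else:
        local_mean = ndimage.uniform_filter(
            image, size=mean_size, mode=mode, origin=o
        )
    return image - local_mean


def valid_region(shape: tuple[int, int], mean_size: int) -> tuple[slice, slice]:
    """Slices of the region where the moving-average window lies fully
    inside the frame (border padding has no influence there)."""
    m, n = shape[:2]
    if mean_size % 2 == 0:
        lo = mean_size // 2 - 1
    else:
        lo = mean_size // 2
    hi_m = m - mean_size // 2
    hi_n = n - mean_size // 2
    return slice(lo, hi_m), slice(lo, hi_n)
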