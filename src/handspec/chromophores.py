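"""Chromophore band aggregation and the red/green composite.

The melanin image is the per-pixel sum of the corrected reflectance bands
over 450-600 nm; the haemoglobin image sums 397-500 nm (the Soret region,
extending toward the ultraviolet end of the camera support).  These are
plain reflectance-band sums — no absorbance conversion or spectral
unmixing — optionally stretched to [0, 1] for display and tabulation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envi import SpectralCube, band_indices
from .preprocess import normalize

__all__ = [
    "ChromophoreMap",
    "MELANIN_RANGE_NM",
    "HAEMOGLOBIN_RANGE_NM",
    "aggregate_band",
    "composite_rgb",
]

#: default aggregation ranges (nm)
MELANIN_RANGE_NM = (450.0, 600.0)
HAEMOGLOBIN_RANGE_NM = (397.0, 500.0)


@dataclass
class ChromophoreMap:
    """Per-pixel band aggregate with its provenance."""

    values: np.ndarray
    band_lo: float
    band_hi: float
    n_bands: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("a chromophore map is a 2-D image")
        if self.normalized and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValueError("a normalized map must lie in [0, 1]")


def aggregate_band(
    cube: SpectralCube, lo: float, hi: float, normalized: bool = False
) -> ChromophoreMap:
    """Sum the corrected cube's bands over the closed range [lo, hi] nm.

    With ``normalized=True`` the sum is additionally stretched to the full
    [0, 1] range, matching how the maps are displayed and tabulated.
    """
    idx = band_indices(cube.wavelengths_nm, lo, hi)
    if idx.size == 0:
        raise ValueError(f"no bands inside [{lo}, {hi}] nm")
    values = cube.values[:, :, idx].sum(axis=2)
    if normalized:
        values = normalize(values)
    return ChromophoreMap(values, lo, hi, int(idx.size), normalized)


def composite_rgb(
    melanin: ChromophoreMap, haemoglobin: ChromophoreMap
) -> np.ndarray:
    """Red/green composite: R = melanin map, G = haemoglobin map, B = 0.

    Both maps must be normalized and share dimensions.
    """
    if melanin.values.shape != haemoglobin.values.shape:
        raise ValueError(
            f"map dimensions differ: {melanin.values.shape} vs "
            f"{haemoglobin.values.shape}"
        )
    if not (melanin.normalized and haemoglobin.normalized):
        raise ValueError("composite requires normalized maps")
    blue = np.zeros_like(melanin.values)
    return np.stack([melanin.values, haemoglobin.values, blue], axis=-1)
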