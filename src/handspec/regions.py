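"""Per-finger area partition and region statistics.

Each matched finger is delimited from its fingertip landmark toward the
palm by the template's scaled finger length and divided into 12 areas:
six equal-length segments along the finger axis (A1/B1 at the tip), each
split across the finger width by the per-row centreline into side A (the
smaller-column, thumb side) and side B.  Segment boundaries are half-open,
so every finger pixel belongs to exactly one area.  Statistics are the
per-area mean and population standard deviation of a chromophore map
(the standard error of the mean is also tabulated for transparency).

Convention: the corrected hand is upright, so the finger axis runs along
rows and the width across columns.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromophores import ChromophoreMap
from .envi import SpectralCube, band_indices
from .geometry import LandmarkSet
from .matching import HandTemplate

__all__ = [
    "AreaPartition",
    "area_labels",
    "partition_finger",
    "area_stats",
    "spectral_profile",
    "SpectralProfile",
    "along_finger_trend",
]

N_SEGMENTS = 6


def area_labels() -> list[str]:
    """The 12 area labels in table order: A1..A6 then B1..B6."""
    return [f"A{j}" for j in range(1, N_SEGMENTS + 1)] + [
        f"B{j}" for j in range(1, N_SEGMENTS + 1)
    ]


@dataclass
class AreaPartition:
    """12-area partition of one finger.

    ``area_map`` assigns every pixel an area id 1..12 (0 = not in this
    finger); ``id_to_label`` maps ids to the labels of
    :func:`area_labels`.  ``axis_rows``/``centerline`` give the per-row
    centreline column over the finger's row span.
    """

    finger: int
    area_map: np.ndarray = field(repr=False)
    id_to_label: dict[int, str]
    axis_rows: np.ndarray = field(repr=False)
    centerline: np.ndarray = field(repr=False)
    row_span: tuple[int, int]

    def pixels(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        ids = [i for i, l in self.id_to_label.items() if l == label]
        return np.nonzero(self.area_map == ids[0])

    @property
    def finger_mask(self) -> np.ndarray:
        return self.area_map > 0


def partition_finger(
    mask: np.ndarray,
    landmarks: LandmarkSet,
    template: HandTemplate,
    finger: int,
    width_margin: float = 1.6,
) -> AreaPartition | None:
    """Partition one finger of the corrected mask into 12 labelled areas.

    ``finger`` is the landmark slot (0 = thumb side).  The finger region is
    the mask restricted to rows ``[tip, tip + scaled length)`` and to
    columns within ``width_margin x width/2`` of the fingertip column; the
    division then follows the module convention above.  A finger whose
    landmark is not visible is skipped with a warning (returns None).
    """
    if not landmarks.visible[finger]:
        warnings.warn(f"finger {finger} not visible; partition skipped")
        return None
    mask = np.asarray(mask).astype(bool)
    tip_r, tip_c = landmarks.point(finger)
    length = float(template.finger_lengths[finger])
    width = float(template.finger_widths[finger])
    if not np.isfinite(length) or not np.isfinite(width):
        warnings.warn(f"finger {finger} has no template geometry; skipped")
        return None

    r0 = int(round(tip_r))
    r1 = min(int(round(tip_r + length)), mask.shape[0])
    r0 = max(r0, 0)
    if r1 <= r0:
        warnings.warn(f"finger {finger} region empty; partition skipped")
        return None
    half = width_margin * width / 2.0
    c0 = max(int(np.floor(tip_c - half)), 0)
    c1 = min(int(np.ceil(tip_c + half)) + 1, mask.shape[1])

    region = np.zeros_like(mask)
    region[r0:r1, c0:c1] = mask[r0:r1, c0:c1]
    if not region.any():
        warnings.warn(f"finger {finger} region empty; partition skipped")
        return None

    # half-open equal-length segments along the axis, segment 1 at the tip
    bounds = r0 + np.round(np.arange(N_SEGMENTS + 1) * (r1 - r0) / N_SEGMENTS).astype(int)

    rows_idx, cols_idx = np.nonzero(region)
    segment = np.searchsorted(bounds, rows_idx, side="right") - 1
    segment = np.clip(segment, 0, N_SEGMENTS - 1)

    # per-row centreline = centroid column of the finger pixels in that row
    axis_rows = np.arange(r0, r1)
    centerline = np.full(axis_rows.size, np.nan)
    sums = np.bincount(rows_idx, weights=cols_idx, minlength=mask.shape[0])
    counts = np.bincount(rows_idx, minlength=mask.shape[0])
    have = counts[r0:r1] > 0
    centerline[have] = sums[r0:r1][have] / counts[r0:r1][have]

    side_b = cols_idx >= centerline[rows_idx - r0]  # A = smaller columns
    area_id = segment + 1 + N_SEGMENTS * side_b.astype(int)

    area_map = np.zeros(mask.shape, dtype=np.int16)
    area_map[rows_idx, cols_idx] = area_id
    id_to_label = {i + 1: lab for i, lab in enumerate(area_labels())}
    return AreaPartition(
        finger=finger,
        area_map=area_map,
        id_to_label=id_to_label,
        axis_rows=axis_rows,
        centerline=centerline,
        row_span=(r0, r1),
    )


def area_stats(cmap: ChromophoreMap, partition: AreaPartition) -> pd.DataFrame:
    """Mean, population standard deviation, SEM and pixel count per area,
    ordered A1..A6, B1..B6.  Empty areas are recorded as missing (NaN)."""
    if not partition.finger_mask.any():
        raise ValueError("partition contains no pixels")
    rows = []
    for label in area_labels():
        r, c = partition.pixels(label)
        vals = cmap.values[r, c]
        if vals.size == 0:
            rows.append((label, np.nan, np.nan, np.nan, 0))
        else:
            sd = float(vals.std(ddof=0))
            rows.append(
                (
                    label,
                    float(vals.mean()),
                    sd,
                    sd / np.sqrt(vals.size),
                    int(vals.size),
                )
            )
    return pd.DataFrame(rows, columns=["area", "mean", "std", "sem", "count"])


@dataclass
class SpectralProfile:
    """Across-width means of one finger: ``grid[p, k]`` is the mean over
    the finger width at along-axis position ``positions[p]`` and band
    ``k``; ``band_curve`` restricts the mean to a wavelength range."""

    positions: np.ndarray
    wavelengths_nm: np.ndarray
    grid: np.ndarray
    band_curve: np.ndarray
    band_range: tuple[float, float]


def spectral_profile(
    cube: SpectralCube,
    partition: AreaPartition,
    band_range: tuple[float, float] = (450.0, 600.0),
) -> SpectralProfile:
    """Per along-axis position, the mean across the finger width for every
    band, plus the band-restricted mean curve.  Positions with no finger
    pixels are skipped with a warning."""
    fm = partition.finger_mask
    r0, r1 = partition.row_span
    positions, rows_grid = [], []
    for r in range(r0, r1):
        cols = np.nonzero(fm[r])[0]
        if cols.size == 0:
            warnings.warn(f"finger {partition.finger}: empty axis position {r}")
            continue
        positions.append(r)
        rows_grid.append(cube.values[r, cols, :].mean(axis=0))
    if not positions:
        raise ValueError("no non-empty axis positions in the finger region")
    grid = np.asarray(rows_grid)
    idx = band_indices(cube.wavelengths_nm, *band_range)
    if idx.size == 0:
        raise ValueError(f"no bands inside {band_range} nm")
    return SpectralProfile(
        positions=np.asarray(positions),
        wavelengths_nm=cube.wavelengths_nm.copy(),
        grid=grid,
        band_curve=grid[:, idx].mean(axis=1),
        band_range=band_range,
    )


def along_finger_trend(
    cmap: ChromophoreMap, partitions: dict[int, AreaPartition]
) -> pd.DataFrame:
    """Along-finger intensity trend of a chromophore map.

    For every partitioned finger: the mean map value per along-axis
    position (tip first) and the wrist-end / tip-end ratio, read off a
    least-squares line fitted to the positional curve (robust to
    single-position noise; for a constant map the ratio is exactly 1).
    """
    if not partitions:
        raise ValueError("no partitioned fingers")
    records = []
    for finger, part in sorted(partitions.items()):
        fm = part.finger_mask
        r0, r1 = part.row_span
        pos, curve = [], []
        for r in range(r0, r1):
            cols = np.nonzero(fm[r])[0]
            if cols.size:
                pos.append(r)
                curve.append(float(cmap.values[r, cols].mean()))
        pos_arr = np.asarray(pos, dtype=float)
        curve_arr = np.asarray(curve)
        if pos_arr.size >= 2 and np.ptp(pos_arr) > 0:
            coeff = np.polyfit(pos_arr, curve_arr, 1)
            tip_val = float(np.polyval(coeff, pos_arr[0]))
            wrist_val = float(np.polyval(coeff, pos_arr[-1]))
        else:
            tip_val = wrist_val = float(curve_arr.mean())
        ratio = wrist_val / tip_val if tip_val != 0 else np.nan
        records.append(
            {
                "finger": finger,
                "positions": pos_arr,
                "curve": curve_arr,
                "wrist_tip_ratio": ratio,
            }
        )
    return pd.DataFrame.from_records(records)
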