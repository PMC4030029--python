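"""Hand localisation on the segmentation image.

The pipeline locates the hand hierarchically: the working image is a
nearest-neighbour downscale of the segmentation image, the inclination
angle is recovered by brute-force search of a column-sum criterion, the
silhouette is binarised at an automatic Otsu threshold, fingertips are the
local minima of the per-column first-foreground-row contour curve, and the
wrist landmark is the centroid of the silhouette after a morphological
opening whose square structuring element is wider than any finger (which
deletes the fingers and leaves the palm/wrist blob).

Convention: after rotation correction the hand is upright — fingers point
toward row 0, fingertips occupy distinct columns, the finger axis runs
along rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "LandmarkSet",
    "RotationResult",
    "CONTOUR_SENTINEL",
    "downscale",
    "rotate_image",
    "estimate_rotation",
    "otsu_threshold",
    "binarize",
    "contour_curve",
    "find_tip_landmarks",
    "opening",
    "wrist_centroid",
    "scale_landmarks",
]

#: value marking columns with no foreground pixel in a contour curve
CONTOUR_SENTINEL = -1

#: landmark slot of the wrist point V6 (slots 0..4 are fingertips V1..V5)
WRIST_SLOT = 5


@dataclass
class LandmarkSet:
    """Detected hand points V1..V6.

    Slots 0..4 hold fingertip coordinates ordered by column (thumb side
    first); slot 5 holds the wrist centroid.  Undetected points carry NaN
    coordinates and a False visibility flag.
    """

    rows: np.ndarray
    cols: np.ndarray
    visible: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.cols = np.asarray(self.cols, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if not (self.rows.shape == self.cols.shape == self.visible.shape == (6,)):
            raise ValueError("a LandmarkSet holds exactly 6 slots (V1..V6)")

    @classmethod
    def empty(cls) -> "LandmarkSet":
        return cls(np.full(6, np.nan), np.full(6, np.nan), np.zeros(6, bool))

    @property
    def tip_slots(self) -> np.ndarray:
        """Indices of visible fingertip slots (V1..V5 only)."""
        return np.nonzero(self.visible[:WRIST_SLOT])[0]

    def point(self, slot: int) -> tuple[float, float]:
        return float(self.rows[slot]), float(self.cols[slot])

    def with_wrist(self, row: float, col: float) -> "LandmarkSet":
        rows, cols, vis = self.rows.copy(), self.cols.copy(), self.visible.copy()
        rows[WRIST_SLOT], cols[WRIST_SLOT], vis[WRIST_SLOT] = row, col, True
        return LandmarkSet(rows, cols, vis)


@dataclass
class RotationResult:
    """Outcome of the brute-force inclination search."""

    alpha_deg: float
    score: float
    angles_deg: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------


def downscale(image: np.ndarray, factor: float) -> np.ndarray:
    """Nearest-neighbour downscale; output dims = round(dim * factor).

    Source index for output index ``i`` is ``floor(i / factor)``.
    """
    if factor <= 0 or factor > 1:
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    image = np.asarray(image)
    out_m = max(1, round(image.shape[0] * factor))
    out_n = max(1, round(image.shape[1] * factor))
    rows = np.minimum((np.arange(out_m) / factor).astype(int), image.shape[0] - 1)
    cols = np.minimum((np.arange(out_n) / factor).astype(int), image.shape[1] - 1)
    return image[np.ix_(rows, cols)]


def rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image centre, nearest-neighbour, frame preserved,
    out-of-frame filled with 0.  Works on 2-D images and on 3-D cubes
    (rotation in the row/column plane, identical for every band)."""
    if angle_deg % 360 == 0:
        return np.asarray(image).copy()
    return ndimage.rotate(
        image, angle_deg, axes=(1, 0), reshape=False, order=0,
        mode="constant", cval=0.0,
    )


def estimate_rotation(
    image: np.ndarray, step_deg: float = 1.0,
) -> RotationResult:
    """Recover the hand inclination by exhaustive search.

    For every angle alpha on a grid over (0°, 180°) the image is rotated by
    alpha and scored by the maximum over columns of its column sums; the
    score peaks when the hand's long axis lies along a single column (hand
    upright).  Returns the maximising angle, smallest on ties.

    ``image`` is the wavelength-summed working image (summing over bands
    before rotating is mathematically identical to rotating every band and
    summing afterwards, and far cheaper).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot estimate rotation of an empty image")
    if not np.any(image > 0):
        raise ValueError("rotation criterion undefined for a non-positive image")
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    angles = np.arange(step_deg, 180.0, step_deg)
    scores = np.empty(angles.size)
    for i, a in enumerate(angles):
        scores[i] = rotate_image(image, a).sum(axis=0).max()
    best = int(np.argmax(scores))  # argmax returns the first (smallest) tie
    return RotationResult(float(angles[best]), float(scores[best]), angles, scores)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold: the histogram cut maximising between-class variance.

    The histogram is built on values rescaled to [0, 1]; the returned
    threshold is mapped back to the original value range (the upper edge of
    the last below-threshold bin, so the strict ``>`` comparison of the
    binarisation step excludes the whole lower class).
    """
    x = np.asarray(image, dtype=float).ravel()
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("Otsu threshold undefined for a constant image")
    u = (x - lo) / (hi - lo)
    hist, edges = np.histogram(u, bins=nbins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    total = w.sum()
    w0 = np.cumsum(w)[:-1]
    w1 = total - w0
    s0 = np.cumsum(w * centers)[:-1]
    mu_total = (w * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (mu_total - s0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[np.isnan(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))  # cut between bin k and k+1
    return lo + edges[k + 1] * (hi - lo)


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask by strict comparison: 1 where ``image > threshold``."""
    return (np.asarray(image) > threshold).astype(np.uint8)


def contour_curve(mask: np.ndarray) -> np.ndarray:
    """Per column, the first (smallest) row holding a foreground pixel.

    Columns without foreground carry :data:`CONTOUR_SENTINEL`.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("contour curve undefined for an empty mask")
    first = np.argmax(mask, axis=0).astype(int)
    first[~mask.any(axis=0)] = CONTOUR_SENTINEL
    return first


def contour_minima(
    curve: np.ndarray, min_separation: int = 10, min_prominence: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Columns of the contour curve's local minima and their prominences.

    Minima must stand out by at least ``min_prominence`` rows and be at
    least ``min_separation`` columns apart; sentinel (empty) columns count
    as background.
    """
    curve = np.asarray(curve, dtype=float)
    big = np.nanmax(curve) + 2.0 * max(min_prominence, 1.0) + 2.0
    y = np.where(curve < 0, big, curve)
    peaks, props = signal.find_peaks(
        -y, prominence=min_prominence, distance=max(1, int(min_separation))
    )
    return peaks, props["prominences"]


def find_tip_landmarks(
    curve: np.ndarray,
    min_separation: int = 10,
    min_prominence: float = 5.0,
    max_tips: int = 5,
) -> LandmarkSet:
    """Fingertip landmarks from the local minima of the contour curve.

    A fingertip protrudes toward row 0, so it is a local minimum of the
    first-row curve.  At most ``max_tips`` minima (the most prominent,
    ``max_tips`` <= 5) are kept, ordered by column.  Fewer than five
    detections leave the remaining slots flagged not-visible (e.g. a thumb
    outside the frame).
    """
    if not (1 <= max_tips <= 5):
        raise ValueError("max_tips must be between 1 and 5")
    curve = np.asarray(curve, dtype=float)
    peaks, prominences = contour_minima(curve, min_separation, min_prominence)
    if peaks.size == 0:
        raise ValueError("no contour minima found: landmark detection failed")
    if peaks.size > max_tips:
        keep = np.argsort(prominences)[::-1][:max_tips]
        peaks = np.sort(peaks[keep])
    lm = LandmarkSet.empty()
    for i, p in enumerate(np.sort(peaks)):
        lm.rows[i] = curve[p]
        lm.cols[i] = p
        lm.visible[i] = True
    return lm


def opening(mask: np.ndarray, se_size: int) -> np.ndarray:
    """Morphological opening with a square structuring element.

    Erosion (sliding-window minimum) followed by dilation (sliding-window
    maximum), outside pixels counted as 0.  With an element wider than any
    finger, the fingers are deleted and only the palm/wrist blob remains.
    """
    mask = np.asarray(mask)
    if se_size % 2 == 0 or se_size < 3:
        raise ValueError(f"structuring element size must be odd >= 3, got {se_size}")
    if se_size >= min(mask.shape):
        raise ValueError(
            f"structuring element ({se_size}) must be smaller than the mask "
            f"{mask.shape}"
        )
    eroded = ndimage.minimum_filter(mask, size=se_size, mode="constant", cval=0)
    opened = ndimage.maximum_filter(eroded, size=se_size, mode="constant", cval=0)
    return opened.astype(np.uint8)


def wrist_centroid(weights: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centre of mass ``(m, n)`` of an image or mask.

    On a binary mask the weights are 0/1, i.e. the plain centroid.  The
    result is real-valued; round to the nearest pixel for the V6 landmark.
    """
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("centroid undefined: empty (all-zero) mask")
    m_idx, n_idx = np.indices(w.shape)
    return float((w * m_idx).sum() / total), float((w * n_idx).sum() / total)


def rotate_points(
    rows: np.ndarray,
    cols: np.ndarray,
    shape: tuple[int, int],
    angle_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate counterpart of :func:`rotate_image`: where a point at
    ``(rows, cols)`` lands when the image is rotated by ``angle_deg``."""
    cm, cn = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    a = np.deg2rad(angle_deg)
    dr = np.asarray(rows, dtype=float) - cm
    dc = np.asarray(cols, dtype=float) - cn
    return (
        cm + dr * np.cos(a) - dc * np.sin(a),
        cn + dr * np.sin(a) + dc * np.cos(a),
    )


def scale_landmarks(lm: LandmarkSet, factor: float) -> LandmarkSet:
    """Map landmark coordinates from a downscaled frame back to full
    resolution (pixel-centre convention: ``x_full = (x + 0.5)/factor - 0.5``)."""
    scale = lambda x: (x + 0.5) / factor - 0.5  # noqa: E731
    return LandmarkSet(scale(lm.rows), scale(lm.cols), lm.visible.copy())
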