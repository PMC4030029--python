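"""Anthropometric template matching.

Detected fingertip landmarks are matched to a hand pattern by exhaustive
minimisation of the criterion

    J(dm, dn) = sum_i (m_vi - (m_wvi + dm))^2 + sum_i (n_vi - (n_wvi + dn))^2

over integer displacements of the pattern within +/-range_px in both axes
(sum over visible fingertips; the square-root is omitted since the argmin
is identical).  A per-vertex refinement then repeats the search for each
fingertip independently.  The convention is that the *template* moves;
correcting the image therefore translates it by the opposite displacement.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .envi import SpectralCube
from .geometry import LandmarkSet, rotate_image

__all__ = [
    "HandTemplate",
    "MatchResult",
    "criterion_J",
    "global_match",
    "refine_vertices",
    "apply_correction",
    "default_template",
]


@dataclass
class HandTemplate:
    """Hand pattern: fingertip points V_w1..V_w5 (ordered by column, thumb
    side first), the wrist point V_w6, and per-finger anthropometric
    geometry, all in pixels of ``frame_shape``.

    Slots for fingers absent from the pattern hold NaN.
    """

    tip_rows: np.ndarray
    tip_cols: np.ndarray
    wrist: tuple[float, float]
    finger_lengths: np.ndarray
    finger_widths: np.ndarray
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.tip_rows = np.asarray(self.tip_rows, dtype=float)
        self.tip_cols = np.asarray(self.tip_cols, dtype=float)
        self.finger_lengths = np.asarray(self.finger_lengths, dtype=float)
        self.finger_widths = np.asarray(self.finger_widths, dtype=float)
        if self.tip_rows.shape != (5,) or self.tip_cols.shape != (5,):
            raise ValueError("a template holds 5 fingertip slots")
        cols = self.tip_cols[np.isfinite(self.tip_cols)]
        if cols.size != np.unique(cols).size:
            raise ValueError("template fingertips must occupy distinct columns")
        m, n = self.frame_shape
        rr = self.tip_rows[np.isfinite(self.tip_rows)]
        if rr.size and (rr.min() < 0 or rr.max() >= m):
            raise ValueError("template points outside the pattern frame")
        if cols.size and (cols.min() < 0 or cols.max() >= n):
            raise ValueError("template points outside the pattern frame")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.tip_rows) & np.isfinite(self.tip_cols)

    def shifted(self, dm: float, dn: float) -> "HandTemplate":
        return replace(
            self,
            tip_rows=self.tip_rows + dm,
            tip_cols=self.tip_cols + dn,
            wrist=(self.wrist[0] + dm, self.wrist[1] + dn),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "frame": {"rows": int(self.frame_shape[0]), "cols": int(self.frame_shape[1])},
            "tips": [
                {"row": float(r), "col": float(c)}
                for r, c in zip(self.tip_rows, self.tip_cols)
            ],
            "wrist": {"row": float(self.wrist[0]), "col": float(self.wrist[1])},
            "finger_lengths": [float(v) for v in self.finger_lengths],
            "finger_widths": [float(v) for v in self.finger_widths],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(
        cls, path: str | Path, frame_shape: tuple[int, int] | None = None
    ) -> "HandTemplate":
        """Load a template from YAML.

        The file may store absolute pixel coordinates with its own
        ``frame``, or fractional coordinates (``relative: true``) that are
        scaled to ``frame_shape`` at load time.
        """
        doc = yaml.safe_load(Path(path).read_text())
        return _template_from_doc(doc, frame_shape)


def _template_from_doc(doc: dict, frame_shape: tuple[int, int] | None) -> HandTemplate:
    relative = bool(doc.get("relative", False))
    if relative:
        if frame_shape is None:
            raise ValueError("a relative template needs a target frame_shape")
        m, n = frame_shape
        sr, sc = float(m), float(n)
    else:
        m = int(doc["frame"]["rows"])
        n = int(doc["frame"]["cols"])
        sr = sc = 1.0
        if frame_shape is not None and tuple(frame_shape) != (m, n):
            # rescale an absolute template to the requested frame
            sr = frame_shape[0] / m
            sc = frame_shape[1] / n
            m, n = frame_shape
    tips = doc["tips"]
    rows = np.array([t["row"] * sr for t in tips], dtype=float)
    cols = np.array([t["col"] * sc for t in tips], dtype=float)
    lengths = np.asarray(doc["finger_lengths"], dtype=float) * sr
    widths = np.asarray(doc["finger_widths"], dtype=float) * sc
    wrist = (doc["wrist"]["row"] * sr, doc["wrist"]["col"] * sc)
    return HandTemplate(rows, cols, wrist, lengths, widths, (m, n))


def default_template(frame_shape: tuple[int, int]) -> HandTemplate:
    """The packaged standard-proportion hand pattern scaled to a frame."""
    with resources.files("handspec.data").joinpath("hand_template.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return _template_from_doc(doc, frame_shape)


@dataclass
class MatchResult:
    """Result of the displacement search.

    ``dm, dn`` is the template displacement minimising J; ``j_surface``
    holds J over the whole grid (rows indexed by ``dm_axis``, columns by
    ``dn_axis``) for diagnostics; ``refinements`` are the per-vertex
    residual displacements found by the local search (zeros before
    refinement).
    """

    dm: int
    dn: int
    j_min: float
    j_surface: np.ndarray = field(repr=False)
    dm_axis: np.ndarray = field(repr=False)
    dn_axis: np.ndarray = field(repr=False)
    refinements: np.ndarray = field(default_factory=lambda: np.zeros((5, 2), int))
    refined: bool = False


def _residuals(points: LandmarkSet, template: HandTemplate):
    slots = [s for s in points.tip_slots if template.defined[s]]
    if not slots:
        raise ValueError("no visible landmark has a template counterpart")
    slots = np.asarray(slots)
    rm = points.rows[slots] - template.tip_rows[slots]
    rn = points.cols[slots] - template.tip_cols[slots]
    return slots, rm, rn


def criterion_J(
    points: LandmarkSet,
    template: HandTemplate,
    displacement: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Sum of squared row and column residuals between detected fingertips
    and the (displaced) template fingertips, over visible points."""
    _, rm, rn = _residuals(points, template)
    dm, dn = displacement
    return float(((rm - dm) ** 2).sum() + ((rn - dn) ** 2).sum())


def global_match(
    points: LandmarkSet, template: HandTemplate, range_px: int = 100
) -> MatchResult:
    """Exhaustive integer grid search of the template displacement
    minimising J over ``[-range_px, range_px]^2``.

    Ties break toward the smallest ``|dm| + |dn|``, then lexicographically.
    """
    if range_px < 0:
        raise ValueError("range_px must be >= 0")
    _, rm, rn = _residuals(points, template)
    axis = np.arange(-range_px, range_px + 1)
    jm = ((rm[:, None] - axis[None, :]) ** 2).sum(axis=0)
    jn = ((rn[:, None] - axis[None, :]) ** 2).sum(axis=0)
    surface = jm[:, None] + jn[None, :]
    j_min = float(surface.min())
    ti, tj = np.nonzero(surface == j_min)
    cand = sorted(
        zip(axis[ti], axis[tj]),
        key=lambda d: (abs(d[0]) + abs(d[1]), d[0], d[1]),
    )
    dm, dn = (int(v) for v in cand[0])
    return MatchResult(dm, dn, j_min, surface, axis.copy(), axis.copy())


def refine_vertices(
    points: LandmarkSet,
    template: HandTemplate,
    match: MatchResult,
    local_range_px: int = 25,
) -> MatchResult:
    """Per-vertex adjustment: for each visible fingertip independently,
    grid-search its residual displacement (after the global match) within
    ``+/-local_range_px`` under the single-vertex criterion.

    Total J never increases (each vertex term is minimised separately).
    """
    slots, rm, rn = _residuals(points, template)
    rm = rm - match.dm
    rn = rn - match.dn
    axis = np.arange(-local_range_px, local_range_px + 1)
    refinements = np.zeros((5, 2), int)
    j_total = 0.0
    for s, resm, resn in zip(slots, rm, rn):
        jm = (resm - axis) ** 2
        jn = (resn - axis) ** 2
        bm = int(np.argmin(jm))
        bn = int(np.argmin(jn))
        refinements[s] = (axis[bm], axis[bn])
        j_total += float(jm[bm] + jn[bn])
    return replace(match, refinements=refinements, j_min=j_total, refined=True)


def apply_correction(
    cube: SpectralCube | np.ndarray,
    alpha_deg: float,
    match: MatchResult | None = None,
) -> SpectralCube | np.ndarray:
    """Affine correction: rotate every band by ``alpha_deg`` about the
    frame centre (nearest-neighbour, out-of-frame pixels set to 0), then
    translate by the negated match displacement so the scene lands on the
    template.

    Per-vertex refinements are *not* warped into the image — they only
    shift the region placement downstream (the correction is a single
    global affine transform).
    Accepts a :class:`SpectralCube` or a bare 2-D/3-D array.
    """
    is_cube = isinstance(cube, SpectralCube)
    values = cube.values if is_cube else np.asarray(cube)
    out = rotate_image(values, alpha_deg)
    if match is not None and (match.dm or match.dn):
        out = integer_shift(out, -match.dm, -match.dn)
    if is_cube:
        return SpectralCube(out, cube.wavelengths_nm.copy(), cube.calib_rows)
    return out


def integer_shift(image: np.ndarray, dm: int, dn: int) -> np.ndarray:
    """Shift an array by whole pixels along (rows, cols), filling with 0."""
    out = np.zeros_like(image)
    m, n = image.shape[:2]
    src_r = slice(max(0, -dm), min(m, m - dm))
    src_c = slice(max(0, -dn), min(n, n - dn))
    dst_r = slice(max(0, dm), min(m, m + dm))
    dst_c = slice(max(0, dn), min(n, n + dn))
    if src_r.start < src_r.stop and src_c.start < src_c.stop:
        out[dst_r, dst_c] = image[src_r, src_c]
    return out
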