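"""Synthetic hyperspectral hand phantoms with analytic ground truth.

A phantom scene is a hand-shaped object — palm ellipse, finger capsules
and a forearm stub running toward the frame edge, as in a real push-broom
acquisition of a hand resting on the stage — drawn at an arbitrary
inclination, with per-region melanin/haemoglobin concentrations modulating
a smooth skin reflectance model, a multiplicative across-track
illumination gradient, leading 100%-emission reference rows, and additive
Gaussian plus impulse noise.  Geometry is evaluated analytically per
pixel (no raster resampling), so the truth landmarks, inclination and
concentrations are exact.

The phantom is a test oracle, not a biophysical simulator: absorption
bands are Gaussian bumps with the documented centres and widths, not
radiative-transfer spectra.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .envi import SpectralCube
from .geometry import LandmarkSet
from .matching import HandTemplate

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "skin_reflectance",
    "baseline_reflectance",
    "generate_hand_mask",
    "generate_cube",
    "template_from_phantom",
    "PALM_LABEL",
]

#: label used for the palm/wrist region in concentration maps
PALM_LABEL = "palm"

# Reflectance model constants: a smooth baseline rising toward the NIR,
# a broad melanin absorption over ~450-600 nm and haemoglobin absorption
# bands at the Soret (420 nm) and the 542/577 nm pair.
_MELANIN_CENTER, _MELANIN_WIDTH, _MELANIN_DEPTH = 525.0, 75.0, 0.45
_HAEM_BANDS = ((420.0, 18.0, 0.9), (542.0, 15.0, 0.5), (577.0, 12.0, 0.45))
_HAEM_DEPTH = 0.4


def _finger_label(i: int) -> str:
    return f"finger_{i + 1}"


@dataclass
class PhantomSpec:
    """Parameters of a synthetic hand scene.

    Geometry is given in pixels at the scene's own resolution; the default
    frame (128 x 196, 200 bands over 397-1030 nm) is a scaled-down
    acquisition that keeps finger widths at roughly 6% of the frame width,
    matching the proportions of a full-frame hand image.
    """

    rows: int = 128
    cols: int = 196
    wl_start: float = 397.0
    wl_step: float = 3.18
    wl_stop: float = 1030.0
    finger_count: int = 5
    finger_lengths: tuple[float, ...] = (30.0, 38.0, 42.0, 36.0, 28.0)
    finger_widths: tuple[float, ...] = (13.0, 12.0, 12.0, 11.0, 10.0)
    finger_spacing: float = 18.0
    palm_axes: tuple[float, float] = (26.0, 22.0)
    forearm_length: float = 28.0
    forearm_width: float = 30.0
    rotation_deg: float = 90.0
    melanin: Mapping[str, float] = field(
        default_factory=lambda: {
            PALM_LABEL: 0.25,
            "finger_1": 0.15,
            "finger_2": 0.22,
            "finger_3": 0.30,
            "finger_4": 0.38,
            "finger_5": 0.45,
        }
    )
    haemoglobin: Mapping[str, float] = field(
        default_factory=lambda: {
            PALM_LABEL: 0.35,
            "finger_1": 0.28,
            "finger_2": 0.30,
            "finger_3": 0.32,
            "finger_4": 0.34,
            "finger_5": 0.36,
        }
    )
    axial_gain: float = 0.0
    illum_gradient: float = 0.10
    noise_sd: float = 0.01
    impulse_fraction: float = 0.001
    calib_rows: int = 4
    background_reflectance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (3 <= self.finger_count <= 5):
            raise ValueError("finger_count must be 3..5")
        if len(self.finger_lengths) < self.finger_count or len(
            self.finger_widths
        ) < self.finger_count:
            raise ValueError("finger_lengths/widths shorter than finger_count")
        if not (0 < self.rotation_deg < 180):
            raise ValueError("rotation_deg must lie in (0, 180)")
        if any(w <= 0 for w in self.finger_widths) or any(
            l <= 0 for l in self.finger_lengths
        ):
            raise ValueError("finger dimensions must be positive")
        if max(self.finger_widths[: self.finger_count]) > 200:
            raise ValueError("finger widths above 200 px break the opening step")
        for name in ("melanin", "haemoglobin"):
            conc = getattr(self, name)
            if any(not (0.0 <= c <= 1.0) for c in conc.values()):
                raise ValueError(f"{name} concentrations must lie in [0, 1]")
        if not (0.0 <= self.illum_gradient < 0.5):
            raise ValueError("illum_gradient must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.impulse_fraction <= 0.05):
            raise ValueError("impulse_fraction must lie in [0, 0.05]")
        if self.calib_rows < 0:
            raise ValueError("calib_rows must be >= 0")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        n = int(np.floor((self.wl_stop - self.wl_start) / self.wl_step)) + 1
        return self.wl_start + self.wl_step * np.arange(n)

    @property
    def region_labels(self) -> list[str]:
        return [_finger_label(i) for i in range(self.finger_count)] + [PALM_LABEL]


@dataclass
class PhantomTruth:
    """Exact ground truth of a generated scene."""

    mask: np.ndarray
    landmarks: LandmarkSet
    rotation_deg: float
    alignment_deg: float
    area_concentrations: pd.DataFrame
    label_map: np.ndarray = field(repr=False)
    axis_position: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# reflectance model
# ---------------------------------------------------------------------------

def baseline_reflectance(wavelength_nm):
    """Chromophore-free skin reflectance: smooth, rising toward the NIR."""
    lam = np.asarray(wavelength_nm, dtype=float)
    return 0.45 + 0.35 / (1.0 + np.exp(-(lam - 600.0) / 60.0))


def skin_reflectance(melanin, haemoglobin, wavelength_nm):
    """Reflectance of skin with the given chromophore concentrations.

    ``baseline - melanin * broad 450-600 nm absorption - haemoglobin *
    Soret/542/577 nm absorption``, clipped to [0, 1].  Strictly decreasing
    in each concentration at its band centre.  Inputs broadcast.
    """
    mel = np.asarray(melanin, dtype=float)
    hb = np.asarray(haemoglobin, dtype=float)
    if np.any(mel < 0) or np.any(mel > 1) or np.any(hb < 0) or np.any(hb > 1):
        raise ValueError("concentrations must lie in [0, 1]")
    lam = np.asarray(wavelength_nm, dtype=float)
    mel_abs = np.exp(-(((lam - _MELANIN_CENTER) / _MELANIN_WIDTH) ** 2))
    hb_abs = np.zeros_like(lam)
    for center, width, weight in _HAEM_BANDS:
        hb_abs = hb_abs + weight * np.exp(-(((lam - center) / width) ** 2))
    r = (
        baseline_reflectance(lam)
        - _MELANIN_DEPTH * mel * mel_abs
        - _HAEM_DEPTH * hb * hb_abs
    )
    return np.clip(r, 0.0, 1.0)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _canonical_geometry(spec: PhantomSpec) -> dict:
    """Scene layout in the canonical (upright, fingers toward row 0) pose.

    Rows ``[0, calib_rows)`` are reserved for the reference strip; the hand
    is centred in the remaining frame so that rotation about the frame
    centre keeps it in view at any inclination.
    """
    k = spec.finger_count
    lengths = np.asarray(spec.finger_lengths[:k], dtype=float)
    widths = np.asarray(spec.finger_widths[:k], dtype=float)
    a_r, a_c = spec.palm_axes
    lmax = float(lengths.max() + widths.max() / 2.0)

    center = np.array([(spec.rows - 1) / 2.0, (spec.cols - 1) / 2.0])
    # palm centre placed so that the fingertip-to-forearm extent is centred
    top_rel = -(0.7 * a_r + lmax)
    bottom_rel = 0.7 * a_r + spec.forearm_length
    palm_row = center[0] - (top_rel + bottom_rel) / 2.0
    palm_col = center[1]

    base_row = palm_row - 0.7 * a_r
    offsets = (np.arange(k) - (k - 1) / 2.0) * spec.finger_spacing
    base = np.stack([np.full(k, base_row), palm_col + offsets], axis=1)
    tip = base.copy()
    tip[:, 0] -= lengths
    return {
        "center": center,
        "palm": np.array([palm_row, palm_col]),
        "palm_axes": (a_r, a_c),
        "base": base,
        "tip": tip,
        "lengths": lengths,
        "widths": widths,
        "forearm_end": np.array([palm_row + 0.7 * a_r + spec.forearm_length, palm_col]),
    }


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _scene_transform(spec: PhantomSpec):
    """Forward map canonical -> scene coordinates (rotation about centre).

    ``rotation_deg = 90`` is the upright canonical pose itself; other
    values incline the hand.  The inverse rotation that re-erects the
    scene (what the rotation search should find) is
    ``alignment_deg = (90 - rotation_deg) mod 180``.
    """
    geo = _canonical_geometry(spec)
    delta = spec.rotation_deg - 90.0
    rot = _rotation_matrix(delta)

    def forward(points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - geo["center"]) @ rot.T + geo["center"]

    def inverse(points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - geo["center"]) @ rot + geo["center"]

    return geo, forward, inverse


def _capsule_distance(mc, nc, p0, p1):
    """Distance from canonical points (mc, nc) to the segment p0-p1."""
    d = p1 - p0
    den = float(d @ d)
    t = ((mc - p0[0]) * d[0] + (nc - p0[1]) * d[1]) / den if den > 0 else 0.0
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(mc - (p0[0] + t * d[0]), nc - (p0[1] + t * d[1]))


def generate_hand_mask(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render the binary hand mask and its exact ground truth.

    Deterministic (the mask involves no randomness).  Raises if the
    rotated geometry leaves the frame, naming the offending finger.
    """
    geo, forward, inverse = _scene_transform(spec)
    k = spec.finger_count

    # bounds check on the rotated extreme points
    extremes = []
    for i in range(k):
        t = geo["tip"][i].copy()
        t[0] -= geo["widths"][i] / 2.0
        extremes.append((f"finger {i + 1}", t))
    pr, pc = geo["palm"]
    a_r, a_c = geo["palm_axes"]
    extremes += [
        ("palm", np.array([pr - a_r, pc])),
        ("palm", np.array([pr + a_r, pc])),
        ("palm", np.array([pr, pc - a_c])),
        ("palm", np.array([pr, pc + a_c])),
        ("forearm", geo["forearm_end"] + [0.0, -spec.forearm_width / 2.0]),
        ("forearm", geo["forearm_end"] + [0.0, spec.forearm_width / 2.0]),
    ]
    for name, pt in extremes:
        (r, c), = forward(pt)
        if not (spec.calib_rows <= r < spec.rows and 0 <= c < spec.cols):
            raise ValueError(
                f"{name} leaves the frame at rotation {spec.rotation_deg} deg "
                f"(point ({r:.1f}, {c:.1f}))"
            )

    mm, nn = np.indices((spec.rows, spec.cols))
    pts = np.stack([mm.ravel(), nn.ravel()], axis=1).astype(float)
    canon = inverse(pts)
    mc, nc = canon[:, 0], canon[:, 1]

    inside = (((mc - pr) / a_r) ** 2 + ((nc - pc) / a_c) ** 2) <= 1.0
    label = np.where(inside, k + 1, 0)  # palm = finger_count+1, background = 0

    # forearm stub (labelled as palm region)
    fa0 = geo["palm"] + np.array([0.5 * a_r, 0.0])
    fa1 = geo["forearm_end"]
    fa_dist = _capsule_distance(mc, nc, fa0, fa1)
    label = np.where((fa_dist <= spec.forearm_width / 2.0) & (label == 0), k + 1, label)

    axis_t = np.zeros(mc.size)  # along-finger position, 0 at tip, 1 at base
    for i in range(k):
        p_tip, p_base = geo["tip"][i], geo["base"][i]
        dist = _capsule_distance(mc, nc, p_tip, p_base)
        in_finger = dist <= geo["widths"][i] / 2.0
        label = np.where(in_finger, i + 1, label)
        # along-finger position: 0 at the fingertip apex, 1 one finger
        # length below it (the span region statistics are computed over)
        t = (mc - (p_tip[0] - geo["widths"][i] / 2.0)) / geo["lengths"][i]
        axis_t = np.where(in_finger, np.clip(t, 0.0, 1.0), axis_t)

    label_map = label.reshape(spec.rows, spec.cols)
    # reference strip is never part of the scene
    label_map[: spec.calib_rows, :] = 0
    axis_map = axis_t.reshape(spec.rows, spec.cols)
    mask = (label_map > 0).astype(np.uint8)

    # ground-truth landmarks: fingertip apices (pulled one pixel inward so
    # the rounded landmark always lies on the mask) and the palm centre
    tips_canon = geo["tip"].copy()
    tips_canon[:, 0] -= geo["widths"] / 2.0 - 1.0
    tips = forward(tips_canon)
    wrist = forward(geo["palm"])[0]
    rows6 = np.full(6, np.nan)
    cols6 = np.full(6, np.nan)
    vis6 = np.zeros(6, bool)
    order = np.argsort(tips[:, 1])  # slots ordered by scene column
    for slot, idx in enumerate(order):
        rows6[slot], cols6[slot] = tips[idx]
        vis6[slot] = True
    rows6[5], cols6[5] = wrist
    vis6[5] = True
    landmarks = LandmarkSet(rows6, cols6, vis6)

    conc = pd.DataFrame(
        {
            "label": spec.region_labels,
            "melanin": [spec.melanin[l] for l in spec.region_labels],
            "haemoglobin": [spec.haemoglobin[l] for l in spec.region_labels],
        }
    )
    truth = PhantomTruth(
        mask=mask,
        landmarks=landmarks,
        rotation_deg=spec.rotation_deg,
        alignment_deg=(90.0 - spec.rotation_deg) % 180.0,
        area_concentrations=conc,
        label_map=label_map,
        axis_position=axis_map,
    )
    return mask, truth


# ---------------------------------------------------------------------------
# cube synthesis
# ---------------------------------------------------------------------------

def illumination_field(spec: PhantomSpec) -> np.ndarray:
    """Across-track multiplicative illumination profile, one value per
    column: a linear ramp from ``1 - a`` to ``1 + a``."""
    if spec.cols == 1:
        return np.ones(1)
    u = np.arange(spec.cols) / (spec.cols - 1)
    return 1.0 + spec.illum_gradient * (2.0 * u - 1.0)


def generate_cube(spec: PhantomSpec) -> tuple[SpectralCube, PhantomTruth]:
    """Synthesise the hyperspectral cube for a phantom scene.

    Per-pixel spectrum = region reflectance x along-finger gain x
    illumination, plus Gaussian noise and impulse (dead/saturated) pixels;
    the leading ``calib_rows`` rows image the 100%-emission reference.
    Deterministic given ``spec.seed`` (bit-identical float32 cubes).
    """
    mask, truth = generate_hand_mask(spec)
    wl = spec.wavelengths_nm
    k = spec.finger_count

    # per-region spectra (region id 0 = background)
    spectra = np.empty((k + 2, wl.size))
    spectra[0] = spec.background_reflectance
    for i, lab in enumerate(spec.region_labels):
        spectra[i + 1] = skin_reflectance(
            spec.melanin[lab], spec.haemoglobin[lab], wl
        )

    base = spectra[truth.label_map]  # (rows, cols, bands)

    gain = np.ones((spec.rows, spec.cols))
    if spec.axial_gain != 0.0:
        finger = (truth.label_map >= 1) & (truth.label_map <= k)
        gain[finger] = 1.0 + spec.axial_gain * truth.axis_position[finger]
        gain[truth.label_map == k + 1] = 1.0 + spec.axial_gain

    values = base * gain[:, :, None]
    if spec.calib_rows:
        values[: spec.calib_rows, :, :] = 1.0
    values *= illumination_field(spec)[None, :, None]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    if spec.impulse_fraction > 0:
        n_imp = int(round(spec.impulse_fraction * values.size))
        if n_imp:
            flat = values.reshape(-1)
            idx = rng.choice(flat.size, size=n_imp, replace=False)
            flat[idx] = rng.integers(0, 2, size=n_imp).astype(float)

    cube = SpectralCube(
        values.astype(np.float32), wl, calib_rows=spec.calib_rows
    )
    return cube, truth


def template_from_phantom(spec: PhantomSpec) -> HandTemplate:
    """Anthropometric pattern of the phantom population: the canonical
    (upright) landmark layout of a scene, used as the matching template."""
    upright = replace(spec, rotation_deg=90.0)
    _, truth = generate_hand_mask(upright)
    k = spec.finger_count
    tip_rows = truth.landmarks.rows[:5].copy()
    tip_cols = truth.landmarks.cols[:5].copy()
    lengths = np.full(5, np.nan)
    widths = np.full(5, np.nan)
    lengths[:k] = spec.finger_lengths[:k]
    widths[:k] = spec.finger_widths[:k]
    return HandTemplate(
        tip_rows=tip_rows,
        tip_cols=tip_cols,
        wrist=(float(truth.landmarks.rows[5]), float(truth.landmarks.cols[5])),
        finger_lengths=lengths,
        finger_widths=widths,
        frame_shape=(spec.rows, spec.cols),
    )
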