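# Methods

## Problem and processing model

The package measures the spatial distribution of two skin chromophores on
the dorsal hand from a VNIR hyperspectral cube. Melanin attenuates
reflectance broadly over ~450–600 nm; haemoglobin absorbs over
~397–500 nm (the Soret band near 420 nm and the 542/577 nm pair). The
measurement itself is deliberately simple — a per-pixel sum of corrected
reflectance bands over each range — because the scientific value lies in
*where* it is measured: the pipeline localises the hand, its inclination
and its fingers automatically, so the same anatomical areas are compared
across acquisitions without operator input. No absorbance conversion,
spectral unmixing or oxy/deoxy separation is attempted; the maps are
reflectance-band sums, and higher chromophore content appears as *lower*
band intensity.

Conventions used throughout: 0-based (row, column) coordinates with row 0
at top; after rotation correction the hand is upright — fingers point
toward row 0, fingertips occupy distinct columns, each finger's axis runs
along rows.

## Stages and parameters

| Parameter | Default | Meaning |
|---|---|---|
| `median_size` | 3 px | square median mask; rejects optical-path impulse noise without erasing small real structure |
| `mean_size` | 30 px | moving-average mask for illumination flattening (twice the largest small-object scale) |
| `downscale_factor` | 0.1 | working resolution for geometry (899×1312 → 90×131); phantom-scale scenes use 0.5 |
| `rotation_step_deg` | 1° | grid over (0°, 180°) for the inclination search |
| `se_size_fullres` | 201 px | square structuring element, wider than any finger at full resolution; scaled by the downscale factor (odd-forced) when applied to the working mask |
| `match_range_px` | ±100 px | exhaustive displacement grid for criterion J |
| `refine_range_px` | ±25 px | per-vertex refinement grid |
| melanin band | [450, 600] nm | closed interval; 189 bands on the 0.79 nm camera grid |
| haemoglobin band | [397, 500] nm | closed interval (the alternative 350 nm lower bound is below camera support) |

Wavelength intervals are **closed**; on the 0.79 nm grid no sample falls
exactly on a bound, so the choice is observationally neutral there and is
fixed for determinism. Calibration divides each band, per column, by the
mean of the leading white-reference rows (standard push-broom flat-field
practice; dark reference assumed zero; near-zero references floored).
Normalisation is an error on a constant band so dead bands surface
instead of silently becoming zeros. Illumination removal subtracts the
30×30 moving average; outside the region where the window fits, replicate
padding keeps the output full-size, and oracle comparisons are restricted
to the interior valid region. The binarisation threshold is Otsu's
between-class-variance maximum on a 256-bin histogram of values rescaled
to [0, 1], mapped back to the original range, with the strict `>`
comparison of the silhouette rule.

**Which image feeds which stage.** The flattened image (`L_C`) drives the
rotation criterion, where a smooth illumination gradient would otherwise
bias column sums. The silhouette for binarisation, contour landmarks,
opening and the wrist centroid is thresholded from the λ-summed
*normalized* image (`L_P`, reference rows excluded): mean-subtraction
with a 30-px mask hollows any region wider than the mask — the palm — so
a threshold on `L_C` cannot produce the filled hand shape those stages
require. On textured real skin the two choices converge; on clean data
only the brightness silhouette is well-defined.

**Landmark correspondence.** Detected fingertips are assigned to slots
V1…V5 in column order (thumb side first). When fewer than five minima
survive the prominence/separation rules (e.g. the thumb outside the
frame), the remaining slots are flagged not-visible and excluded from J;
the assignment of a partial detection to specific fingers is by column
order only, which is a known limitation for hands missing a middle
finger from view. Minima prominence defaults to 5% of the working-image
height and minimum separation to half the widest template finger at
working resolution.

**Matching.** The template moves; the image is corrected by the opposite
displacement. Criterion J is the sum of squared row and column residuals
(the square root is omitted — the argmin is identical). Ties break toward
the smallest |Δm|+|Δn|, then lexicographically. Per-vertex refinements
adjust only the placement of the region partition; the image itself
receives one global rotation + translation (nearest-neighbour, zeros
outside the frame).

**Regions.** Each visible finger is delimited from its (refined) tip
landmark toward the palm by the template's finger length and split into
six equal half-open segments along the axis; each segment is divided by
the per-row centreline (centroid column of the finger's mask pixels in
that row) into side A (smaller columns, thumb side) and side B. Because
the centreline follows the actual mask, the split tolerates a few degrees
of residual inclination. "STD" in the tables is the population standard
deviation of pixel values within the area (the standard error of the mean
would be orders of magnitude smaller at thousands of pixels per area and
would not match the printed magnitudes of comparable studies); the SEM is
tabulated alongside for transparency. The along-finger trend reports, per
finger, the mean map value per axis row and a wrist-end/tip-end ratio
read off a least-squares line fitted to that curve (robust to
single-row noise; exactly 1 for a constant map). When one number is
needed, the across-finger median of the ratio is used.

## The phantom: what it emulates, what it does not

A phantom scene is a palm ellipse, 3–5 finger capsules, and a forearm
stub running toward the frame edge (as when the arm rests on the stage),
drawn analytically at an arbitrary inclination — membership of every
pixel is evaluated in closed form, so the ground-truth mask, landmarks
and inclination carry no resampling error. Truth fingertip landmarks sit
one pixel inside the capsule apex so their rounded coordinates always lie
on the mask. Reflectance is a smooth baseline rising toward the NIR minus
Gaussian absorption bumps — melanin centred at 525 nm (width 75 nm),
haemoglobin at 420/542/577 nm — scaled by per-region concentrations in
[0, 1]. The spectral shapes are *not* radiative-transfer skin models
(no Kubelka–Munk, no photon transport); they are analytic stand-ins with
the documented band structure, which is exactly what the downstream
band-sum measurement needs for verification. Multiplicative illumination
is a linear across-track ramp (±10% by default) captured by the leading
100%-emission reference rows, which is what in-frame calibration can
remove; Gaussian noise (σ = 0.01) and impulse pixels (0.1%) emulate
sensor defects. An optional `axial_gain` programs a linear tip-to-wrist
reflectance increase along each finger (span-normalised to the finger
length measured from the apex) for trend-recovery experiments.

Default scene: 128×196 px, 200 bands over 397–1030 nm (3.18 nm step),
finger widths ~6% of frame width — the proportions of a full-frame hand
acquisition at reduced scale. Pipeline runs on phantoms therefore use
`downscale_factor=0.5` and `se_size_fullres=27` (2 × max finger width
+ 1), the scale-equivalents of the full-frame 0.1 / 201 defaults.

Passing phantom tests demonstrates the geometric and statistical chain
end to end with exact truth; it does not validate the spectral biology of
real skin, inter-patient variability, specular artefacts, or hands with
jewellery/overlapping fingers.

## Numerical choices

- Nearest-neighbour everywhere resampling occurs (downscale, rotation),
  keeping the chain integer-exact where possible and consistent across
  stages; out-of-frame pixels are 0.
- The downscale source index is `floor(i / factor)`; output dims are
  `round(dim × factor)` (899×1312 → 90×131).
- Binary opening is implemented as separable sliding-window min then max
  (outside = 0), bit-identical to the naive erosion/dilation oracle.
- ENVI round trips are bit-exact for float32; BIL is the acquisition
  order of push-broom cameras (each spatial row written for every
  wavelength). Byte order defaults to little-endian when absent; unknown
  header keys are preserved, never fatal.
- Determinism: a single integer seed drives all phantom randomness
  (`numpy` PCG64); pipeline outputs are byte-identical across reruns of
  the same (input, config, seed).

## Known limitations

**Inclination is recovered only coarsely — by design of the criterion.**
The rotation score (max over columns of the column sums of the rotated
image) is, in the continuum, the longest projection of the silhouette
along the column direction. For a limb of width *w* embedded in a hand of
length *T*, the maximising set is a plateau of half-width ≈ atan(w/T) —
about ±5° for real hand proportions (w/T ≈ 0.1) and for the phantom
alike, at any image resolution. Within that plateau the discrete argmax
is decided by nearest-neighbour resampling jitter. Measured on noiseless
phantoms across nine poses, recovery errors are 1–13° at a 1° grid; a
plateau-centroid variant reduces but does not eliminate this. The
pipeline therefore treats α\* as a rough pre-alignment: landmark
detection, matching refinement and the mask-following centreline all
tolerate a several-degree residual, and every recovery test downstream of
rotation evaluates its own stage in the recovered frame rather than
assuming perfect alignment. Sub-degree rotation refinement is explicitly
out of scope.

Other limitations: no elastic/thin-plate warping (translation-only
matching plus per-vertex region shifts); no scale search beyond what the
template encodes; finger identity for partial detections is by column
order only; compressed ENVI and vendor-proprietary raw formats are not
supported.
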