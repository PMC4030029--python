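"""Finger area partition, per-area statistics, profiles and trends."""
import numpy as np
import pytest

from handspec.chromophores import ChromophoreMap
from handspec.envi import SpectralCube
from handspec.geometry import LandmarkSet
from handspec.matching import HandTemplate
from handspec.regions import (
    along_finger_trend,
    area_labels,
    area_stats,
    partition_finger,
    spectral_profile,
)


def _rect_scene(length=24, width=8, tip=(4, 10), shape=(40, 28)):
    """An axis-aligned rectangular synthetic finger plus its landmark set
    and matching template."""
    mask = np.zeros(shape, np.uint8)
    r0, c0 = tip
    mask[r0 : r0 + length, c0 - width // 2 : c0 + width // 2] = 1
    rows = np.full(6, np.nan)
    cols = np.full(6, np.nan)
    vis = np.zeros(6, bool)
    rows[0], cols[0], vis[0] = r0, c0 - 0.5, True
    lm = LandmarkSet(rows, cols, vis)
    template = HandTemplate(
        tip_rows=np.array([float(r0), np.nan, np.nan, np.nan, np.nan]),
        tip_cols=np.array([float(c0 - 0.5), 1.0, 2.0, 3.0, 4.0]),
        wrist=(float(shape[0] - 2), float(c0)),
        finger_lengths=np.array([float(length)] + [np.nan] * 4),
        finger_widths=np.array([float(width)] + [np.nan] * 4),
        frame_shape=shape,
    )
    return mask, lm, template


class TestPartitionFinger:
    def test_twelve_areas_six_per_side(self):
        mask, lm, template = _rect_scene()
        part = partition_finger(mask, lm, template, 0)
        labels = [lab for lab in area_labels() if part.pixels(lab)[0].size > 0]
        assert len(labels) == 12
        assert sum(lab.startswith("A") for lab in labels) == 6
        assert sum(lab.startswith("B") for lab in labels) == 6

    def test_symmetric_rectangle_has_mirrored_counts(self):
        mask, lm, template = _rect_scene(width=8)
        part = partition_finger(mask, lm, template, 0)
        for j in range(1, 7):
            na = part.pixels(f"A{j}")[0].size
            nb = part.pixels(f"B{j}")[0].size
            assert na == nb > 0

    def test_disjoint_cover_of_finger_region(self):
        mask, lm, template = _rect_scene(length=23, width=7)
        part = partition_finger(mask, lm, template, 0)
        # union of all areas == finger region; area ids partition by construction,
        # so a pixel-exhaustive check reduces to: every finger pixel has exactly
        # one non-zero area id and nothing outside carries one
        covered = part.area_map > 0
        np.testing.assert_array_equal(covered, part.finger_mask)
        total = sum(part.pixels(lab)[0].size for lab in area_labels())
        assert total == int(part.finger_mask.sum())

    def test_invisible_finger_skipped_with_warning(self):
        mask, lm, template = _rect_scene()
        lm.visible[0] = False
        with pytest.warns(UserWarning, match="not visible"):
            assert partition_finger(mask, lm, template, 0) is None


class TestAreaStats:
    def test_constant_map(self):
        mask, lm, template = _rect_scene()
        part = partition_finger(mask, lm, template, 0)
        cmap = ChromophoreMap(np.full(mask.shape, 0.7), 450, 600, 10)
        df = area_stats(cmap, part)
        np.testing.assert_allclose(df["mean"], 0.7)
        np.testing.assert_array_equal(df["std"], 0.0)
        assert list(df["area"]) == area_labels()

    def test_matches_two_pass_loop_oracle(self, rng):
        mask, lm, template = _rect_scene()
        part = partition_finger(mask, lm, template, 0)
        cmap = ChromophoreMap(rng.random(mask.shape), 450, 600, 10)
        df = area_stats(cmap, part).set_index("area")
        for lab in area_labels():
            r, c = part.pixels(lab)
            vals = [cmap.values[i, j] for i, j in zip(r, c)]
            mean = sum(vals) / len(vals)
            var = sum((v - mean) ** 2 for v in vals) / len(vals)
            assert df.loc[lab, "mean"] == pytest.approx(mean)
            assert df.loc[lab, "std"] == pytest.approx(var**0.5)
            assert df.loc[lab, "count"] == len(vals)

    def test_affine_equivariance(self, rng):
        mask, lm, template = _rect_scene()
        part = partition_finger(mask, lm, template, 0)
        vals = rng.random(mask.shape)
        d1 = area_stats(ChromophoreMap(vals, 450, 600, 10), part)
        d2 = area_stats(ChromophoreMap(2.0 * vals + 3.0, 450, 600, 10), part)
        np.testing.assert_allclose(d2["mean"], 2.0 * d1["mean"] + 3.0)
        np.testing.assert_allclose(d2["std"], 2.0 * d1["std"])

    def test_mirror_symmetry_swaps_sides(self, rng):
        """Reflecting mask and map across the finger axis exchanges the A
        and B statistics exactly (even-width finger, axis between pixels)."""
        mask, lm, template = _rect_scene(width=8, tip=(4, 10))
        part = partition_finger(mask, lm, template, 0)
        vals = rng.random(mask.shape)
        df = area_stats(ChromophoreMap(vals, 450, 600, 10), part).set_index("area")
        # reflect about the centreline column c = 9.5 -> n' = 19 - n
        vals_ref = vals[:, ::-1].copy()
        mask_ref = mask[:, ::-1].copy()
        shift = mask.shape[1] - 1 - 2 * 9.5  # column of the axis after flip
        lm_ref = LandmarkSet(
            lm.rows.copy(), (mask.shape[1] - 1) - lm.cols, lm.visible.copy()
        )
        template_ref = HandTemplate(
            template.tip_rows.copy(),
            np.where(
                np.isfinite(template.tip_cols),
                (mask.shape[1] - 1) - template.tip_cols,
                np.nan,
            ),
            ((template.wrist[0]), (mask.shape[1] - 1) - template.wrist[1]),
            template.finger_lengths.copy(),
            template.finger_widths.copy(),
            template.frame_shape,
        )
        part_ref = partition_finger(mask_ref, lm_ref, template_ref, 0)
        df_ref = area_stats(
            ChromophoreMap(vals_ref, 450, 600, 10), part_ref
        ).set_index("area")
        for j in range(1, 7):
            assert df_ref.loc[f"A{j}", "mean"] == pytest.approx(df.loc[f"B{j}", "mean"])
            assert df_ref.loc[f"B{j}", "std"] == pytest.approx(df.loc[f"A{j}", "std"])


class TestSpectralProfile:
    def _cube(self, values):
        wl = 440.0 + 20.0 * np.arange(values.shape[2])
        return SpectralCube(values, wl)

    def test_constant_cube_gives_flat_profile(self):
        mask, lm, template = _rect_scene()
        part = partition_finger(mask, lm, template, 0)
        cube = self._cube(np.full(mask.shape + (4,), 0.3))
        prof = spectral_profile(cube, part, band_range=(440.0, 500.0))
        np.testing.assert_allclose(prof.grid, 0.3)
        np.testing.assert_allclose(prof.band_curve, 0.3)

    def test_matches_per_position_loop_oracle(self, rng):
        mask, lm, template = _rect_scene()
        part = partition_finger(mask, lm, template, 0)
        cube = self._cube(rng.random(mask.shape + (3,)))
        prof = spectral_profile(cube, part, band_range=(440.0, 480.0))
        for p, r in enumerate(prof.positions):
            cols = np.nonzero(part.finger_mask[r])[0]
            for k in range(3):
                expected = np.mean([cube.values[r, c, k] for c in cols])
                assert prof.grid[p, k] == pytest.approx(expected)

    def test_axial_ramp_gives_monotone_band_curve(self):
        mask, lm, template = _rect_scene()
        part = partition_finger(mask, lm, template, 0)
        ramp = np.linspace(0.2, 0.8, mask.shape[0])[:, None, None]
        cube = self._cube(np.broadcast_to(ramp, mask.shape + (3,)).copy())
        prof = spectral_profile(cube, part, band_range=(440.0, 480.0))
        assert np.all(np.diff(prof.band_curve) > 0)


class TestAlongFingerTrend:
    def test_constant_map_ratio_one(self):
        mask, lm, template = _rect_scene()
        part = partition_finger(mask, lm, template, 0)
        cmap = ChromophoreMap(np.full(mask.shape, 0.4), 450, 600, 10)
        trend = along_finger_trend(cmap, {0: part})
        assert trend["wrist_tip_ratio"][0] == pytest.approx(1.0, abs=1e-9)

    def test_linear_ramp_ratio(self):
        mask, lm, template = _rect_scene(length=24, tip=(4, 10))
        part = partition_finger(mask, lm, template, 0)
        vals = np.ones(mask.shape) * np.linspace(1.0, 2.0, mask.shape[0])[:, None]
        cmap = ChromophoreMap(vals, 450, 600, 10)
        trend = along_finger_trend(cmap, {0: part})
        r0, r1 = part.row_span
        expected = vals[r1 - 1, 10] / vals[r0, 10]
        assert trend["wrist_tip_ratio"][0] == pytest.approx(expected, rel=1e-6)

    def test_curve_consistent_with_area_stats(self, rng):
        """Pixel-count-weighted segment averages of the positional curve
        equal the combined A+B area means."""
        mask, lm, template = _rect_scene(length=24)
        part = partition_finger(mask, lm, template, 0)
        cmap = ChromophoreMap(rng.random(mask.shape), 450, 600, 10)
        trend = along_finger_trend(cmap, {0: part})
        stats = area_stats(cmap, part).set_index("area")
        positions = trend["positions"][0]
        curve = trend["curve"][0]
        counts = np.array(
            [part.finger_mask[int(r)].sum() for r in positions], dtype=float
        )
        r0, _ = part.row_span
        seg_len = 4  # 24 rows / 6 segments
        for j in range(6):
            sel = (positions >= r0 + j * seg_len) & (positions < r0 + (j + 1) * seg_len)
            seg_mean = np.average(curve[sel], weights=counts[sel])
            a = stats.loc[f"A{j+1}"]
            b = stats.loc[f"B{j+1}"]
            combined = (a["mean"] * a["count"] + b["mean"] * b["count"]) / (
                a["count"] + b["count"]
            )
            assert seg_mean == pytest.approx(combined)
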