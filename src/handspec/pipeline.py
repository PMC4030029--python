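"""End-to-end orchestration of the hand analysis pipeline.

Stage order: read → calibrate → median → normalize → illumination →
downscale → rotation → binarize → landmarks → wrist → match → correct →
aggregate → partition → stats.  The illumination-removed image feeds the
rotation criterion; the silhouette used for binarisation, landmarks and
the wrist centroid comes from the λ-summed normalized image (brightness
thresholding needs the filled hand, which mean-subtraction hollows out for
regions wider than its mask).

Every run is fully deterministic given (input bytes, configuration, seed)
and produces a machine-readable report with all parameters and per-stage
timings.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import chromophores, envi, geometry, matching, preprocess, regions
from .phantom import PhantomSpec, generate_cube, template_from_phantom

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_fixtures"]

log = logging.getLogger("handspec")

STAGES = [
    "read",
    "calibrate",
    "median",
    "normalize",
    "illumination",
    "downscale",
    "rotation",
    "binarize",
    "landmarks",
    "wrist",
    "match",
    "correct",
    "aggregate",
    "partition",
    "stats",
]


@dataclass
class PipelineConfig:
    """All pipeline parameters.

    Numeric defaults follow the published processing chain: 3-px median
    mask, 30-px mean mask, 10% downscale, 201-px structuring element at
    full resolution, ±100 px matching range, melanin band 450–600 nm,
    haemoglobin band 397–500 nm.
    """

    input_path: str | None = None
    phantom: PhantomSpec | None = None
    median_size: int = 3
    mean_size: int = 30
    downscale_factor: float = 0.1
    rotation_step_deg: float = 1.0
    se_size_fullres: int = 201
    match_range_px: int = 100
    refine_range_px: int = 25
    melanin_range: tuple[float, float] = chromophores.MELANIN_RANGE_NM
    haemoglobin_range: tuple[float, float] = chromophores.HAEMOGLOBIN_RANGE_NM
    minima_prominence: float | None = None
    minima_separation: int | None = None
    template_path: str | None = None
    template: matching.HandTemplate | None = None
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.input_path is None and self.phantom is None:
            raise ValueError("config needs an input_path or a phantom spec")
        if not (0 < self.downscale_factor <= 1):
            raise ValueError("downscale_factor must be in (0, 1]")
        if self.match_range_px < 0 or self.refine_range_px < 0:
            raise ValueError("matching ranges must be >= 0")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("template")
        if d["phantom"] is not None:
            d["phantom"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d["phantom"].items()
                if not isinstance(v, dict)
            } | {
                k: dict(v)
                for k, v in dataclasses.asdict(self.phantom).items()
                if isinstance(v, dict)
            }
        for k in ("melanin_range", "haemoglobin_range"):
            d[k] = list(d[k])
        return d


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    config: PipelineConfig
    cube: envi.SpectralCube
    lp: envi.SpectralCube
    lc_sum: np.ndarray
    rotation: geometry.RotationResult
    work_mask: np.ndarray
    landmarks_work: geometry.LandmarkSet
    landmarks_full: geometry.LandmarkSet
    match: matching.MatchResult
    lp_star: envi.SpectralCube
    corrected_mask: np.ndarray
    melanin: chromophores.ChromophoreMap
    haemoglobin: chromophores.ChromophoreMap
    partitions: dict[int, regions.AreaPartition]
    melanin_stats: pd.DataFrame
    haemoglobin_stats: pd.DataFrame
    trend: pd.DataFrame
    report: dict
    truth: object | None = None


class _Timer:
    def __init__(self) -> None:
        self.records: list[dict] = []

    def stage(self, name: str):
        timer = self

        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, *exc):
                if exc[0] is None:
                    timer.records.append(
                        {
                            "stage": name,
                            "seconds": time.perf_counter() - self_inner.t0,
                            "status": "completed",
                        }
                    )
                return False

        return _Ctx()


def _resolve_template(
    config: PipelineConfig, frame_shape: tuple[int, int]
) -> matching.HandTemplate:
    if config.template is not None:
        return config.template
    if config.template_path is not None:
        return matching.HandTemplate.from_yaml(config.template_path, frame_shape)
    if config.phantom is not None:
        return template_from_phantom(config.phantom)
    return matching.default_template(frame_shape)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full chain on one cube; see the module docstring for the
    stage order.  Any stage error is re-raised with the stage name and the
    input provenance prepended."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    timer = _Timer()
    provenance = config.input_path or "phantom"
    truth = None

    stage_name = "read"
    try:
        with timer.stage("read"):
            if config.phantom is not None:
                phantom_spec = dataclasses.replace(config.phantom, seed=config.seed)
                cube, truth = generate_cube(phantom_spec)
            else:
                cube = envi.load_cube(config.input_path)

        with timer.stage("calibrate"):
            stage_name = "calibrate"
            if cube.calib_rows > 0:
                calibrated = preprocess.calibrate(cube)
            else:
                warnings.warn("no reference rows; skipping calibration")
                calibrated = cube

        with timer.stage("median"):
            stage_name = "median"
            filtered = envi.SpectralCube(
                preprocess.median_filter(calibrated.values, config.median_size),
                calibrated.wavelengths_nm.copy(),
                calibrated.calib_rows,
            )

        with timer.stage("normalize"):
            stage_name = "normalize"
            lp = preprocess.normalize_cube(filtered)

        with timer.stage("illumination"):
            stage_name = "illumination"
            # λ-summed first: removal is linear, so flattening the band sum
            # equals summing per-band flattened images
            lp_sum = lp.band_sum()
            lc_sum = preprocess.remove_illumination(lp_sum, config.mean_size)

        with timer.stage("downscale"):
            stage_name = "downscale"
            # the reference strip is not part of the scene
            seg_rot = np.clip(lc_sum, 0.0, None)
            seg_rot[: lp.calib_rows] = 0.0
            seg_sil = lp_sum.copy()
            seg_sil[: lp.calib_rows] = 0.0
            work_rot = geometry.downscale(seg_rot, config.downscale_factor)
            work_sil = geometry.downscale(seg_sil, config.downscale_factor)

        with timer.stage("rotation"):
            stage_name = "rotation"
            rotation = geometry.estimate_rotation(work_rot, config.rotation_step_deg)

        with timer.stage("binarize"):
            stage_name = "binarize"
            work_upright = geometry.rotate_image(work_sil, rotation.alpha_deg)
            p_r = geometry.otsu_threshold(work_upright)
            work_mask = geometry.binarize(work_upright, p_r)

        with timer.stage("landmarks"):
            stage_name = "landmarks"
            curve = geometry.contour_curve(work_mask)
            template = _resolve_template(config, cube.shape[:2])
            widths = template.finger_widths[np.isfinite(template.finger_widths)]
            if config.minima_separation is not None:
                separation = config.minima_separation
            elif widths.size:
                separation = max(
                    1, int(round(0.5 * widths.max() * config.downscale_factor))
                )
            else:
                separation = 10
            prominence = (
                config.minima_prominence
                if config.minima_prominence is not None
                else 0.05 * work_mask.shape[0]
            )
            lm_work = geometry.find_tip_landmarks(curve, separation, prominence)

        with timer.stage("wrist"):
            stage_name = "wrist"
            se_work = max(3, int(round(config.se_size_fullres * config.downscale_factor)))
            if se_work % 2 == 0:
                se_work += 1
            opened = geometry.opening(work_mask, se_work)
            wrist = geometry.wrist_centroid(opened)
            lm_work = lm_work.with_wrist(*wrist)
            lm_full = geometry.scale_landmarks(lm_work, config.downscale_factor)

        with timer.stage("match"):
            stage_name = "match"
            match = matching.global_match(lm_full, template, config.match_range_px)
            match = matching.refine_vertices(
                lm_full, template, match, config.refine_range_px
            )

        with timer.stage("correct"):
            stage_name = "correct"
            lp_scene = envi.SpectralCube(
                lp.values.copy(), lp.wavelengths_nm.copy(), lp.calib_rows
            )
            lp_scene.values[: lp.calib_rows] = 0.0
            lp_star = matching.apply_correction(lp_scene, rotation.alpha_deg, match)
            star_sum = lp_star.band_sum()
            corrected_mask = geometry.binarize(
                star_sum, geometry.otsu_threshold(star_sum)
            )

        with timer.stage("aggregate"):
            stage_name = "aggregate"
            melanin = chromophores.aggregate_band(
                lp_star, *config.melanin_range, normalized=True
            )
            haemoglobin = chromophores.aggregate_band(
                lp_star, *config.haemoglobin_range, normalized=True
            )

        with timer.stage("partition"):
            stage_name = "partition"
            # fingertips in the corrected frame: template point + refinement
            rows = template.tip_rows + match.refinements[:, 0]
            cols = template.tip_cols + match.refinements[:, 1]
            rows6 = np.append(rows, template.wrist[0])
            cols6 = np.append(cols, template.wrist[1])
            vis6 = np.append(
                lm_full.visible[:5] & template.defined, lm_full.visible[5]
            )
            lm_corr = geometry.LandmarkSet(rows6, cols6, vis6)
            partitions = {}
            for finger in range(5):
                part = regions.partition_finger(
                    corrected_mask, lm_corr, template, finger
                )
                if part is not None:
                    partitions[finger] = part

        with timer.stage("stats"):
            stage_name = "stats"
            mel_stats = _stack_stats(melanin, partitions)
            hb_stats = _stack_stats(haemoglobin, partitions)
            trend = (
                regions.along_finger_trend(melanin, partitions)
                if partitions
                else pd.DataFrame()
            )
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage_name!r} failed for input {provenance!r}: {err}"
        ) from err

    report = {
        "input": provenance,
        "config": config.as_dict(),
        "stages": timer.records,
        "rotation_deg": rotation.alpha_deg,
        "otsu_threshold": float(p_r),
        "displacement": {"dm": match.dm, "dn": match.dn},
        "refinements": match.refinements.tolist(),
        "j_min": match.j_min,
        "landmarks_full": {
            "rows": lm_full.rows.tolist(),
            "cols": lm_full.cols.tolist(),
            "visible": lm_full.visible.tolist(),
        },
        "melanin_bands": melanin.n_bands,
        "haemoglobin_bands": haemoglobin.n_bands,
        "fingers_partitioned": sorted(partitions),
    }

    result = PipelineResult(
        config=config,
        cube=cube,
        lp=lp,
        lc_sum=lc_sum,
        rotation=rotation,
        work_mask=work_mask,
        landmarks_work=lm_work,
        landmarks_full=lm_full,
        match=match,
        lp_star=lp_star,
        corrected_mask=corrected_mask,
        melanin=melanin,
        haemoglobin=haemoglobin,
        partitions=partitions,
        melanin_stats=mel_stats,
        haemoglobin_stats=hb_stats,
        trend=trend,
        report=report,
        truth=truth,
    )
    if config.out_dir is not None:
        _write_artifacts(result, Path(config.out_dir))
    return result


def _stack_stats(
    cmap: chromophores.ChromophoreMap, partitions: dict[int, regions.AreaPartition]
) -> pd.DataFrame:
    frames = []
    for finger, part in sorted(partitions.items()):
        df = regions.area_stats(cmap, part)
        df.insert(0, "finger", finger)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["finger", "area", "mean", "std", "sem", "count"])
    return pd.concat(frames, ignore_index=True)


def _to_png8(values: np.ndarray) -> Image.Image:
    v = np.clip(values, 0.0, 1.0)
    return Image.fromarray((v * 255).round().astype(np.uint8))


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.6f"
    result.melanin_stats.to_csv(
        out_dir / "melanin_stats.csv", index=False, float_format=float_fmt
    )
    result.haemoglobin_stats.to_csv(
        out_dir / "haemoglobin_stats.csv", index=False, float_format=float_fmt
    )
    np.savetxt(
        out_dir / "j_surface.csv", result.match.j_surface, delimiter=",", fmt="%.1f"
    )
    for name, cmap in (
        ("melanin", result.melanin),
        ("haemoglobin", result.haemoglobin),
    ):
        single = envi.SpectralCube(
            cmap.values[:, :, None].astype(np.float32),
            np.array([(cmap.band_lo + cmap.band_hi) / 2.0]),
        )
        envi.save_cube(single, out_dir / f"{name}_map")
        arr16 = (np.clip(cmap.values, 0, 1) * 65535).round().astype(np.uint16)
        Image.fromarray(arr16).save(out_dir / f"{name}_map.png")
    comp = chromophores.composite_rgb(result.melanin, result.haemoglobin)
    Image.fromarray(
        (np.clip(comp, 0, 1) * 255).round().astype(np.uint8), mode="RGB"
    ).save(out_dir / "composite.png")
    trend_rows = []
    for rec in result.trend.to_dict("records"):
        for pos, val in zip(rec["positions"], rec["curve"]):
            trend_rows.append(
                {"finger": rec["finger"], "position": pos, "mean": val}
            )
    pd.DataFrame(trend_rows).to_csv(
        out_dir / "melanin_trend.csv", index=False, float_format=float_fmt
    )
    (out_dir / "report.json").write_text(json.dumps(result.report, indent=2))


def make_fixtures(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a phantom ENVI cube plus its truth sidecar (JSON) to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cube, truth = generate_cube(spec)
    dat, hdr = envi.save_cube(cube, out_dir / "phantom")
    truth_doc = {
        "rotation_deg": truth.rotation_deg,
        "alignment_deg": truth.alignment_deg,
        "landmarks": {
            "rows": truth.landmarks.rows.tolist(),
            "cols": truth.landmarks.cols.tolist(),
            "visible": truth.landmarks.visible.tolist(),
        },
        "area_concentrations": truth.area_concentrations.to_dict("records"),
        "spec": {
            k: (list(v) if isinstance(v, tuple) else (dict(v) if isinstance(v, dict) else v))
            for k, v in dataclasses.asdict(spec).items()
        },
    }
    truth_path = out_dir / "phantom_truth.json"
    truth_path.write_text(json.dumps(truth_doc, indent=2))
    return {"dat": dat, "hdr": hdr, "truth": truth_path}
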