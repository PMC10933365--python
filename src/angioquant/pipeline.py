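"""Single-image and batch orchestration of the full analysis pipeline.

``run_single`` executes load → resample → [median] → [vesselness] →
threshold → skeletonize → diameters → graph → prune → FAZ → regions →
metrics → artefacts, logging every stage's parameters.  A FAZ segmentation
failure does not abort the run: the FAZ fields are left null and ETDRS
regions fall back to the image centre with a logged warning.

``run_batch`` applies the same configuration to every readable image in a
directory, isolating per-image failures, and writes one spreadsheet plus an
intermediates folder per image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import faz as faz_mod
from .binarize import BinaryMap, adaptive_threshold, fuzzy_threshold
from .config import PipelineConfig
from .errors import AngioquantError, FazSegmentationError, ValidationError
from .graph import build_graph, classify_elements, diameter_map, prune_twigs, skeletonize
from .imagery import RasterImage, load_grayscale, resample_to_grid, save_intermediates, write_report
from .metrics import MetricsRecord, compile_metrics
from .preprocess import FrangiSettings, frangi_vesselness, median_filter
from .regions import RegionSet, custom_region, etdrs_grid, nine_squares, whole_image

__all__ = ["SingleRunResult", "run_single", "run_batch", "IMAGE_SUFFIXES"]

log = logging.getLogger("angioquant")

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")

REPORT_COLUMNS = [
    "Image",
    "Region",
    "VAD [%]",
    "VLD [%]",
    "Total VL [mm]",
    "Mean VL [mm]",
    "Median VL [mm]",
    "Mean diameter [um]",
    "Median diameter [um]",
    "Branchpoint density [nodes/mm]",
    "Tortuosity [1]",
    "Fractal dimension [1]",
    "FAZA [mm^2]",
    "FAZ perimeter [mm]",
    "FAZ circularity [1]",
    "FAZ acircularity index [1]",
    "FAZ axis ratio [1]",
    "FD-300 [%]",
    "Config",
]


@dataclass
class SingleRunResult:
    image: str
    records: list[MetricsRecord]
    faz_metrics: "faz_mod.FazMetrics | None"
    artefacts: list[Path]
    rows: list[dict]
    warnings: list[str]


def _segment(img: RasterImage, cfg: PipelineConfig) -> BinaryMap:
    work = img
    if cfg.median_kernel > 0:
        work = median_filter(work, cfg.median_kernel)
        log.info("median filter: kernel %d px", cfg.median_kernel)
    if cfg.frangi_max_kernel > 0:
        work = frangi_vesselness(work, FrangiSettings(max_kernel_px=cfg.frangi_max_kernel))
        log.info("vesselness: max kernel %d px", cfg.frangi_max_kernel)
    if cfg.method == "fuzzy":
        bin_map = fuzzy_threshold(work)
        log.info("fuzzy threshold: %.4f", bin_map.threshold_info["threshold"])
    else:
        window = cfg.adaptive_window if cfg.adaptive_window > 0 else None
        bin_map = adaptive_threshold(work, window, cfg.adaptive_offset)
        log.info("adaptive threshold: %s", bin_map.threshold_info)
    return bin_map


def _segment_faz(
    img: RasterImage, bin_map: BinaryMap, cfg: PipelineConfig, warnings_out: list[str]
):
    if cfg.faz_method == "none":
        return None
    try:
        if cfg.faz_method in ("rapid", "rapid_tuned"):
            mask = faz_mod.rapid_faz(bin_map, cfg.stringency)
            if cfg.faz_method == "rapid_tuned":
                mask = faz_mod.tune_faz(img, mask, cfg.tune_iterations)
        else:  # manual | drawn: vertices from the sidecar CSV
            if not cfg.faz_contour_csv:
                raise FazSegmentationError(
                    f"faz_method={cfg.faz_method!r} needs faz_contour_csv"
                )
            pts = np.loadtxt(cfg.faz_contour_csv, delimiter=",", ndmin=2)
            mask = faz_mod.accept_contour(
                pts, img.shape, img.calibration,
                method="manual" if cfg.faz_method == "manual" else "drawn",
            )
            if cfg.faz_method == "manual":
                mask = faz_mod.tune_faz(img, mask, cfg.tune_iterations)
        return mask
    except (FazSegmentationError, ValidationError, OSError) as exc:
        msg = f"FAZ segmentation failed ({exc}); FAZ metrics null, grid at image centre"
        log.warning(msg)
        warnings_out.append(msg)
        return None


def _build_regions(cfg: PipelineConfig, shape, cal, faz_mask) -> RegionSet:
    if cfg.regions == "whole":
        return RegionSet([], scheme="whole")
    if cfg.regions == "squares":
        return nine_squares(shape)
    if cfg.regions == "custom":
        return custom_region(cfg.custom_rect, shape)
    centre = (
        faz_mod.faz_centroid(faz_mask)
        if faz_mask is not None
        else ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    )
    return etdrs_grid(shape, cal, centre, cfg.eye)


def _rows_from_records(
    image_name: str, records, fazm, cfg: PipelineConfig
) -> list[dict]:
    cfg_json = json.dumps(cfg.as_dict(), sort_keys=True)
    rows = []
    for rec in records:
        rows.append(
            {
                "Image": image_name,
                "Region": rec.region_name,
                "VAD [%]": rec.vad_percent,
                "VLD [%]": rec.vld_percent,
                "Total VL [mm]": rec.total_vl_mm,
                "Mean VL [mm]": rec.mean_vl_mm,
                "Median VL [mm]": rec.median_vl_mm,
                "Mean diameter [um]": rec.mean_d_um,
                "Median diameter [um]": rec.median_d_um,
                "Branchpoint density [nodes/mm]": rec.bd_nodes_per_mm,
                "Tortuosity [1]": rec.tortuosity_mean,
                "Fractal dimension [1]": rec.fd,
                "FAZA [mm^2]": fazm.area_mm2 if fazm else None,
                "FAZ perimeter [mm]": fazm.perimeter_mm if fazm else None,
                "FAZ circularity [1]": fazm.circularity if fazm else None,
                "FAZ acircularity index [1]": fazm.acircularity if fazm else None,
                "FAZ axis ratio [1]": fazm.axis_ratio if fazm else None,
                "FD-300 [%]": fazm.fd300_percent if fazm else None,
                "Config": cfg_json,
            }
        )
    return rows


def run_single(
    cfg: PipelineConfig,
    image_path,
    save_artefacts: bool = True,
) -> SingleRunResult:
    """Run the full pipeline on one image."""
    image_path = Path(image_path)
    warnings_out: list[str] = []
    log.info("processing %s", image_path)
    img = load_grayscale(image_path, cfg.field_width_mm, cfg.field_height_mm)
    img = resample_to_grid(img, cfg.target_grid_px)
    log.info("analysis grid: %d px, pitch %.3f um", cfg.target_grid_px,
             img.calibration.um_per_px)
    bin_map = _segment(img, cfg)
    skel = skeletonize(bin_map)
    dmap = diameter_map(bin_map, skel)
    graph = classify_elements(build_graph(skel, dmap))
    graph, skel = prune_twigs(graph, cfg.twig_size_px, dmap)
    log.info("graph after pruning (twig %d px): %d nodes, %d edges",
             cfg.twig_size_px, len(graph.nodes), len(graph.edges))

    faz_mask = _segment_faz(img, bin_map, cfg, warnings_out)
    fazm = None
    if faz_mask is not None:
        fazm = faz_mod.faz_shape_metrics(faz_mask)
        try:
            fazm.fd300_percent = faz_mod.fd300(bin_map, faz_mask)
        except ValidationError as exc:
            warnings_out.append(f"FD-300 failed: {exc}")

    regions = _build_regions(cfg, img.shape, img.calibration, faz_mask)
    records = compile_metrics(bin_map, skel, dmap, graph, regions)
    rows = _rows_from_records(image_path.name, records, fazm, cfg)

    artefacts: list[Path] = []
    if save_artefacts:
        bundle = {"binary": bin_map.mask, "skeleton": skel.mask}
        if faz_mask is not None:
            bundle["faz_overlay"] = (img.pixels, faz_mask.mask)
        artefacts = save_intermediates(
            bundle, Path(cfg.output_dir) / "intermediates", stem=image_path.stem
        )
    return SingleRunResult(
        image=image_path.name,
        records=records,
        faz_metrics=fazm,
        artefacts=artefacts,
        rows=rows,
        warnings=warnings_out,
    )


def run_batch(cfg: PipelineConfig, dir_path) -> Path:
    """Process every image in a directory with one shared configuration.

    Per-image failures are logged and skipped; the run continues.  Returns
    the path of the combined spreadsheet (a sibling CSV is written too).
    """
    dir_path = Path(dir_path)
    images = sorted(
        p for p in dir_path.iterdir()
        if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file()
    )
    if not images:
        raise ValidationError(f"no readable images in {dir_path}")
    rows: list[dict] = []
    failures: list[str] = []
    for p in images:
        try:
            result = run_single(cfg, p)
            rows.extend(result.rows)
        except (AngioquantError, OSError) as exc:
            log.error("failed on %s: %s", p.name, exc)
            failures.append(p.name)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = write_report(rows, out / "report.xlsx")
    log.info("batch complete: %d processed, %d failed", len(images) - len(failures),
             len(failures))
    if failures:
        (out / "failures.txt").write_text("\n".join(failures) + "\n", encoding="utf-8")
    return report
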