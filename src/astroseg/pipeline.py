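"""End-to-end orchestration: denoise -> normalize -> detect -> segment ->
post-process -> reassemble, with per-stage logging and a JSON run report."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from . import detection as det
from . import postprocess as post
from . import preprocess as pre
from . import segmentation as seg
from .config import PipelineConfig
from .filters import build_filter_bank

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    detection: det.DetectionResult
    segmentation: post.LabeledSegmentation | None
    classes: list[post.ShapeClass] | None
    report: dict


def run_pipeline(image: np.ndarray, config: PipelineConfig | None = None,
                 model: "seg.StackedUNet | None" = None,
                 detection_only: bool = False) -> PipelineResult:
    """Run the full detection-and-segmentation pipeline on one image.

    ``model`` may be omitted only with ``detection_only=True``.  The run
    report counts objects at every stage: detected, segmented,
    discarded-as-string, final cells.
    """
    config = config or PipelineConfig()
    if model is None and not detection_only:
        raise ValueError("a segmentation model is required unless "
                         "detection_only=True")
    report: dict = {"stages": {}}
    t0 = time.perf_counter()

    fb = config.filters
    bank = build_filter_bank(
        n_scales=fb.n_scales, n_orientations=fb.n_orientations,
        base_kernel_size=fb.base_kernel_size, aspect_ratio=fb.aspect_ratio,
        sigma_fraction=fb.sigma_fraction,
    )

    denoised = pre.denoise(image, bank, config.preprocess)
    normalized = pre.normalize_intensity(denoised, config.preprocess)
    report["stages"]["preprocess"] = {"seconds": time.perf_counter() - t0}
    logger.info("preprocess done in %.2fs", time.perf_counter() - t0)

    t1 = time.perf_counter()
    result = det.detect_cells(
        normalized, bank,
        dr_threshold=config.detection.dr_threshold,
        min_blob_area=config.detection.min_blob_area,
        patch_size=config.detection.patch_size,
    )
    report["stages"]["detection"] = {
        "seconds": time.perf_counter() - t1,
        "detected": len(result),
    }
    report["detected"] = len(result)
    logger.info("detected %d cells in %.2fs", len(result),
                time.perf_counter() - t1)

    if detection_only:
        report["final_cells"] = len(result)
        report["total_seconds"] = time.perf_counter() - t0
        return PipelineResult(detection=result, segmentation=None,
                              classes=None, report=report)

    t2 = time.perf_counter()
    profile_bank = post.build_profile_bank(n_orientations=fb.n_orientations)
    patch = config.detection.patch_size
    masks: list[tuple[np.ndarray, tuple[int, int, int]]] = []
    classes: list[post.ShapeClass] = []
    pp = config.postprocess
    for i in range(len(result)):
        patch_img = result.extract_patch(normalized, i)
        mask = seg.segment_patch(model, patch_img)
        top, left, _ = result.rois[i]
        local_centroid = (result.centroids[i][0] - top,
                          result.centroids[i][1] - left)
        mask = post.keep_central_component(mask, local_centroid,
                                           min_size=pp.min_size)
        target = patch_img if pp.classify_on == "patch" else mask.astype(float)
        profile = post.orientation_profile(target, profile_bank)
        cls = post.classify_star_string(
            profile, prominence_frac=pp.prominence_frac,
            min_separation_deg=pp.min_separation_deg)
        if not mask.any():
            cls = post.ShapeClass(label="string", n_prominent=0, peak_angles=())
        masks.append((mask, (top, left, patch)))
        classes.append(cls)

    labeled = post.reassemble(masks, image.shape, classes)
    n_strings = sum(1 for c in classes if c.label == "string")
    report["stages"]["segmentation"] = {"seconds": time.perf_counter() - t2,
                                        "segmented": len(masks)}
    report["segmented"] = len(masks)
    report["discarded_as_string"] = n_strings
    report["final_cells"] = len(labeled.cell_ids)
    report["total_seconds"] = time.perf_counter() - t0
    logger.info("segmented %d, discarded %d strings, %d final cells",
                len(masks), n_strings, len(labeled.cell_ids))
    return PipelineResult(detection=result, segmentation=labeled,
                          classes=classes, report=report)
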