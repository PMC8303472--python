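"""Pipeline orchestration and the calcium score.

The score of one exam is the set of white (above-adaptive-threshold) pixels
inside the operator-chosen aortic-valve ROI: their count is the proxy for
calcium area, and their mean/median intensity — raw and dark-reference
normalized — summarizes calcium brightness.

Stage order of :func:`run_pipeline`:

1. optionally compensate post-processing gain (outside-sector ROI mean),
2. median-blur the image to suppress speckle before segmentation,
3. estimate the dark reference on the blurred, gain-compensated image
   (the image actually thresholded),
4. binarize at the adaptive threshold (base + dark reference),
5. optionally dilate to recover blob pixels eroded by the blur,
6. collect white-pixel coordinates inside the valve ROI,
7. quantify intensities on the *un-blurred* gain-compensated image — the
   blur informs detection only, never the reported intensities.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .enhance import (EnhanceConfig, as_binary_image, binarize, dilate,
                      median_blur)
from .image import RectROI, ValidationError, as_gray_image
from .normalize import (NormalizationContext, adaptive_threshold,
                        compensate_postproc, estimate_dark_reference,
                        estimate_postproc_gain)

__all__ = [
    "CalciumMask",
    "CalciumReport",
    "PipelineConfig",
    "extract_calcium_mask",
    "quantify",
    "run_pipeline",
    "write_reports_csv",
    "write_report_json",
]


@dataclass(frozen=True)
class CalciumMask:
    """White-pixel coordinates (image frame, row-major order) inside a ROI."""

    roi: RectROI
    coords: np.ndarray  # (n, 2) int array of (row, col)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.intp).reshape(-1, 2)
        object.__setattr__(self, "coords", coords)
        if coords.size:
            rows, cols = coords[:, 0], coords[:, 1]
            inside = ((rows >= self.roi.y0) & (rows < self.roi.y0 + self.roi.height)
                      & (cols >= self.roi.x0) & (cols < self.roi.x0 + self.roi.width))
            if not inside.all():
                raise ValidationError("mask coordinate outside its ROI")
            if len(np.unique(coords, axis=0)) != len(coords):
                raise ValidationError("mask coordinates must be unique")

    @property
    def count(self) -> int:
        return int(self.coords.shape[0])


@dataclass(frozen=True)
class CalciumReport:
    """The per-image calcium score plus its normalization provenance."""

    white_pixel_count: int
    raw_mean: float | None
    raw_median: float | None
    normalized_mean: float | None
    normalized_median: float | None
    effective_threshold: float
    context: NormalizationContext
    component_sizes: tuple[int, ...] = field(default_factory=tuple)
    image_id: str = ""

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "white_pixel_count": self.white_pixel_count,
            "raw_mean": self.raw_mean,
            "raw_median": self.raw_median,
            "normalized_mean": self.normalized_mean,
            "normalized_median": self.normalized_median,
            "effective_threshold": self.effective_threshold,
            "postproc_gain": self.context.postproc_gain,
            "dark_reference": self.context.dark_reference,
            "base_threshold": self.context.base_threshold,
            "component_sizes": list(self.component_sizes),
        }


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one analysis run needs besides the image itself."""

    valve_roi: RectROI
    dark_roi: RectROI
    outside_roi: RectROI | None = None
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    compensate_gain: bool = False
    apply_dilation: bool = True

    def __post_init__(self) -> None:
        if self.compensate_gain and self.outside_roi is None:
            raise ValidationError(
                "gain compensation requested but no outside-sector ROI given")


def extract_calcium_mask(binary: np.ndarray, roi: RectROI) -> CalciumMask:
    """All white pixels of a binary image inside the ROI, row-major order."""
    binary = as_binary_image(binary)
    roi.validate_within(binary.shape)
    sub = binary[roi.slices]
    local = np.argwhere(sub == 255)
    coords = local + np.array([roi.y0, roi.x0])
    return CalciumMask(roi=roi, coords=coords)


def _component_sizes(mask: CalciumMask, shape: tuple[int, int]) -> tuple[int, ...]:
    """Sizes of 8-connected white components, largest first (convenience only)."""
    if mask.count == 0:
        return ()
    canvas = np.zeros(shape, dtype=bool)
    canvas[mask.coords[:, 0], mask.coords[:, 1]] = True
    labels, n = ndimage.label(canvas, structure=np.ones((3, 3), dtype=bool))
    sizes = np.bincount(labels.ravel())[1:]
    return tuple(sorted((int(s) for s in sizes), reverse=True))


def quantify(original: np.ndarray, mask: CalciumMask,
             ctx: NormalizationContext, image_id: str = "") -> CalciumReport:
    """Summarize the masked pixels of the (un-blurred) image into a report.

    An empty mask yields count 0 with absent (None) intensity statistics —
    never zeros, which would masquerade as measured values downstream.
    """
    original = as_gray_image(original)
    if mask.count and (mask.coords[:, 0].max() >= original.shape[0]
                       or mask.coords[:, 1].max() >= original.shape[1]):
        raise ValidationError("mask coordinate outside the image")
    threshold = adaptive_threshold(ctx)
    if mask.count == 0:
        return CalciumReport(0, None, None, None, None, threshold, ctx,
                             (), image_id)
    values = original[mask.coords[:, 0], mask.coords[:, 1]].astype(np.float64)
    raw_mean = float(values.mean())
    raw_median = float(np.median(values))
    return CalciumReport(
        white_pixel_count=mask.count,
        raw_mean=raw_mean,
        raw_median=raw_median,
        normalized_mean=raw_mean - ctx.dark_reference,
        normalized_median=raw_median - ctx.dark_reference,
        effective_threshold=threshold,
        context=ctx,
        component_sizes=_component_sizes(mask, original.shape),
        image_id=image_id,
    )


def run_pipeline(img: np.ndarray, cfg: PipelineConfig, image_id: str = "",
                 debug_dir: str | Path | None = None,
                 return_mask: bool = False):
    """Execute the full analysis flow on one grey image.

    With ``debug_dir`` set, every intermediate stage image is written there
    as PNG (input, gain-compensated, blurred, binary, dilated).  With
    ``return_mask=True`` the result is ``(report, mask)`` so callers can
    inspect the exact pixel set behind the count.
    """
    img = as_gray_image(img)
    cfg.valve_roi.validate_within(img.shape)
    cfg.dark_roi.validate_within(img.shape)

    stages: list[tuple[str, np.ndarray]] = [("0_input", img)]
    gain = 0.0
    work = img
    if cfg.compensate_gain:
        assert cfg.outside_roi is not None
        gain = estimate_postproc_gain(img, cfg.outside_roi)
        work = compensate_postproc(img, gain)
        stages.append(("1_gain_compensated", work))

    blurred = median_blur(work, cfg.enhance.blur_kernel)
    stages.append(("2_blurred", blurred))

    dark = estimate_dark_reference(blurred, cfg.dark_roi,
                                   base_threshold=cfg.enhance.base_threshold)
    ctx = NormalizationContext(postproc_gain=gain, dark_reference=dark,
                               base_threshold=cfg.enhance.base_threshold)
    threshold = adaptive_threshold(ctx)

    binary = binarize(blurred, threshold, strict=True)
    stages.append(("3_binary", binary))
    if cfg.apply_dilation:
        binary = dilate(binary, cfg.enhance.dilation_kernel,
                        cfg.enhance.dilation_iterations)
        stages.append(("4_dilated", binary))

    mask = extract_calcium_mask(binary, cfg.valve_roi)
    report = quantify(work, mask, ctx, image_id=image_id)

    if debug_dir is not None:
        from .image import save_grayscale
        debug_dir = Path(debug_dir)
        debug_dir.mkdir(parents=True, exist_ok=True)
        prefix = f"{image_id}_" if image_id else ""
        for name, stage in stages:
            save_grayscale(stage, debug_dir / f"{prefix}{name}.png")
    if return_mask:
        return report, mask
    return report


_CSV_FIELDS = ["image_id", "white_pixel_count", "raw_mean", "raw_median",
               "normalized_mean", "normalized_median", "effective_threshold",
               "postproc_gain", "dark_reference", "base_threshold"]


def write_reports_csv(reports, path: str | Path) -> None:
    """One CSV row per image, mirroring the white-pixel / normalized-mean tables."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS, extrasaction="ignore")
        writer.writeheader()
        for rep in reports:
            row = rep.to_dict()
            writer.writerow({k: ("" if row[k] is None else row[k])
                             for k in _CSV_FIELDS})


def write_report_json(report: CalciumReport, path: str | Path,
                      config_echo: dict | None = None) -> None:
    """Full-provenance JSON variant, with an optional effective-config echo."""
    payload = report.to_dict()
    if config_echo is not None:
        payload["config"] = config_echo
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
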