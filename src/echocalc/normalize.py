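"""Two-stage brightness normalization.

Echocardiographic pixel intensities drift with acquisition and
post-processing settings, so a fixed calcium threshold does not transfer
between exams.  Two measured references restore comparability:

1. *Post-processing gain* — the mean of a small ROI outside the ultrasound
   sector.  That region images nothing, so any brightness there was added in
   post-processing; subtracting it recovers the acquired image.
2. *Dark reference* ("black threshold") — the mean of a ROI placed on a blood
   pool (the left atrium cavity), the structure whose intensity is most
   stable across settings.  Blood should be near black, so its measured mean
   is the exam's extra brightness.

The dark reference is used twice: added to the base threshold to form the
adaptive binarization threshold, and subtracted from measured calcium
intensities when reporting.  Shifting the threshold up by d and subtracting
d from every pixel before a fixed threshold produce identical masks (strict
inequality is translation-invariant), so the implementation shifts the
threshold — cheaper and lossless, with no clamping of the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import (RectROI, ValidationError, as_gray_image, roi_mean,
                    round_half_away, warn)

__all__ = [
    "NormalizationContext",
    "ThresholdSaturationError",
    "DarkReferenceError",
    "estimate_postproc_gain",
    "compensate_postproc",
    "estimate_dark_reference",
    "adaptive_threshold",
    "normalize_intensity",
]


class ThresholdSaturationError(ValidationError):
    """base threshold + dark reference >= 255: nothing could ever be calcium."""


class DarkReferenceError(ValidationError):
    """The 'dark' ROI is brighter than the calcium threshold: mis-selected ROI."""


@dataclass(frozen=True)
class NormalizationContext:
    """Measured brightness references for one image.

    postproc_gain : mean of the outside-sector ROI (0 when compensation is
        off or the image carries no post-processing gain)
    dark_reference : mean of the blood-pool ROI on the image actually
        thresholded (gain-compensated and blurred)
    base_threshold : fixed calcium threshold before the adaptive shift
    """

    postproc_gain: float = 0.0
    dark_reference: float = 0.0
    base_threshold: int = 160

    def __post_init__(self) -> None:
        if not 0 <= self.postproc_gain <= 255:
            raise ValidationError("postproc_gain must lie in [0, 255]")
        if not 0 <= self.dark_reference <= 255:
            raise ValidationError("dark_reference must lie in [0, 255]")
        if not 0 <= self.base_threshold <= 255:
            raise ValidationError("base_threshold must lie in [0, 255]")

    def to_dict(self) -> dict:
        return {
            "postproc_gain": self.postproc_gain,
            "dark_reference": self.dark_reference,
            "base_threshold": self.base_threshold,
            "effective_threshold": adaptive_threshold(self),
        }


def estimate_postproc_gain(img: np.ndarray, outside_roi: RectROI) -> float:
    """Mean of the outside-sector ROI — the brightness added in post-processing.

    Emits a warning when the mean exceeds 128, which indicates the ROI most
    likely lies inside the imaging sector.
    """
    img = as_gray_image(img)
    gain = roi_mean(img, outside_roi)
    if gain > 128:
        warn(f"outside-sector ROI mean {gain:.1f} > 128; "
             "this does not look like a region outside the ultrasound sector")
    return gain


def compensate_postproc(img: np.ndarray, gain: float) -> np.ndarray:
    """Subtract the post-processing gain from every pixel, clamped at 0."""
    if not 0 <= gain <= 255:
        raise ValidationError("gain must lie in [0, 255]")
    img = as_gray_image(img)
    out = round_half_away(img.astype(np.float64) - gain)
    return as_gray_image(np.clip(out, 0, 255))


def estimate_dark_reference(img: np.ndarray, dark_roi: RectROI,
                            base_threshold: int | None = None) -> float:
    """Mean of the blood-pool ROI, the exam's "black threshold".

    When ``base_threshold`` is given, a dark mean exceeding it raises
    :class:`DarkReferenceError`: a "dark" region brighter than the calcium
    threshold saturates the adaptive threshold and signals a mis-placed ROI.
    """
    img = as_gray_image(img)
    dark = roi_mean(img, dark_roi)
    if base_threshold is not None and dark > base_threshold:
        raise DarkReferenceError(
            f"dark-reference ROI mean {dark:.1f} exceeds the base threshold "
            f"{base_threshold}; the ROI is probably not on a blood pool")
    return dark


def adaptive_threshold(ctx: NormalizationContext) -> float:
    """Brightness-adapted binarization threshold: base + dark reference.

    Raises :class:`ThresholdSaturationError` when the sum reaches 255 —
    no pixel could then ever be classified as calcium.
    """
    t = ctx.base_threshold + ctx.dark_reference
    if t >= 255:
        raise ThresholdSaturationError(
            f"adaptive threshold saturates at {t:.1f} >= 255 "
            f"(base {ctx.base_threshold} + dark reference {ctx.dark_reference:.1f})")
    return t


def normalize_intensity(value: float, ctx: NormalizationContext) -> float:
    """Report-scale intensity: measured value minus the dark reference.

    Not clamped; a negative result (possible only for a mis-selected ROI)
    triggers a warning but is reported as-is.
    """
    if not 0 <= value <= 255:
        raise ValidationError("intensity must lie in [0, 255]")
    out = value - ctx.dark_reference
    if out < 0:
        warn(f"normalized intensity {out:.1f} is negative; "
             "check the dark-reference ROI placement")
    return out
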