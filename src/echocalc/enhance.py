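"""Image-conditioning operators used ahead of calcium segmentation.

Global histogram equalization, contrast-limited adaptive histogram
equalization (CLAHE), multi-threshold region labelling, median blurring,
fixed-threshold binarization and morphological dilation.  All operators are
pure: a grey image in, a new image out.

In the shipped pipeline only *median blur -> binarize -> dilate* participate;
equalization, CLAHE and region labelling are visualization / exploration
aids, since global contrast manipulation would defeat the dark-reference
brightness normalization downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .image import ValidationError, as_gray_image, round_half_away

__all__ = [
    "EnhanceConfig",
    "as_binary_image",
    "equalize_histogram",
    "clahe",
    "region_label_by_thresholds",
    "median_blur",
    "binarize",
    "dilate",
]


@dataclass(frozen=True)
class EnhanceConfig:
    """Tunable knobs of the conditioning stages.

    blur_kernel : side of the square median-filter kernel (odd, default 11)
    base_threshold : fixed binarization threshold before the dark-reference
        shift (default 160; 140 reproduces the first-pass experiment)
    dilation_kernel / dilation_iterations : square structuring element used
        to recover blob pixels eroded by the blur (default 3x3, once)
    clahe_clip : CLAHE contrast limit, OpenCV-style multiplier (default 2.0)
    clahe_tiles : CLAHE tile grid size per axis (default 8)
    """

    blur_kernel: int = 11
    base_threshold: int = 160
    dilation_kernel: int = 3
    dilation_iterations: int = 1
    clahe_clip: float = 2.0
    clahe_tiles: int = 8

    def __post_init__(self) -> None:
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValidationError("blur_kernel must be an odd integer >= 1")
        if self.dilation_kernel < 1 or self.dilation_kernel % 2 == 0:
            raise ValidationError("dilation_kernel must be an odd integer >= 1")
        if not 0 <= self.base_threshold <= 255:
            raise ValidationError("base_threshold must lie in [0, 255]")
        if self.dilation_iterations < 0:
            raise ValidationError("dilation_iterations must be >= 0")
        if self.clahe_clip <= 0:
            raise ValidationError("clahe_clip must be positive")
        if self.clahe_tiles < 1:
            raise ValidationError("clahe_tiles must be >= 1")


def as_binary_image(values: np.ndarray) -> np.ndarray:
    """Validate a {0, 255} binary image (uint8)."""
    arr = as_gray_image(values)
    if not np.isin(arr, (0, 255)).all():
        raise ValidationError("binary image values must be exactly 0 or 255")
    return arr


def equalize_histogram(img: np.ndarray, inclusive: bool = True) -> np.ndarray:
    """Global histogram equalization by the cumulative-distribution remap.

    With the 256-bin histogram H of the input and N pixels, each pixel value
    v maps to ``round(H'(v) / N * 255)`` where H' is the cumulative histogram.
    ``inclusive=True`` (default) uses H'(i) = sum_{j<=i} H(j), which sends the
    brightest occupied bin to 255; ``inclusive=False`` keeps the strict
    cumulative sum_{j<i} H(j) for comparison.
    """
    img = as_gray_image(img)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    cum = np.cumsum(hist)
    if not inclusive:
        cum = cum - hist
    lut = round_half_away(cum / img.size * 255.0).astype(np.uint8)
    return lut[img]


def clahe(img: np.ndarray, clip: float = 2.0, tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Tile-wise clipped equalization with bilinear blending between tile
    mappings (delegated to scikit-image).  ``clip`` follows the OpenCV-style
    multiplier convention and is translated to the normalized clip fraction.
    """
    img = as_gray_image(img)
    if img.shape[0] < tiles or img.shape[1] < tiles:
        raise ValidationError(
            f"image {img.shape} smaller than the {tiles}x{tiles} tile grid")
    kernel = (max(img.shape[0] // tiles, 1), max(img.shape[1] // tiles, 1))
    out = exposure.equalize_adapthist(img, kernel_size=kernel,
                                      clip_limit=clip / 256.0)
    return as_gray_image(round_half_away(out * 255.0))


def region_label_by_thresholds(img: np.ndarray, thresholds) -> np.ndarray:
    """Label pixels by the number of thresholds at or below their value.

    Label 0 is background (below the first threshold); a pixel exactly equal
    to a threshold joins the upper class, consistent with the strict ``>``
    binarization convention.
    """
    img = as_gray_image(img)
    th = np.asarray(list(thresholds), dtype=np.float64)
    if th.size and (np.any(np.diff(th) <= 0)):
        raise ValidationError("thresholds must be strictly ascending")
    if th.size and (th.min() < 0 or th.max() > 255):
        raise ValidationError("thresholds must lie in [0, 255]")
    return np.searchsorted(th, img.ravel(), side="right").reshape(img.shape)


def median_blur(img: np.ndarray, k: int) -> np.ndarray:
    """k x k median filter with replicate border padding (k odd)."""
    if k < 1 or k % 2 == 0:
        raise ValidationError("median kernel must be an odd integer >= 1")
    img = as_gray_image(img)
    if k == 1:
        return img.copy()
    return ndimage.median_filter(img, size=k, mode="nearest")


def binarize(img: np.ndarray, threshold: float, strict: bool = True) -> np.ndarray:
    """Threshold to a {0, 255} image: white iff value > threshold.

    ``strict=False`` switches to >= for completeness; the default matches the
    "intensity above the threshold" convention.
    """
    if not 0 <= threshold <= 255:
        raise ValidationError("threshold must lie in [0, 255]")
    img = as_gray_image(img)
    white = img > threshold if strict else img >= threshold
    return (white.astype(np.uint8)) * 255


def dilate(mask: np.ndarray, kernel: int = 3, iterations: int = 1) -> np.ndarray:
    """Morphological dilation with a square structuring element, repeated."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValidationError("dilation kernel must be an odd integer >= 1")
    if iterations < 0:
        raise ValidationError("iterations must be >= 0")
    mask = as_binary_image(mask)
    if iterations == 0 or kernel == 1:
        return mask.copy()
    structure = np.ones((kernel, kernel), dtype=bool)
    out = ndimage.binary_dilation(mask > 0, structure=structure,
                                  iterations=iterations)
    return out.astype(np.uint8) * 255
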