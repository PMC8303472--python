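"""Core image/ROI data model and grey-scale display mapping.

The whole pipeline works on 2-D ``uint8`` arrays ("grey images", intensities
0-255) and axis-aligned rectangular regions of interest.  ROIs are 0-based,
row-major and half-open on both axes: a ROI covers columns
``[x0, x0 + width)`` and rows ``[y0, y0 + height)``.

Wherever a real-valued intensity is quantized back to an integer image, the
rounding convention is *nearest, half away from zero* — stated once here and
used consistently everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "RectROI",
    "WindowingParams",
    "ValidationError",
    "round_half_away",
    "as_gray_image",
    "load_grayscale",
    "load_dicom_frame",
    "save_grayscale",
    "crop",
    "roi_mean",
    "apply_windowing",
]

#: ITU-R BT.601 luminance weights used for incidentally-coloured inputs.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


class ValidationError(ValueError):
    """Raised when an input violates a pipeline contract (bad ROI, bad kernel...)."""


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer, ties away from zero (NumPy rounds ties to even)."""
    x = np.asarray(x, dtype=np.float64)
    return np.trunc(x + np.copysign(0.5, x))


def as_gray_image(values: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D uint8 grey image.

    Accepts any integer/float array already within [0, 255]; raises
    :class:`ValidationError` on wrong dimensionality, empty axes or
    out-of-range values.
    """
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValidationError(f"grey image must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError(f"grey image must be at least 1x1, got {arr.shape}")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValidationError("grey image values must lie in [0, 255]")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValidationError("grey image values must be integral")
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle: columns [x0, x0+width), rows [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError(f"ROI must be at least 1x1, got {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValidationError(f"ROI origin must be non-negative, got {self}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height),
                slice(self.x0, self.x0 + self.width))

    @property
    def area(self) -> int:
        return self.width * self.height

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape[:2]
        if self.y0 + self.height > h or self.x0 + self.width > w:
            raise ValidationError(
                f"ROI {self} extends outside a {h}x{w} image")

    def contains(self, row: int, col: int) -> bool:
        return (self.y0 <= row < self.y0 + self.height
                and self.x0 <= col < self.x0 + self.width)

    @classmethod
    def from_string(cls, text: str) -> "RectROI":
        """Parse ``"x0,y0,width,height"`` (the run-config serialization)."""
        parts = [int(p) for p in text.replace(" ", "").split(",")]
        if len(parts) != 4:
            raise ValidationError(f"ROI spec needs 4 integers, got {text!r}")
        return cls(*parts)


@dataclass(frozen=True)
class WindowingParams:
    """Window width / window level of the linear grey-scale display mapping."""

    window_width: float
    window_level: float

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValidationError("window width must be positive")


#: Identity display mapping on the 0-255 scale (raw value == displayed value).
IDENTITY_WINDOW = WindowingParams(window_width=255.0, window_level=127.5)


def load_grayscale(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF still image as an 8-bit grey image.

    Colour inputs are converted to luminance with BT.601 weights
    (0.299 R + 0.587 G + 0.114 B), rounded half away from zero.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("P", "CMYK", "YCbCr"):
                im = im.convert("RGB")
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises a zoo of types for bad files
        raise ValidationError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(np.float64)
        lum = rgb @ np.asarray(BT601_WEIGHTS)
        arr = round_half_away(lum)
    elif arr.ndim != 2:
        raise ValidationError(f"unsupported image layout with shape {arr.shape}")
    if arr.dtype != np.uint8 and arr.size and arr.max() > 255:
        raise ValidationError(
            f"{path} is not an 8-bit image; use load_dicom_frame / apply_windowing "
            "to map deeper data onto the 0-255 display scale")
    return as_gray_image(arr)


def load_dicom_frame(path: str | Path, wp: WindowingParams | None = None) -> np.ndarray:
    """Extract a single frame from a DICOM file as an 8-bit grey image.

    Deeper-than-8-bit pixel data are mapped to the display scale with
    :func:`apply_windowing`, using ``wp`` when given, else the file's own
    WindowCenter/WindowWidth, else the full data range.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        arr = round_half_away(rgb @ np.asarray(BT601_WEIGHTS))
    elif arr.ndim == 3:  # multi-frame: take the first frame
        arr = arr[0]
    arr = np.asarray(arr, dtype=np.float64)
    if wp is None:
        if getattr(ds, "WindowWidth", None) and getattr(ds, "WindowCenter", None):
            ww = float(np.atleast_1d(ds.WindowWidth)[0])
            wl = float(np.atleast_1d(ds.WindowCenter)[0])
            wp = WindowingParams(ww, wl)
        elif arr.max() > 255:
            lo, hi = float(arr.min()), float(arr.max())
            wp = WindowingParams(max(hi - lo, 1.0), (hi + lo) / 2.0)
    if wp is not None:
        return apply_windowing(arr, wp)
    return as_gray_image(arr)


def save_grayscale(img: np.ndarray, path: str | Path) -> None:
    """Write a grey image (or 0/255 binary image) as PNG/TIFF."""
    Image.fromarray(as_gray_image(img), mode="L").save(str(path))


def crop(img: np.ndarray, roi: RectROI) -> np.ndarray:
    """Return a copy of the ROI sub-image."""
    img = np.asarray(img)
    roi.validate_within(img.shape)
    return img[roi.slices].copy()


def roi_mean(img: np.ndarray, roi: RectROI) -> float:
    """Arithmetic mean intensity over the ROI (unrounded)."""
    img = np.asarray(img)
    roi.validate_within(img.shape)
    return float(np.mean(img[roi.slices], dtype=np.float64))


def apply_windowing(raw: np.ndarray, wp: WindowingParams) -> np.ndarray:
    """Linear window width / level display mapping.

    ``display = clamp((raw - (WL - WW/2)) / WW, 0, 1) * 255`` rounded half
    away from zero.  Raw input may be real-valued (the phantom's raw scenes
    are); the output is always an 8-bit grey image.
    """
    if wp.window_width <= 0:
        raise ValidationError("window width must be positive")
    raw = np.asarray(raw, dtype=np.float64)
    floor = wp.window_level - wp.window_width / 2.0
    frac = np.clip((raw - floor) / wp.window_width, 0.0, 1.0)
    return as_gray_image(round_half_away(frac * 255.0))


def warn(message: str) -> None:
    """Pipeline-level warning channel (plain warnings, category UserWarning)."""
    warnings.warn(message, UserWarning, stacklevel=3)
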