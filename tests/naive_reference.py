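"""Naive per-pixel reference implementations of the segmentation stages.

Direct Python loops, written from the operator definitions alone, used as
the independent oracle for the vectorized pipeline.  Deliberately slow and
deliberately free of numpy vector tricks.
"""

from __future__ import annotations

import numpy as np

from echocalc.image import RectROI


def naive_median_blur(img: np.ndarray, k: int) -> np.ndarray:
    """k x k median with replicate (clamped-index) border padding."""
    h, w = img.shape
    r = k // 2
    out = np.zeros_like(img)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    vals.append(int(img[yy, xx]))
            vals.sort()
            out[y, x] = vals[len(vals) // 2]
    return out


def naive_binarize(img: np.ndarray, threshold: float) -> np.ndarray:
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            if img[y, x] > threshold:
                out[y, x] = 255
    return out


def naive_dilate(mask: np.ndarray, kernel: int, iterations: int) -> np.ndarray:
    h, w = mask.shape
    r = kernel // 2
    current = mask.copy()
    for _ in range(iterations):
        out = np.zeros((h, w), dtype=np.uint8)
        for y in range(h):
            for x in range(w):
                if current[y, x] == 255:
                    for dy in range(-r, r + 1):
                        for dx in range(-r, r + 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w:
                                out[yy, xx] = 255
        current = out
    return current


def naive_roi_mean(img: np.ndarray, roi: RectROI) -> float:
    total = 0
    for y in range(roi.y0, roi.y0 + roi.height):
        for x in range(roi.x0, roi.x0 + roi.width):
            total += int(img[y, x])
    return total / (roi.width * roi.height)


def naive_mask_coords(binary: np.ndarray, roi: RectROI) -> np.ndarray:
    coords = []
    for y in range(roi.y0, roi.y0 + roi.height):
        for x in range(roi.x0, roi.x0 + roi.width):
            if binary[y, x] == 255:
                coords.append((y, x))
    return np.asarray(coords, dtype=np.intp).reshape(-1, 2)


def naive_pipeline_mask(img: np.ndarray, valve_roi: RectROI, dark_roi: RectROI,
                        base_threshold: int, blur_kernel: int,
                        dilation_kernel: int, dilation_iterations: int
                        ) -> np.ndarray:
    """Full detection flow as direct loops; returns white coords in valve ROI."""
    blurred = naive_median_blur(img, blur_kernel)
    dark = naive_roi_mean(blurred, dark_roi)
    binary = naive_binarize(blurred, base_threshold + dark)
    binary = naive_dilate(binary, dilation_kernel, dilation_iterations)
    return naive_mask_coords(binary, valve_roi)
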