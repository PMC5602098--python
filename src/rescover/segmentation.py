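"""Excess-green residue segmentation of RGB field photos.

The processing chain mirrors the standard image-processing recipe for
separating straw from soil in colour photographs:

1. per-channel colour balance (linear percentile stretch),
2. excess-green index ``2*G - R - B`` per pixel (signed arithmetic),
3. binarisation (Otsu by default, or a fixed threshold),
4. cover = percentage of residue pixels.

Soil maps to black (False) and residue to white (True) in the binary
mask.  The index of a straw-like pixel such as (210, 190, 120) is
2*190 - 210 - 120 = 50, well above typical soil values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class SegmentationResult:
    """Intermediate artifacts of :func:`segment_cover`."""

    balanced: np.ndarray
    index: np.ndarray
    mask: np.ndarray
    threshold: float
    cover: float


def color_balance(image: np.ndarray, saturation_fraction: float = 0.007) -> np.ndarray:
    """Per-channel linear contrast stretch with tail clipping.

    The lowest and highest ``saturation_fraction / 2`` of each channel's
    pixels saturate to 0 and 255; the rest are mapped affinely.  A
    constant channel cannot be stretched and is returned unchanged with
    a warning.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if not 0.0 <= saturation_fraction < 1.0:
        raise ValueError("saturation_fraction must lie in [0, 1)")
    out = np.empty_like(img, dtype=np.uint8)
    q = saturation_fraction / 2.0
    for c in range(3):
        ch = img[..., c].astype(np.float64)
        lo, hi = np.quantile(ch, [q, 1.0 - q])
        if hi <= lo:
            warnings.warn(f"channel {c} is constant; colour balance skipped")
            out[..., c] = img[..., c]
            continue
        stretched = (ch - lo) * (255.0 / (hi - lo))
        out[..., c] = np.clip(np.round(stretched), 0, 255).astype(np.uint8)
    return out


def excess_index(image: np.ndarray) -> np.ndarray:
    """Excess-green index ``2G - R - B``, signed (range [-510, 510] for 8-bit)."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    r, g, b = (img[..., i].astype(np.int32) for i in range(3))
    return 2 * g - r - b


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's optimal split of an integer-valued grid.

    Exhaustive search over all distinct values, maximising between-class
    variance; ties broken toward the lower threshold.  Deterministic.
    """
    v = np.asarray(values).ravel()
    levels, counts = np.unique(v, return_counts=True)
    if len(levels) < 2:
        raise ValueError(
            "all pixels share one value; Otsu is undefined — use a fixed threshold")
    levels = levels.astype(np.float64)
    w = counts.astype(np.float64)
    # candidate threshold t = levels[i]: classes (<= t) vs (> t)
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * levels)
    total_w, total_m = cum_w[-1], cum_m[-1]
    w0, w1 = cum_w[:-1], total_w - cum_w[:-1]
    m0 = cum_m[:-1] / w0
    m1 = (total_m - cum_m[:-1]) / w1
    between = w0 * w1 * (m0 - m1) ** 2
    return float(levels[np.argmax(between)])


def binarize(index: np.ndarray, method: str = "otsu",
             threshold: float | None = None) -> np.ndarray:
    """Binarise an index grid: True (residue) strictly above the threshold."""
    idx = np.asarray(index)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = threshold
    elif method == "otsu":
        t = otsu_threshold(idx)
    else:
        raise ValueError(f"unknown binarisation method {method!r}")
    return idx > t


def cover_fraction(mask: np.ndarray) -> float:
    """Residue cover in percent: 100 x residue pixels / total pixels."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        raise ValueError("empty mask")
    return 100.0 * float(m.mean())


def segment_cover(image: np.ndarray, saturation_fraction: float = 0.007,
                  method: str = "otsu", threshold: float | None = None,
                  return_intermediates: bool = False):
    """Full segmentation chain: colour balance → 2G−R−B → binarise → cover %.

    Returns the cover percent, or a :class:`SegmentationResult` with all
    intermediate artifacts when ``return_intermediates`` is set.
    """
    balanced = color_balance(image, saturation_fraction)
    index = excess_index(balanced)
    mask = binarize(index, method=method, threshold=threshold)
    cover = cover_fraction(mask)
    if not return_intermediates:
        return cover
    t = threshold if method == "fixed" else otsu_threshold(index)
    return SegmentationResult(balanced=balanced, index=index, mask=mask,
                              threshold=float(t), cover=cover)
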