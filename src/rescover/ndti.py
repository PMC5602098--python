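"""Normalized Difference Tillage Index (NDTI).

NDTI = (SWIR1 - SWIR2) / (SWIR1 + SWIR2), computed per pixel from the
two shortwave-infrared reflectance bands (Landsat 8 bands near 1.6 and
2.2 um).  Crop residue's cellulose absorption depresses SWIR2, so the
index rises with residue cover.  For comparison with percent-cover
measurements the raw index in [-1, 1] is rescaled affinely to [0, 100];
no empirical calibration is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class NdtiGrid:
    """An NDTI raster; ``scaled`` records whether values are on [0, 100]."""

    values: np.ndarray          # float, NaN where invalid
    scaled: bool = False


def compute_ndti(swir1: np.ndarray, swir2: np.ndarray) -> NdtiGrid:
    """Raw NDTI grid; pixels where both bands are zero are flagged invalid (NaN)."""
    s1 = np.asarray(swir1, dtype=float)
    s2 = np.asarray(swir2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"band shapes differ: {s1.shape} vs {s2.shape}")
    if (s1 < 0).any() or (s2 < 0).any():
        raise ValueError("reflectances must be non-negative")
    denom = s1 + s2
    values = np.full(s1.shape, np.nan)
    ok = denom > 0
    values[ok] = (s1[ok] - s2[ok]) / denom[ok]
    return NdtiGrid(values=values, scaled=False)


def scale_ndti(raw: NdtiGrid) -> NdtiGrid:
    """Rescale raw NDTI from [-1, 1] to [0, 100]: scaled = (raw + 1) * 50."""
    if raw.scaled:
        raise ValueError("grid is already scaled")
    return NdtiGrid(values=(raw.values + 1.0) * 50.0, scaled=True)


def extract_plot_value(grid: NdtiGrid,
                       geotransform: tuple[float, float, float, float, float, float],
                       point: tuple[float, float], mode: str = "pixel") -> float:
    """NDTI value at a plot coordinate.

    ``mode='pixel'`` (default) returns the value of the single 30 m
    pixel containing the point; ``mode='mean3'`` averages the 3x3
    neighbourhood (edge-clipped).  Invalid pixels propagate as NaN.
    """
    x0, dx, _, y0, _, dy = geotransform
    x, y = point
    h, w = grid.values.shape
    col = int(np.floor((x - x0) / dx))
    row = int(np.floor((y - y0) / dy))   # dy is negative for north-up rasters
    if not (0 <= row < h and 0 <= col < w):
        raise ValueError(f"point {point} outside raster extent")
    if mode == "pixel":
        return float(grid.values[row, col])
    if mode == "mean3":
        r0, r1 = max(0, row - 1), min(h, row + 2)
        c0, c1 = max(0, col - 1), min(w, col + 2)
        return float(np.mean(grid.values[r0:r1, c0:c1]))
    raise ValueError(f"unknown extraction mode {mode!r}")
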