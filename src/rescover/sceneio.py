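"""Lossless scene I/O: PNG images + masks, two-band GeoTIFF rasters.

PNG is used for RGB field photos (8-bit, lossless) with the ground-truth
mask stored alongside as a single-channel PNG (255 = residue).  Spectral
scenes are written as two-band float32 TIFFs carrying the standard
GeoTIFF geolocation tags (ModelPixelScale, ModelTiepoint), which is all
the pipeline needs to map plot coordinates to pixels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError

from .imagery import FieldScene, SpectralScene

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


def write_png(scene: FieldScene, image_path: str | Path,
              mask_path: str | Path | None = None) -> None:
    """Write a field scene's RGB image (and, optionally, its mask) as PNG."""
    Image.fromarray(scene.image, mode="RGB").save(str(image_path), format="PNG")
    if mask_path is not None:
        Image.fromarray(scene.mask.astype(np.uint8) * 255, mode="L").save(
            str(mask_path), format="PNG")


def read_png(image_path: str | Path, mask_path: str | Path | None = None,
             pixel_size_cm: float = 0.27) -> FieldScene:
    """Read a field scene back from PNG; raises ValueError on malformed files."""
    try:
        image = np.asarray(Image.open(str(image_path)).convert("RGB"))
    except (UnidentifiedImageError, OSError) as exc:
        raise ValueError(f"cannot parse PNG image {image_path}: {exc}") from exc
    if mask_path is not None:
        try:
            mask = np.asarray(Image.open(str(mask_path)).convert("L")) >= 128
        except (UnidentifiedImageError, OSError) as exc:
            raise ValueError(f"cannot parse PNG mask {mask_path}: {exc}") from exc
        if mask.shape != image.shape[:2]:
            raise ValueError("mask and image dimensions differ")
    else:
        mask = np.zeros(image.shape[:2], dtype=bool)
    return FieldScene(mask=mask, image=image, pixel_size_cm=pixel_size_cm)


def write_geotiff(scene: SpectralScene, path: str | Path) -> None:
    """Write a two-band SWIR raster as float32 GeoTIFF (north-up geotransform)."""
    data = np.stack([scene.swir1, scene.swir2]).astype(np.float32)
    x0, y0 = scene.origin
    p = float(scene.pixel_size_m)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (p, p, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    tifffile.imwrite(str(path), data, photometric="minisblack",
                     planarconfig="separate", extratags=extratags)


def read_geotiff(path: str | Path) -> SpectralScene:
    """Read a two-band SWIR GeoTIFF written by :func:`write_geotiff`."""
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            tags = tif.pages[0].tags
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
    except (tifffile.TiffFileError, KeyError, IndexError, OSError) as exc:
        raise ValueError(f"cannot parse GeoTIFF {path}: {exc}") from exc
    if data.ndim != 3 or data.shape[0] != 2:
        raise ValueError(f"expected a two-band raster, got shape {data.shape}")
    return SpectralScene(
        swir1=data[0].astype(np.float32),
        swir2=data[1].astype(np.float32),
        origin=(float(tiepoint[3]), float(tiepoint[4])),
        pixel_size_m=float(scale[0]),
    )
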