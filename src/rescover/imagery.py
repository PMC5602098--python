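"""Procedural field imagery with exact ground truth.

Two kinds of scenes stand in for the experiment's aerial data:

* :class:`FieldScene` — an RGB image of straw strewn on soil, as a drone
  would photograph from ~7.5 m (default 0.27 cm/pixel), together with
  the exact boolean residue mask it was rendered from.  Ground truth is
  counted from the mask, never estimated, so segmentation accuracy can
  be scored exactly.
* :class:`SpectralScene` — a two-band shortwave-infrared reflectance
  raster at 30 m/pixel (a Landsat stand-in) in which the tillage signal
  is monotone in residue cover: cellulose absorption depresses SWIR2
  relative to SWIR1 where residue is present.

Straw is drawn as hard-edged rectangular strokes (no anti-aliasing), so
every pixel is unambiguously residue or soil.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon

#: Mean straw (pale yellow, green ~ red >> blue) and per-soil mean colours.
#: Soil blues sit near the straw blue on purpose: the per-channel colour
#: balance rescales each channel to full range, so a narrow-span blue
#: channel would otherwise get an outsized gain in the 2G-R-B index.
STRAW_RGB = np.array([205.0, 200.0, 80.0])
SOIL_RGB = {
    "cambisol": np.array([125.0, 90.0, 88.0]),
    "leptosol": np.array([152.0, 132.0, 115.0]),
    "luvisol": np.array([145.0, 85.0, 92.0]),
    "vertisol": np.array([70.0, 55.0, 62.0]),   # dark clay: darkest
}

#: Base SWIR1 reflectance per soil type; vertisol (moist dark clay) lowest.
SOIL_SWIR1 = {
    "cambisol": 0.28,
    "leptosol": 0.32,
    "luvisol": 0.26,
    "vertisol": 0.16,
}


@dataclass
class FieldScene:
    """A rendered field photo with its exact residue mask."""

    mask: np.ndarray            # bool, True = residue
    image: np.ndarray           # uint8, (H, W, 3)
    pixel_size_cm: float = 0.27
    soil: str = "cambisol"

    @property
    def true_cover(self) -> float:
        """Exact residue cover, percent (counted from the mask)."""
        return 100.0 * float(self.mask.mean())

    @property
    def extent_m2(self) -> float:
        h, w = self.mask.shape
        return h * w * (self.pixel_size_cm / 100.0) ** 2


@dataclass
class SpectralScene:
    """Two-band SWIR raster with a north-up affine geotransform."""

    swir1: np.ndarray           # float32 reflectance in [0, 1]
    swir2: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)   # (x0, y0) of the top-left corner
    pixel_size_m: float = 30.0
    plot_points: list = field(default_factory=list)  # (x, y, true_cover)

    @property
    def geotransform(self) -> tuple[float, float, float, float, float, float]:
        """(x0, dx, 0, y0, 0, -dy) — GDAL-style north-up affine."""
        x0, y0 = self.origin
        p = self.pixel_size_m
        return (x0, p, 0.0, y0, 0.0, -p)


def _stroke_pixels(rng: np.random.Generator, shape: tuple[int, int],
                   length: float, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of one randomly placed, randomly oriented straw stroke."""
    h, w = shape
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    theta = rng.uniform(0, np.pi)
    dy, dx = np.sin(theta), np.cos(theta)
    # rectangle corners: centre +- half-length along axis, +- half-width across
    hl, hw = length / 2.0, width / 2.0
    py, px = -dx, dy
    rr = np.array([cy - hl * dy - hw * py, cy - hl * dy + hw * py,
                   cy + hl * dy + hw * py, cy + hl * dy - hw * py])
    cc = np.array([cx - hl * dx - hw * px, cx - hl * dx + hw * px,
                   cx + hl * dx + hw * px, cx + hl * dx - hw * px])
    return polygon(rr, cc, shape=shape)


def generate_residue_mask(cover_target: float, shape: tuple[int, int] = (768, 1024),
                          stroke_length: float = 60.0, stroke_width: float = 4.0,
                          tolerance: float = 1.0,
                          rng: np.random.Generator | int = 0) -> np.ndarray:
    """Boolean residue mask whose cover is within ``tolerance`` of the target.

    Straw strokes are added until the counted cover reaches the target;
    if the final stroke overshoots past the tolerance, a random subset
    of its newly covered pixels is removed so the bound always holds.
    """
    if not 0.0 <= cover_target <= 100.0:
        raise ValueError("cover_target must lie in [0, 100]")
    if tolerance <= 0.0:
        raise ValueError("tolerance must be positive (strokes are discrete)")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mask = np.zeros(shape, dtype=bool)
    total = mask.size
    target_px = cover_target / 100.0 * total
    if cover_target >= 100.0:
        mask[:] = True
        return mask
    guard = 0
    while mask.sum() < target_px:
        rr, cc = _stroke_pixels(rng, shape, stroke_length, stroke_width)
        fresh = np.flatnonzero(~mask[rr, cc])
        needed = int(round(target_px - mask.sum()))
        if len(fresh) > needed:
            # final stroke would overshoot: keep a random subset of its
            # fresh pixels so the counted cover lands on the target
            fresh = rng.permutation(fresh)[:needed]
            mask[rr[fresh], cc[fresh]] = True
            break
        mask[rr[fresh], cc[fresh]] = True
        guard += 1
        if guard > 500_000:
            raise RuntimeError("stroke placement failed to reach the target cover")
    assert abs(100.0 * mask.mean() - cover_target) <= tolerance
    return mask


def render_field_image(mask: np.ndarray, soil: str = "cambisol",
                       contrast: float = 1.0, color_sd: float = 4.0,
                       illumination_sd: float = 18.0, color_cast: float = 0.0,
                       rng: np.random.Generator | int = 0) -> np.ndarray:
    """Render an RGB image from a residue mask.

    Texture is dominated by common-mode illumination noise
    (``illumination_sd``, applied equally to all channels, as shadows
    and surface relief are in real photographs) plus a smaller
    independent per-channel colour noise (``color_sd``).

    ``contrast`` in [0, 1] interpolates the straw colour between the
    soil mean (0: straw and soil indistinguishable) and the full pale
    yellow (1: separable); it emulates the lighting/colour shifts that
    broke segmentation in uncontrolled aerial photography.  ``color_cast``
    adds a global additive shift to all channels (altitude-dependent
    sensor response).
    """
    if soil not in SOIL_RGB:
        raise ValueError(f"unknown soil type {soil!r}")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    h, w = mask.shape
    soil_mean = SOIL_RGB[soil]
    straw_mean = soil_mean + contrast * (STRAW_RGB - soil_mean)
    img = np.where(mask[..., None], straw_mean, soil_mean)
    img = img + rng.normal(0.0, color_sd, size=(h, w, 3))
    img = img + rng.normal(0.0, illumination_sd, size=(h, w, 1))   # common-mode lighting
    img = img + color_cast
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_field_scene(cover_target: float, soil: str = "cambisol",
                         shape: tuple[int, int] = (768, 1024),
                         contrast: float = 1.0, pixel_size_cm: float = 0.27,
                         stroke_length: float = 60.0, stroke_width: float = 4.0,
                         tolerance: float = 1.0, color_cast: float = 0.0,
                         seed: int | np.random.Generator = 0) -> FieldScene:
    """Generate a straw-on-soil scene with exact cover near ``cover_target``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = generate_residue_mask(cover_target, shape, stroke_length, stroke_width,
                                 tolerance, rng)
    image = render_field_image(mask, soil=soil, contrast=contrast,
                               color_cast=color_cast, rng=rng)
    return FieldScene(mask=mask, image=image, pixel_size_cm=pixel_size_cm, soil=soil)


def render_spectral_scene(covers: np.ndarray, coords: np.ndarray,
                          shape: tuple[int, int] = (64, 64),
                          origin: tuple[float, float] = (0.0, 0.0),
                          pixel_size_m: float = 30.0,
                          soils: np.ndarray | None = None,
                          k: float = 0.4, noise_sd: float = 0.01,
                          vertisol_noise_sd: float = 0.02,
                          seed: int | np.random.Generator = 0) -> SpectralScene:
    """Render a two-band SWIR raster with plots of known cover embedded.

    The residue signal is ``swir2 = swir1 * (1 - k * cover/100)`` plus
    band noise, so the tillage index (SWIR1−SWIR2)/(SWIR1+SWIR2) rises
    monotonically with cover in the noise-free limit.  Vertisol plots
    receive extra reflectance perturbation, emulating the moist dark
    clays that degraded the satellite method in the field.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    covers = np.asarray(covers, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(covers), 2):
        raise ValueError("coords must be (n, 2) matching covers")
    h, w = shape
    x0, y0 = origin
    # background: bare-soil mosaic
    swir1 = rng.normal(0.27, 0.02, size=shape)
    swir2 = swir1 * rng.normal(0.97, 0.01, size=shape)

    soils = np.asarray(soils) if soils is not None else np.full(len(covers), "cambisol")
    for cov, (x, y), soil in zip(covers, coords, soils):
        col = int(np.floor((x - x0) / pixel_size_m))
        row = int(np.floor((y0 - y) / pixel_size_m))
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(f"plot coordinate ({x}, {y}) outside raster extent")
        base = SOIL_SWIR1.get(str(soil), 0.27)
        s1 = base + rng.normal(0.0, noise_sd)
        s2 = base * (1.0 - k * cov / 100.0) + rng.normal(0.0, noise_sd)
        if str(soil) == "vertisol":
            s2 += rng.normal(0.0, vertisol_noise_sd)
        swir1[row, col] = s1
        swir2[row, col] = s2

    return SpectralScene(
        swir1=np.clip(swir1, 0.0, 1.0).astype(np.float32),
        swir2=np.clip(swir2, 0.0, 1.0).astype(np.float32),
        origin=origin, pixel_size_m=pixel_size_m,
        plot_points=[(float(x), float(y), float(c)) for (x, y), c in zip(coords, covers)],
    )
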