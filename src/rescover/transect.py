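"""Line-transect simulation over a ground-truth residue mask.

The benchmark field protocol: a 30 m rope with marks at 1 m intervals is
laid diagonally at each of the field's four corners; the enumerator
looks straight down at each mark and counts marks lying over residue.
The four per-transect percentages (hits / 30 x 100) are averaged into
the field estimate, so estimates are multiples of 100/120.

A mark "intersects residue" iff the grid cell containing the mark is
residue — point sampling with no mark width.  When the field is smaller
than the rope (a drone-scale scene is only metres across), the transect
is clipped to the corner-to-corner diagonal with a warning and the 30
marks are spaced evenly along the available length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class TransectReading:
    """One rope laid on the field: geometry, mark positions, hit count."""

    start: tuple[float, float]       # (x, y) in metres, x right / y down
    end: tuple[float, float]
    mark_positions: np.ndarray       # (n_marks, 2) metre coordinates
    hits: int

    @property
    def n_marks(self) -> int:
        return len(self.mark_positions)

    @property
    def percent(self) -> float:
        return 100.0 * self.hits / self.n_marks


def read_transect(mask: np.ndarray, start: tuple[float, float],
                  end: tuple[float, float], pixel_size_m: float,
                  n_marks: int = 30) -> TransectReading:
    """Count marks over residue along one rope.

    Marks sit at the centres of ``n_marks`` equal intervals along the
    segment (so a 30 m rope has marks at 0.5, 1.5, ..., 29.5 m).
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    x0, y0 = start
    x1, y1 = end
    fracs = (np.arange(n_marks) + 0.5) / n_marks
    xs = x0 + fracs * (x1 - x0)
    ys = y0 + fracs * (y1 - y0)
    cols = np.floor(xs / pixel_size_m).astype(int)
    rows = np.floor(ys / pixel_size_m).astype(int)
    if (cols < 0).any() or (cols >= w).any() or (rows < 0).any() or (rows >= h).any():
        raise ValueError("transect exits the field extent")
    hits = int(mask[rows, cols].sum())
    return TransectReading(start=start, end=end,
                           mark_positions=np.column_stack([xs, ys]), hits=hits)


def lt_estimate(mask: np.ndarray, pixel_size_m: float,
                rope_length_m: float = 30.0, n_marks: int = 30,
                seed: int | np.random.Generator = 0,
                jitter_m: float = 0.0) -> float:
    """Field cover estimate: four corner transects averaged, in percent.

    Each transect starts just inside a corner and runs along the inward
    diagonal (toward the opposite corner), clipped to the rope length.
    ``jitter_m`` randomises the corner inset slightly, emulating rope
    placement variability between enumerators.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    H, W = h * pixel_size_m, w * pixel_size_m
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diag = float(np.hypot(W, H))
    length = min(rope_length_m, diag)
    if rope_length_m > diag:
        warnings.warn(
            f"field diagonal {diag:.1f} m shorter than the {rope_length_m:.0f} m rope; "
            "transects clipped and marks rescaled to the field diagonal")
    corners = [(0.0, 0.0), (W, 0.0), (W, H), (0.0, H)]
    opposite = [(W, H), (0.0, H), (0.0, 0.0), (W, 0.0)]  # diagonal partner of each corner
    readings = []
    eps = 1e-9
    for (cx, cy), (ox, oy) in zip(corners, opposite):
        off = rng.uniform(0.0, jitter_m) if jitter_m > 0 else 0.0
        ux, uy = (ox - cx) / diag, (oy - cy) / diag
        sx, sy = cx + ux * off, cy + uy * off
        seg = min(length, diag - off) - eps
        r = read_transect(mask, (sx + ux * eps, sy + uy * eps),
                          (sx + ux * seg, sy + uy * seg), pixel_size_m, n_marks)
        readings.append(r)
    return float(np.mean([r.percent for r in readings]))
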