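"""Cell segmentation and morphometry of discriminable detections.

Each retained cell crop is binarized at its own Otsu statistic (cell of
interest white on black), the largest foreground component is selected
and its closed outer contour traced (Moore boundary following). From
the contour we measure:

* area — number of enclosed pixels;
* perimeter — length of the boundary chain, counting axial steps as 1
  and diagonal steps as sqrt(2) (a plain pixel count would inflate
  diagonal travel inconsistently across orientations);
* compactness — ``perimeter**2 / (4 * pi * area)``; 1 for a perfect
  disc, larger for irregular outlines (isoperimetric inequality);
* minimum pixel intensity — reported as the per-patch Otsu statistic,
  which estimates the lowest intensity of the cell's own pixels.

Case-level features are arithmetic means over the case's cells plus a
cell density per mm^2 of tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .discriminability import SignalPatch


class MorphometryError(ValueError):
    """Segmentation/measurement failed (empty mask, degenerate contour)."""


@dataclass(frozen=True)
class CellMorphometry:
    area: float                 # enclosed pixel count
    perimeter: float            # weighted boundary chain length, px
    compactness: float          # dimensionless, >= ~1
    min_intensity: float | None  # the per-patch Otsu statistic
    contour: np.ndarray         # (n, 2) of (x, y), closed, CCW


@dataclass(frozen=True)
class CaseFeatures:
    n_cells: int
    mean_area: float | None
    mean_perimeter: float | None
    mean_compactness: float | None
    mean_min_intensity: float | None
    density_per_mm2: float


def binarize(signal: SignalPatch | np.ndarray, sigma: float) -> np.ndarray:
    """Foreground (cell) mask: signal strictly above the Otsu value."""
    values = signal.values if isinstance(signal, SignalPatch) else signal
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must lie in [0, 1]")
    return np.asarray(values) > sigma


# ---------------------------------------------------------------------------
# contour tracing
# ---------------------------------------------------------------------------

# clockwise Moore neighbourhood in image coordinates (row grows downward)
_OFFSETS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def _moore_trace(mask: np.ndarray) -> list[tuple[int, int]]:
    """Boundary pixels of a single foreground component, in order.

    Moore boundary following from the topmost-leftmost pixel with
    Jacob's stopping criterion; returns (row, col) pixels.
    """
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    first = np.lexsort((cols, rows))[0]
    start = (int(rows[first]), int(cols[first]))
    b0 = (start[0], start[1] - 1)  # west of start is background by choice
    contour = [start]
    p, b = start, b0
    max_steps = 4 * int(padded.sum()) + 8
    for _ in range(max_steps):
        bi = _OFFSETS.index((b[0] - p[0], b[1] - p[1]))
        q = None
        for k in range(1, 9):
            d = _OFFSETS[(bi + k) % 8]
            cand = (p[0] + d[0], p[1] + d[1])
            if padded[cand]:
                prev = _OFFSETS[(bi + k - 1) % 8]
                q, newb = cand, (p[0] + prev[0], p[1] + prev[1])
                break
        if q is None:       # isolated single pixel
            break
        p, b = q, newb
        if p == start and b == b0:
            break
        contour.append(p)
    return [(r - 1, c - 1) for r, c in contour]


def _signed_area(contour_xy: np.ndarray) -> float:
    x, y = contour_xy[:, 0], contour_xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_cell_contour(mask: np.ndarray, min_area: int = 5) -> np.ndarray:
    """Closed outer contour of the largest foreground component.

    Holes are filled before tracing (the outer boundary is wanted).
    Points are (x, y) pixels ordered counter-clockwise in the Cartesian
    sense. Raises :class:`MorphometryError` for an empty mask or a
    component below ``min_area`` pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        raise MorphometryError("no segmentable cell: mask is empty")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    comp = ndimage.binary_fill_holes(comp)
    if comp.sum() < min_area:
        raise MorphometryError(
            f"largest component ({int(comp.sum())} px) below min area {min_area}")
    rc = _moore_trace(comp)
    contour = np.array([(c, r) for r, c in rc], dtype=np.int64)
    if len(contour) >= 3 and _signed_area(contour) < 0:
        contour = contour[::-1]
    return contour


def simplify_collinear(contour: np.ndarray) -> np.ndarray:
    """Drop points collinear with their cyclic neighbours (exact test)."""
    n = len(contour)
    if n < 3:
        return contour.copy()
    prev = np.roll(contour, 1, axis=0)
    nxt = np.roll(contour, -1, axis=0)
    cross = ((contour[:, 0] - prev[:, 0]) * (nxt[:, 1] - contour[:, 1])
             - (contour[:, 1] - prev[:, 1]) * (nxt[:, 0] - contour[:, 0]))
    return contour[cross != 0]


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def chain_perimeter(contour: np.ndarray) -> float:
    """Closed-chain length: 1 per axial step, sqrt(2) per diagonal step."""
    if len(contour) < 2:
        return 0.0
    diffs = np.abs(np.roll(contour, -1, axis=0) - contour)
    steps = np.where((diffs[:, 0] == 1) & (diffs[:, 1] == 1), np.sqrt(2.0),
                     diffs.max(axis=1).astype(float))
    return float(steps.sum())


def enclosed_pixel_count(contour: np.ndarray) -> int:
    """Pixels on or inside the closed contour (exact raster fill)."""
    if len(contour) == 0:
        return 0
    x0, y0 = contour.min(axis=0)
    x1, y1 = contour.max(axis=0)
    canvas = np.zeros((y1 - y0 + 3, x1 - x0 + 3), dtype=bool)
    canvas[contour[:, 1] - y0 + 1, contour[:, 0] - x0 + 1] = True
    return int(ndimage.binary_fill_holes(canvas).sum())


def compactness(perimeter: float, area: float) -> float:
    """perimeter^2 / (4 pi area); 1 for a disc in the continuous limit."""
    if area <= 0:
        raise MorphometryError("compactness undefined for zero area")
    return perimeter ** 2 / (4.0 * np.pi * area)


def measure(contour: np.ndarray, signal: SignalPatch | np.ndarray | None = None,
            sigma: float | None = None) -> CellMorphometry:
    """Morphometry of one traced cell contour.

    ``sigma`` (the patch's Otsu statistic) is carried through as the
    cell's minimum pixel intensity.
    """
    if len(contour) < 1:
        raise MorphometryError("empty contour")
    area = enclosed_pixel_count(contour)
    if area <= 0:
        raise MorphometryError("zero enclosed area")
    perim = chain_perimeter(contour)
    return CellMorphometry(
        area=float(area), perimeter=perim,
        compactness=compactness(perim, area) if perim > 0 else 0.0,
        min_intensity=sigma, contour=contour)


def measure_patch(signal: SignalPatch | np.ndarray, sigma: float,
                  min_area: int = 5) -> CellMorphometry:
    """Binarize at sigma, trace the dominant component, measure it."""
    mask = binarize(signal, sigma)
    contour = extract_cell_contour(mask, min_area=min_area)
    return measure(contour, signal, sigma)


def case_summary(cells: Sequence[CellMorphometry],
                 tissue_area_mm2: float) -> CaseFeatures:
    """Arithmetic means over a case's cells plus density per mm^2."""
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue area must be positive")
    n = len(cells)
    if n == 0:
        return CaseFeatures(0, None, None, None, None, 0.0)
    mi = [c.min_intensity for c in cells if c.min_intensity is not None]
    return CaseFeatures(
        n_cells=n,
        mean_area=float(np.mean([c.area for c in cells])),
        mean_perimeter=float(np.mean([c.perimeter for c in cells])),
        mean_compactness=float(np.mean([c.compactness for c in cells])),
        mean_min_intensity=float(np.mean(mi)) if mi else None,
        density_per_mm2=n / tissue_area_mm2)
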