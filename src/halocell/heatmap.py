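"""Sliding-window inference heatmaps and detection merging.

The trained bifocal net is slid over a tile with a 10 px stride (upper
left to bottom right); the positive-class scores form a stride-indexed
lattice rendered as a pseudo-colour heatmap (red = cell, turquoise =
background). Overlapping supra-threshold windows are merged into
discrete detections by 8-connected component analysis on the lattice: a
cell tens of pixels across lights up several stride-10 windows, and one
record per connected component — placed at the score-weighted centroid —
matches the convention of counting cells rather than windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .annotations import (
    HALF_WIDE, ImageTile, enumerate_inference_centres, lattice_shape,
)
from .bcnn import BifocalNet, _standardize

POSITIVE_COLOUR = (255, 0, 0)       # red
NEGATIVE_COLOUR = (64, 224, 208)    # turquoise


@dataclass
class HeatmapGrid:
    """Stride-resolution lattice of positive-class scores over one tile."""

    scores: np.ndarray              # (rows, cols) in [0, 1]
    stride: int
    origin: tuple[int, int] = (HALF_WIDE, HALF_WIDE)  # centre of grid (0,0)
    tile_id: str = ""
    case_id: str = ""
    microns_per_pixel: float = 0.25

    def centre_of(self, row: int, col: int) -> tuple[int, int]:
        return (self.origin[0] + col * self.stride,
                self.origin[1] + row * self.stride)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), scores=self.scores)
        path.with_suffix(".json").write_text(json.dumps({
            "stride": self.stride, "origin": list(self.origin),
            "tile_id": self.tile_id, "case_id": self.case_id,
            "microns_per_pixel": self.microns_per_pixel}))

    @classmethod
    def load(cls, path: str | Path) -> "HeatmapGrid":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as data:
            scores = data["scores"]
        return cls(scores=scores, stride=meta["stride"],
                   origin=tuple(meta["origin"]), tile_id=meta["tile_id"],
                   case_id=meta["case_id"],
                   microns_per_pixel=meta["microns_per_pixel"])


@dataclass
class DetectionRecord:
    """One predicted cell, enriched by later pipeline stages."""

    centre: tuple[int, int]          # tile pixel coords
    score: float
    crop: np.ndarray | None = field(default=None, repr=False)  # 64x64 RGB
    sigma: float | None = None       # per-patch Otsu statistic
    threshold_T: float | None = None
    discriminable: bool | None = None
    morphometry: object | None = None
    case_id: str = ""
    tile_id: str = ""


def sliding_inference(model: BifocalNet, tile: ImageTile, stride: int = 10,
                      batch_size: int = 256) -> HeatmapGrid:
    """Score every lattice window of a tile with the bifocal net."""
    centres = enumerate_inference_centres(tile.shape, stride)
    rows, cols = lattice_shape(tile.shape, stride)
    scores = np.empty(len(centres), dtype=np.float64)
    px = tile.pixels
    for start in range(0, len(centres), batch_size):
        batch = centres[start:start + batch_size]
        narrow = np.stack([
            _standardize(px[y - 16:y + 16, x - 16:x + 16]) for x, y in batch])
        wide = np.stack([
            _standardize(px[y - 32:y + 32, x - 32:x + 32]) for x, y in batch])
        scores[start:start + len(batch)] = model.predict_proba(
            narrow, wide, batch_size=batch_size)[:, 1]
    return HeatmapGrid(scores=scores.reshape(rows, cols), stride=stride,
                       tile_id=tile.tile_id, case_id=tile.case_id,
                       microns_per_pixel=tile.microns_per_pixel)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render(grid: HeatmapGrid, threshold: float = 0.5,
           palette: tuple = (POSITIVE_COLOUR, NEGATIVE_COLOUR)) -> np.ndarray:
    """Pseudo-colour RGB image: positive colour where score >= threshold.

    Each lattice cell becomes a stride x stride block, so the image is at
    tile scale; the binary mask round-trips losslessly.
    """
    pos, neg = palette
    if tuple(pos) == tuple(neg):
        raise ValueError("palette must map the two classes to distinct colours")
    mask = grid.scores >= threshold
    img = np.where(mask[..., None], np.array(pos, np.uint8),
                   np.array(neg, np.uint8))
    return np.repeat(np.repeat(img, grid.stride, axis=0), grid.stride, axis=1)


def mask_from_rendered(image: np.ndarray, stride: int,
                       positive_colour=POSITIVE_COLOUR) -> np.ndarray:
    """Invert :func:`render`: recover the binary supra-threshold grid."""
    sub = image[::stride, ::stride]
    return np.all(sub == np.array(positive_colour, np.uint8), axis=-1)


def save_heatmap_png(grid: HeatmapGrid, path: str | Path,
                     threshold: float = 0.5) -> None:
    iio.imwrite(Path(path), render(grid, threshold))


# ---------------------------------------------------------------------------
# detection merging
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)


def merge_detections(grid: HeatmapGrid, threshold: float = 0.5,
                     tile: ImageTile | None = None) -> list[DetectionRecord]:
    """8-connected components of supra-threshold lattice cells -> cells.

    Each component yields one record at its score-weighted centroid
    (snapped to the nearest pixel); the component's maximum score is the
    detection score. When the source tile is supplied, a 64x64 crop
    around each centre is attached for the discriminability stage.
    """
    mask = grid.scores >= threshold
    labels, n = ndimage.label(mask, structure=_EIGHT)
    records: list[DetectionRecord] = []
    h = w = None
    if tile is not None:
        h, w = tile.shape
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        weights = grid.scores[rows, cols]
        total = weights.sum()
        r = float((rows * weights).sum() / total)
        c = float((cols * weights).sum() / total)
        x = int(round(grid.origin[0] + c * grid.stride))
        y = int(round(grid.origin[1] + r * grid.stride))
        crop = None
        if tile is not None:
            x0 = int(np.clip(x - 32, 0, w - 64))
            y0 = int(np.clip(y - 32, 0, h - 64))
            crop = tile.pixels[y0:y0 + 64, x0:x0 + 64].copy()
        records.append(DetectionRecord(
            centre=(x, y), score=float(weights.max()), crop=crop,
            case_id=grid.case_id, tile_id=grid.tile_id))
    return records


def detections_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "case_id": r.case_id, "tile_id": r.tile_id,
            "x": r.centre[0], "y": r.centre[1], "score": r.score,
            "sigma": r.sigma, "threshold_T": r.threshold_T,
            "discriminable": r.discriminable,
        })
    return pd.DataFrame(rows, columns=["case_id", "tile_id", "x", "y", "score",
                                       "sigma", "threshold_T", "discriminable"])


def write_detections(records, path: str | Path) -> None:
    detections_to_frame(records).to_csv(path, index=False)
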