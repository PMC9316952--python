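"""Point annotations and bifocal patch-pair dataset construction.

Annotations are point marks: a case id, a tile id, a 0-based pixel
coordinate (x = column, y = row) and a label, ``positive`` for an
immunoreactive cell centre or ``negative`` for a region without one.
From each mark a *bifocal pair* is cut: a 32x32 crop focused on the cell
and a co-centred 64x64 crop carrying the surrounding tissue context.
Crops use half-open ``[c - s/2, c + s/2)`` windows so even-sized patches
have an unambiguous centre; marks whose wide crop would cross a tile
border are skipped (and counted), never padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

MARK_COLUMNS = ["case_id", "tile_id", "x", "y", "label", "intensity"]
LABELS = ("positive", "negative")

NARROW = 32
WIDE = 64
HALF_WIDE = WIDE // 2


class AnnotationError(ValueError):
    """Malformed annotation input (bad row, bad coordinates, bad label)."""


@dataclass(frozen=True)
class MarkPoint:
    """One ground-truth point annotation."""

    case_id: str
    tile_id: str
    x: int
    y: int
    label: str
    intensity: float | None = None  # stain intensity for synthetic positives

    def __post_init__(self):
        if self.label not in LABELS:
            raise AnnotationError(f"unknown label {self.label!r}")
        if self.x < 0 or self.y < 0:
            raise AnnotationError(f"negative coordinate ({self.x}, {self.y})")


@dataclass(frozen=True)
class ImageTile:
    """An RGB raster tile with physical scale and its origin in the case."""

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    case_id: str
    tile_id: str
    microns_per_pixel: float = 0.25
    origin: tuple[int, int] = (0, 0)  # (x0, y0) of this tile in case coords

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class BifocalPatchPair:
    """Co-centred 32x32 and 64x64 crops plus label; the classifier's unit."""

    narrow: np.ndarray  # (32, 32, 3)
    wide: np.ndarray    # (64, 64, 3)
    centre: tuple[int, int]
    label: str
    case_id: str = ""
    tile_id: str = ""


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def write_marks(marks: Iterable[MarkPoint], path: str | Path) -> None:
    rows = [
        (m.case_id, m.tile_id, m.x, m.y, m.label,
         "" if m.intensity is None else m.intensity)
        for m in marks
    ]
    pd.DataFrame(rows, columns=MARK_COLUMNS).to_csv(path, index=False)


def read_marks(path: str | Path,
               tile_shape: tuple[int, int] | None = None) -> list[MarkPoint]:
    """Parse a marks CSV; malformed rows raise naming the 1-based data row.

    `tile_shape` (rows, cols), when given, additionally bounds-checks
    coordinates against the tile.
    """
    df = pd.read_csv(path, dtype={"case_id": str, "tile_id": str})
    missing = [c for c in MARK_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise AnnotationError(f"missing columns: {missing}")
    marks: list[MarkPoint] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            x, y = int(row.x), int(row.y)
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"row {i}: non-numeric coordinate") from exc
        if float(row.x) != x or float(row.y) != y:
            raise AnnotationError(f"row {i}: non-integer coordinate")
        if x < 0 or y < 0:
            raise AnnotationError(f"row {i}: negative coordinate ({x}, {y})")
        if tile_shape is not None and (y >= tile_shape[0] or x >= tile_shape[1]):
            raise AnnotationError(f"row {i}: coordinate outside tile {tile_shape}")
        if row.label not in LABELS:
            raise AnnotationError(f"row {i}: unknown label {row.label!r}")
        intensity = None
        if "intensity" in df.columns and pd.notna(row.intensity) \
                and str(row.intensity) != "":
            intensity = float(row.intensity)
        marks.append(MarkPoint(str(row.case_id), str(row.tile_id),
                               x, y, row.label, intensity))
    return marks


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def fits_in_tile(shape: tuple[int, int], centre: tuple[int, int]) -> bool:
    h, w = shape
    x, y = centre
    return HALF_WIDE <= x <= w - HALF_WIDE and HALF_WIDE <= y <= h - HALF_WIDE


def extract_bifocal_pair(tile: ImageTile, centre: tuple[int, int],
                         label: str = "positive") -> BifocalPatchPair:
    """Cut the co-centred 32/64 crops; centre must be >= 32 px from edges."""
    x, y = centre
    if not fits_in_tile(tile.shape, centre):
        raise AnnotationError(
            f"centre ({x}, {y}) too close to border of {tile.shape} tile "
            f"(needs {HALF_WIDE} px margin)")
    px = tile.pixels
    narrow = px[y - 16:y + 16, x - 16:x + 16].copy()
    wide = px[y - 32:y + 32, x - 32:x + 32].copy()
    return BifocalPatchPair(narrow=narrow, wide=wide, centre=(x, y),
                            label=label, case_id=tile.case_id,
                            tile_id=tile.tile_id)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _adjust_contrast(img: np.ndarray, factor: float) -> np.ndarray:
    mean = img.mean()
    return np.clip(mean + factor * (img - mean), 0.0, 1.0)


def _adjust_sharpness(img: np.ndarray, factor: float) -> np.ndarray:
    """factor < 1 blurs, 1 is identity, > 1 sharpens (unsharp blend)."""
    blurred = gaussian_filter(img, sigma=(1.0, 1.0, 0.0))
    return np.clip(blurred + factor * (img - blurred), 0.0, 1.0)


def _augment_pair(pair: BifocalPatchPair, rng: np.random.Generator,
                  contrast_range: tuple[float, float],
                  sharpness_range: tuple[float, float]) -> BifocalPatchPair:
    k = int(rng.integers(0, 4))  # right-angle rotations only
    c = float(rng.uniform(*contrast_range))
    s = float(rng.uniform(*sharpness_range))

    def tf(img):
        out = np.rot90(img, k, axes=(0, 1))
        return _adjust_sharpness(_adjust_contrast(out, c), s)

    return replace(pair, narrow=tf(pair.narrow), wide=tf(pair.wide))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def check_split_disjoint(train_marks: Sequence[MarkPoint],
                         test_marks: Sequence[MarkPoint]) -> None:
    """Training and testing data must come from different cases."""
    overlap = {m.case_id for m in train_marks} & {m.case_id for m in test_marks}
    if overlap:
        raise AnnotationError(f"train/test case overlap: {sorted(overlap)}")


def build_training_set(tiles: Sequence[ImageTile], marks: Sequence[MarkPoint],
                       augment: bool = False, n_variants: int = 3,
                       seed: int = 0,
                       contrast_range: tuple[float, float] = (0.8, 1.2),
                       sharpness_range: tuple[float, float] = (0.8, 1.2),
                       hard_negative_per_positive: int = 0,
                       hard_negative_distance: tuple[float, float] = (22.0, 40.0),
                       ) -> list[BifocalPatchPair]:
    """One pair per in-bounds mark, optionally plus augmented variants.

    With ``augment`` each pair is emitted once unmodified and
    ``n_variants`` more times under a seeded random right-angle rotation
    and contrast/sharpness scaling. Border marks are skipped and counted.

    ``hard_negative_per_positive`` additionally emits, for each positive
    mark, that many *near-miss* negative pairs centred a small random
    offset away (``hard_negative_distance`` pixels). These teach the
    classifier that an off-centre cell is not a hit, which sharpens the
    sliding-window response around true centres and keeps neighbouring
    cells from merging into one detection blob.
    """
    by_key = {(t.case_id, t.tile_id): t for t in tiles}
    rng = np.random.default_rng(seed)
    pairs: list[BifocalPatchPair] = []
    skipped = 0
    for m in marks:
        tile = by_key.get((m.case_id, m.tile_id))
        if tile is None:
            raise AnnotationError(
                f"mark references unknown tile {(m.case_id, m.tile_id)}")
        if not fits_in_tile(tile.shape, (m.x, m.y)):
            skipped += 1
            continue
        pair = extract_bifocal_pair(tile, (m.x, m.y), label=m.label)
        pairs.append(pair)
        if augment:
            pairs.extend(
                _augment_pair(pair, rng, contrast_range, sharpness_range)
                for _ in range(n_variants))
        if m.label == "positive" and hard_negative_per_positive > 0:
            for _ in range(hard_negative_per_positive):
                angle = rng.uniform(0.0, 2.0 * np.pi)
                dist = rng.uniform(*hard_negative_distance)
                x = int(round(m.x + dist * np.cos(angle)))
                y = int(round(m.y + dist * np.sin(angle)))
                if fits_in_tile(tile.shape, (x, y)):
                    pairs.append(extract_bifocal_pair(tile, (x, y),
                                                      label="negative"))
    if skipped:
        logger.info("skipped %d border marks (wide crop would cross the tile edge)",
                    skipped)
    return pairs


def enumerate_inference_centres(shape: tuple[int, int],
                                stride: int = 10) -> list[tuple[int, int]]:
    """Row-major lattice of window centres whose 64x64 crop fits the tile.

    Per axis there are ``floor((dim - 64) / stride) + 1`` centres, the
    first at 32 px from the edge, scanning from the upper-left to the
    bottom-right.
    """
    h, w = shape
    if h < WIDE or w < WIDE:
        raise AnnotationError(f"tile {shape} smaller than {WIDE}px window")
    if stride < 1:
        raise AnnotationError("stride must be >= 1")
    ys = range(HALF_WIDE, h - HALF_WIDE + 1, stride)
    xs = range(HALF_WIDE, w - HALF_WIDE + 1, stride)
    return [(x, y) for y in ys for x in xs]


def lattice_shape(shape: tuple[int, int], stride: int = 10) -> tuple[int, int]:
    """(rows, cols) of the inference lattice for a tile shape."""
    h, w = shape
    if h < WIDE or w < WIDE:
        raise AnnotationError(f"tile {shape} smaller than {WIDE}px window")
    return ((h - WIDE) // stride + 1, (w - WIDE) // stride + 1)
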