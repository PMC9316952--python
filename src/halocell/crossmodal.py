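"""Cell-to-morphology correlation: per-feature counts and densities.

Each retained cell is mapped (via the registration transform) onto the
H&E morphological feature raster and labelled with the class of the
nearest raster pixel; cells landing outside the raster are counted as
"unassigned" and excluded from densities. Densities are computed over
each feature region's own area (raster pixel count x physical pixel
area), giving a cells-per-mm^2 table per diagnostic feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .heatmap import DetectionRecord
from .synthetic import FeatureMapSpec

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class DensityReport:
    """Per-feature-class cell counts, region areas and densities."""

    classes: tuple[str, ...]
    counts: dict[str, int]
    areas_mm2: dict[str, float]
    densities: dict[str, float]
    n_unassigned: int

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": c, "n_cells": self.counts[c],
                 "area_mm2": self.areas_mm2[c],
                 "density_per_mm2": self.densities[c]} for c in self.classes]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "counts": self.counts, "areas_mm2": self.areas_mm2,
            "densities_per_mm2": self.densities,
            "n_unassigned": self.n_unassigned}, indent=2))


def assign_classes(cells: Sequence[DetectionRecord] | np.ndarray,
                   feature_map: FeatureMapSpec,
                   transform=None,
                   origins: Sequence[tuple[int, int]] | None = None) -> list[str]:
    """Feature-class label per cell by nearest raster pixel.

    `cells` are DetectionRecord objects (tile coordinates) or an (n, 2)
    array of (x, y) points already in case coordinates; `origins` gives
    each record's tile origin to lift tile coords into the case frame.
    `transform` (callable on (n, 2) arrays, e.g. a skimage transform)
    maps case coordinates into the feature raster's full-resolution
    frame; the raster's own ``scale`` then downsamples to raster cells.
    """
    if len(cells) == 0:
        return []
    if isinstance(cells, np.ndarray):
        pts = np.asarray(cells, dtype=float)
    else:
        pts = []
        for i, rec in enumerate(cells):
            ox, oy = origins[i] if origins is not None else (0, 0)
            pts.append((rec.centre[0] + ox, rec.centre[1] + oy))
        pts = np.asarray(pts, dtype=float)
    if transform is not None:
        pts = np.asarray(transform(pts), dtype=float)
    rc = np.round(pts[:, ::-1] / feature_map.scale).astype(int)  # (row, col)
    h, w = feature_map.labels.shape
    out: list[str] = []
    for r, c in rc:
        # nearest-pixel rule; snap half-open edge cases onto the raster
        r = min(max(r, 0), h - 1) if -1 <= r <= h else r
        c = min(max(c, 0), w - 1) if -1 <= c <= w else c
        if 0 <= r < h and 0 <= c < w:
            out.append(feature_map.class_names[feature_map.labels[r, c]])
        else:
            out.append(UNASSIGNED)
    return out


def density_report(assignments: Sequence[str], feature_map: FeatureMapSpec,
                   microns_per_pixel: float) -> DensityReport:
    """Counts and cells/mm^2 per feature class (region-area denominator).

    Classes with zero raster area are omitted with a warning.
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be positive")
    areas = feature_map.class_area_mm2(microns_per_pixel)
    counts = {c: 0 for c in feature_map.class_names}
    n_unassigned = 0
    for a in assignments:
        if a == UNASSIGNED:
            n_unassigned += 1
        elif a in counts:
            counts[a] += 1
        else:
            raise ValueError(f"assignment to unknown class {a!r}")
    kept = []
    for c in feature_map.class_names:
        if areas[c] <= 0:
            if counts[c]:
                raise ValueError(f"cells assigned to zero-area class {c!r}")
            warnings.warn(f"feature class {c!r} has zero area; omitted")
            continue
        kept.append(c)
    return DensityReport(
        classes=tuple(kept),
        counts={c: counts[c] for c in kept},
        areas_mm2={c: areas[c] for c in kept},
        densities={c: counts[c] / areas[c] for c in kept},
        n_unassigned=n_unassigned)
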