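"""Wavelet fusion of bimodal heatmaps (H&E features x immunostain cells).

The cell heatmap from an immunostained section is thresholded to keep
only the cells of interest, registered onto the H&E morphological
feature heatmap of the adjacent section via control points, and the two
images fused per RGB channel: single-level 2-D discrete wavelet
decomposition of both inputs, element-wise averaging of each of the
four coefficient bands (approximation, horizontal, vertical, diagonal),
inverse transform, channel concatenation. For any orthogonal wavelet
this equals plain pixel averaging ``(A + B) / 2`` — the wavelet path is
kept because band-wise fusion generalises to non-linear rules and makes
the frequency split explicit.

Default wavelet: Haar. Odd dimensions use symmetric extension and the
output is cropped back to the input size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt
from skimage import transform as sktransform

from .heatmap import POSITIVE_COLOUR


class RegistrationError(ValueError):
    """Control points insufficient or degenerate."""


@dataclass(frozen=True)
class ControlPointSet:
    """Matched coordinate pairs, moving (cell map) -> fixed (H&E map)."""

    moving: np.ndarray  # (n, 2) of (x, y)
    fixed: np.ndarray

    def __post_init__(self):
        moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        object.__setattr__(self, "moving", moving)
        object.__setattr__(self, "fixed", fixed)
        if moving.shape != fixed.shape or moving.shape[1] != 2:
            raise RegistrationError("matched point sets must be (n, 2) and equal")
        if len(moving) < 3:
            raise RegistrationError("need at least 3 control point pairs")
        centred = moving - moving.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9) < 2:
            raise RegistrationError("control points are collinear")

    @classmethod
    def identity_corners(cls, shape: tuple[int, int]) -> "ControlPointSet":
        h, w = shape
        pts = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        return cls(moving=pts, fixed=pts)


def estimate_transform(points: ControlPointSet, kind: str = "affine"):
    """Least-squares transform fitting the control points.

    Returns ``(tform, residual_rms)``; `kind` is ``"affine"`` or
    ``"similarity"``.
    """
    cls = {"affine": sktransform.AffineTransform,
           "similarity": sktransform.SimilarityTransform}.get(kind)
    if cls is None:
        raise ValueError(f"unknown transform kind {kind!r}")
    if hasattr(cls, "from_estimate"):
        tform = cls.from_estimate(points.moving, points.fixed)
        if not tform:
            raise RegistrationError("transform estimation failed")
    else:   # scikit-image < 0.26
        tform = cls()
        if not tform.estimate(points.moving, points.fixed):
            raise RegistrationError("transform estimation failed")
    residual = float(np.sqrt(np.mean(
        np.sum((tform(points.moving) - points.fixed) ** 2, axis=1))))
    return tform, residual


def threshold_cell_heatmap(heatmap: np.ndarray,
                           positive_colour=POSITIVE_COLOUR) -> np.ndarray:
    """Keep positive-colour pixels, black out everything else."""
    heatmap = np.asarray(heatmap)
    if heatmap.ndim != 3 or heatmap.shape[2] != 3:
        raise ValueError("expected an RGB heatmap")
    mask = np.all(heatmap == np.asarray(positive_colour, heatmap.dtype), axis=-1)
    out = np.zeros_like(heatmap)
    out[mask] = heatmap[mask]
    return out


def dwt_fuse(img_a: np.ndarray, img_b: np.ndarray,
             wavelet: str = "haar") -> np.ndarray:
    """Band-averaged single-level DWT fusion of two equal-size RGB images.

    Inputs may be uint8 or float; computation is float, output matches
    the input range (clipped).
    """
    a = np.asarray(img_a)
    b = np.asarray(img_b)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    was_uint8 = a.dtype == np.uint8
    af = a.astype(np.float64)
    bf = b.astype(np.float64)
    if af.ndim == 2:
        af, bf = af[..., None], bf[..., None]
    h, w = af.shape[:2]
    fused = np.empty_like(af)
    for ch in range(af.shape[2]):
        ca, (cha, cva, cda) = pywt.dwt2(af[..., ch], wavelet, mode="symmetric")
        cb, (chb, cvb, cdb) = pywt.dwt2(bf[..., ch], wavelet, mode="symmetric")
        bands = ((ca + cb) / 2.0,
                 ((cha + chb) / 2.0, (cva + cvb) / 2.0, (cda + cdb) / 2.0))
        rec = pywt.idwt2(bands, wavelet, mode="symmetric")
        fused[..., ch] = rec[:h, :w]
    if np.asarray(img_a).ndim == 2:
        fused = fused[..., 0]
    if was_uint8:
        return np.clip(np.round(fused), 0, 255).astype(np.uint8)
    return np.clip(fused, 0.0, 1.0)


def fuse_case(he_heatmap: np.ndarray, cell_heatmap: np.ndarray,
              points: ControlPointSet | None = None, wavelet: str = "haar",
              positive_colour=POSITIVE_COLOUR, out_dir: str | Path | None = None):
    """Threshold -> register onto the H&E frame -> DWT-fuse.

    Without control points the cell map is assumed pre-aligned (resized
    only if shapes differ). Returns ``(fused, thresholded, registered,
    transform)``; intermediates are written to ``out_dir`` when given.
    """
    cells = threshold_cell_heatmap(cell_heatmap, positive_colour)
    tform = None
    if points is not None:
        tform, _ = estimate_transform(points)
        registered = sktransform.warp(
            cells.astype(float), inverse_map=tform.inverse,
            output_shape=he_heatmap.shape[:2], order=0, preserve_range=True)
    elif cells.shape != he_heatmap.shape:
        registered = sktransform.resize(
            cells.astype(float), he_heatmap.shape[:2], order=0,
            preserve_range=True, anti_aliasing=False)
    else:
        registered = cells.astype(float)
    if he_heatmap.dtype == np.uint8:
        registered = np.clip(np.round(registered), 0, 255).astype(np.uint8)
    fused = dwt_fuse(he_heatmap, registered, wavelet=wavelet)
    if out_dir is not None:
        import imageio.v3 as iio
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out_dir / "cells_thresholded.png", _to_u8(cells))
        iio.imwrite(out_dir / "cells_registered.png", _to_u8(registered))
        iio.imwrite(out_dir / "fused.png", _to_u8(fused))
        if tform is not None:
            (out_dir / "transform.json").write_text(
                json.dumps({"matrix": tform.params.tolist()}, indent=2))
    return fused, cells, registered, tform


def _to_u8(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img
    return np.clip(np.round(img * 255 if img.max() <= 1.0 else img),
                   0, 255).astype(np.uint8)
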