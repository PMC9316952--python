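"""Seeded synthetic immunohistochemistry tiles with ground truth.

Emulates 40x-magnification DAB-stained tissue the way the downstream
stages need it: a pale eosinophilic background with mild texture,
scattered blue-grey counterstained nuclei, and brown perinuclear rings
("halo cells") of varying stain intensity at known centres. Every tile
comes with exported ground truth — positive ring centres with their
stain intensity and negative marks on background and nuclei clusters —
so detection, filtering, morphometry and fusion are all testable without
external slides.

Stain intensity is defined as ``1 - relative luminance`` of the ring
pixels: stronger staining means darker brown and a higher signal after
the grayscale inversion used by the discriminability stage. Ring colours
interpolate white -> DAB brown ``(0.36, 0.22, 0.08)``; that endpoint has
luminance 0.24, so intensities up to 0.75 are renderable and the config
validates the requested range against that bound.

Not modelled: scanner artefacts, defocus, tissue folds, photorealism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .annotations import ImageTile, MarkPoint

# DAB-brown endpoint and derived renderable intensity span
_BROWN = np.array([0.36, 0.22, 0.08])
_LUMA = np.array([0.2126, 0.7152, 0.0722])
STAIN_SPAN = float(1.0 - _BROWN @ _LUMA)  # ~0.7603: max renderable intensity

_BACKGROUND = np.array([0.96, 0.93, 0.94])  # pale eosinophilic
_NUCLEUS = np.array([0.42, 0.46, 0.62])     # blue-grey counterstain

MORPHOLOGICAL_CLASSES = (
    "normal vessels",
    "normal brain",
    "geographic necrosis",
    "viable tumour",
    "palisading necrosis",
    "microvascular proliferation",
)

DEFAULT_PALETTE = {
    "normal vessels": (228, 26, 28),
    "normal brain": (55, 126, 184),
    "geographic necrosis": (77, 175, 74),
    "viable tumour": (152, 78, 163),
    "palisading necrosis": (255, 127, 0),
    "microvascular proliferation": (255, 255, 51),
}

BORDER_MARGIN = 32          # both focal crops must fit around every centre
NEGATIVE_CLEARANCE = 64     # negative marks stay this far from positives


class PackingError(RuntimeError):
    """Raised when cell placement constraints cannot all be satisfied."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic stained-tissue generator."""

    tile_width: int = 512
    tile_height: int = 512
    n_cells: int = 12
    n_negatives: int | None = None          # default: same as n_cells
    cell_radius_range: tuple[float, float] = (8.0, 14.0)
    halo_ring_width: float = 5.0
    stain_intensity_range: tuple[float, float] = (0.25, 0.70)
    stain_intensity_strata: tuple[tuple[float, float], ...] | None = None
    background_noise_sd: float = 0.01
    nuclei_density: int = 120               # counterstained nuclei per tile
    microns_per_pixel: float = 0.25         # 40x-like scan
    seed: int = 0

    def __post_init__(self):
        if self.tile_width < 128 or self.tile_height < 128:
            raise ValueError("tile dimensions must be >= 128 px")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid cell_radius_range")
        for rng_ in self.strata():
            a, b = rng_
            if not (0.0 <= a <= b <= 0.75):
                raise ValueError(
                    f"stain intensity range {rng_} outside renderable [0, 0.75]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")

    def strata(self) -> tuple[tuple[float, float], ...]:
        return self.stain_intensity_strata or (self.stain_intensity_range,)

    @property
    def outer_radius(self) -> float:
        return self.cell_radius_range[1] + self.halo_ring_width

    @property
    def min_separation(self) -> float:
        # no two rings may touch: twice the maximum outer radius
        return 2.0 * self.outer_radius


@dataclass(frozen=True)
class FeatureMapSpec:
    """Categorical H&E morphological-feature raster for one case.

    ``labels`` holds one class index per raster cell; ``scale`` is the
    edge length in full-resolution pixels each raster cell covers (the
    heatmap stride), so the raster lives at heatmap resolution. The
    palette must be injective so rendered maps are invertible.
    """

    labels: np.ndarray
    class_names: tuple[str, ...]
    palette: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE))
    scale: int = 10
    densities: dict[str, float] | None = None  # cells per mm^2 per class

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.min() < 0 or labels.max() >= len(self.class_names):
            raise ValueError("label raster references unknown class index")
        colours = [self.palette[c] for c in self.class_names]
        if len(set(map(tuple, colours))) != len(colours):
            raise ValueError("palette must be injective")

    @classmethod
    def vertical_bands(cls, class_names, case_shape_px, scale=10,
                       palette=None, densities=None) -> "FeatureMapSpec":
        """Equal-width vertical class bands spanning a case mosaic."""
        h, w = case_shape_px
        gh, gw = int(np.ceil(h / scale)), int(np.ceil(w / scale))
        cols = np.linspace(0, len(class_names), gw, endpoint=False).astype(int)
        labels = np.broadcast_to(cols, (gh, gw)).copy()
        return cls(labels=labels, class_names=tuple(class_names),
                   palette=palette or {c: DEFAULT_PALETTE.get(c, (17 * i % 256, 97 * i % 256, 53 * i % 256))
                                       for i, c in enumerate(class_names)},
                   scale=scale, densities=densities)

    def class_area_mm2(self, microns_per_pixel: float) -> dict[str, float]:
        cell_mm = self.scale * microns_per_pixel / 1000.0
        areas = {}
        for i, name in enumerate(self.class_names):
            areas[name] = float((self.labels == i).sum()) * cell_mm ** 2
        return areas

    def render(self) -> np.ndarray:
        """RGB uint8 image of the raster, one pixel per raster cell."""
        out = np.zeros((*self.labels.shape, 3), dtype=np.uint8)
        for i, name in enumerate(self.class_names):
            out[self.labels == i] = self.palette[name]
        return out


@dataclass(frozen=True)
class SyntheticCase:
    tiles: list[ImageTile]
    marks: list[MarkPoint]
    feature_map: FeatureMapSpec | None


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def ring_colour(intensity: float) -> np.ndarray:
    """RGB of a ring pixel with the requested stain intensity.

    Linear blend white -> DAB brown; relative luminance is exactly
    ``1 - intensity`` by construction.
    """
    t = intensity / STAIN_SPAN
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"intensity {intensity} outside renderable range")
    return (1.0 - t) * np.ones(3) + t * _BROWN


def _disc_mask(shape, cx, cy, radius):
    h, w = shape
    y, x = np.ogrid[:h, :w]
    return (x - cx) ** 2 + (y - cy) ** 2 <= radius ** 2


def _paint_halo_cell(img, cx, cy, r_inner, ring_width, intensity, rng, noise_sd):
    outer = _disc_mask(img.shape[:2], cx, cy, r_inner + ring_width)
    inner = _disc_mask(img.shape[:2], cx, cy, r_inner)
    ring = outer & ~inner
    colour = ring_colour(intensity)
    img[ring] = colour
    if noise_sd > 0:
        img[ring] += rng.normal(0.0, noise_sd, size=(int(ring.sum()), 1))
    # perinuclear: counterstained nucleus inside the ring
    nucleus = _disc_mask(img.shape[:2], cx, cy, max(2.0, r_inner - 2.0))
    img[nucleus] = _NUCLEUS + rng.normal(0.0, 0.015, size=(int(nucleus.sum()), 3))
    return ring


def _paint_background(shape, rng, noise_sd):
    h, w = shape
    img = np.ones((h, w, 3)) * _BACKGROUND
    # low-frequency eosinophilic texture
    coarse = rng.normal(0.0, 1.0, size=(h // 16 + 1, w // 16 + 1))
    texture = np.kron(coarse, np.ones((16, 16)))[:h, :w]
    img += 0.012 * texture[..., None]
    if noise_sd > 0:
        # luminance noise (channel-correlated), as on a brightfield scan
        img += rng.normal(0.0, noise_sd, size=(h, w, 1))
    return img


def _scatter_nuclei(img, rng, count, keepout_centres, keepout_radius):
    """Blue-grey nuclei discs avoiding halo rings; returns their centres."""
    h, w = img.shape[:2]
    centres = []
    attempts = 0
    while len(centres) < count and attempts < count * 30:
        attempts += 1
        cx = rng.uniform(4, w - 4)
        cy = rng.uniform(4, h - 4)
        if keepout_centres.size and np.min(
                np.hypot(keepout_centres[:, 0] - cx,
                         keepout_centres[:, 1] - cy)) < keepout_radius:
            continue
        r = rng.uniform(2.5, 5.0)
        mask = _disc_mask((h, w), cx, cy, r)
        img[mask] = _NUCLEUS + rng.normal(0.0, 0.02, size=(int(mask.sum()), 3))
        centres.append((cx, cy))
    return np.array(centres) if centres else np.zeros((0, 2))


def _sample_positions(rng, n, shape, margin, min_sep,
                      existing=None, max_attempts_factor=2000):
    """Rejection-sample n centres with border margin and pairwise separation."""
    h, w = shape
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise PackingError("tile too small for the 32 px border margin")
    placed = [] if existing is None else [tuple(p) for p in existing]
    new = []
    attempts = 0
    limit = max(1, n) * max_attempts_factor
    while len(new) < n:
        if attempts >= limit:
            raise PackingError(
                f"cannot place {n} cells with min separation {min_sep:.1f} px "
                f"and {margin} px border margin in a {w}x{h} tile")
        attempts += 1
        cx = int(rng.integers(margin, w - margin + 1))
        cy = int(rng.integers(margin, h - margin + 1))
        if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep ** 2
               for px, py in placed):
            placed.append((cx, cy))
            new.append((cx, cy))
    return new


def _draw_intensity(rng, config: SyntheticConfig) -> float:
    strata = config.strata()
    lo, hi = strata[int(rng.integers(len(strata)))]
    return float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def _render_tile(config: SyntheticConfig, rng: np.random.Generator,
                 positives, case_id: str, tile_id: str,
                 origin=(0, 0)) -> tuple[ImageTile, list[MarkPoint]]:
    """Render one tile given its positive cells (x, y, radius, intensity)."""
    shape = (config.tile_height, config.tile_width)
    img = _paint_background(shape, rng, config.background_noise_sd)

    pos_centres = np.array([(p[0], p[1]) for p in positives]) \
        if positives else np.zeros((0, 2))
    nuc_centres = _scatter_nuclei(
        img, rng, config.nuclei_density, pos_centres,
        keepout_radius=config.outer_radius + 8.0)

    marks: list[MarkPoint] = []
    for (cx, cy, radius, intensity) in positives:
        _paint_halo_cell(img, cx, cy, radius, config.halo_ring_width,
                         intensity, rng, noise_sd=0.008)
        marks.append(MarkPoint(case_id, tile_id, int(cx), int(cy),
                               "positive", intensity))

    # negatives: half plain background, half on nuclei clusters, all well
    # clear of any positive cell
    n_neg = config.n_negatives if config.n_negatives is not None else config.n_cells
    neg_done = 0
    attempts = 0
    def far_from_positives(x, y):
        if pos_centres.size == 0:
            return True
        return np.min(np.hypot(pos_centres[:, 0] - x,
                               pos_centres[:, 1] - y)) >= NEGATIVE_CLEARANCE
    while neg_done < n_neg and attempts < 3000 * max(1, n_neg):
        attempts += 1
        if neg_done % 2 == 1 and len(nuc_centres):
            nx, ny = nuc_centres[int(rng.integers(len(nuc_centres)))]
            x = int(np.clip(round(nx), BORDER_MARGIN,
                            config.tile_width - BORDER_MARGIN))
            y = int(np.clip(round(ny), BORDER_MARGIN,
                            config.tile_height - BORDER_MARGIN))
        else:
            x = int(rng.integers(BORDER_MARGIN,
                                 config.tile_width - BORDER_MARGIN + 1))
            y = int(rng.integers(BORDER_MARGIN,
                                 config.tile_height - BORDER_MARGIN + 1))
        if far_from_positives(x, y):
            marks.append(MarkPoint(case_id, tile_id, x, y, "negative"))
            neg_done += 1
    if neg_done < n_neg:
        raise PackingError(
            f"cannot place {n_neg} negative marks >= {NEGATIVE_CLEARANCE} px "
            "from every positive centre")

    np.clip(img, 0.0, 1.0, out=img)
    tile = ImageTile(pixels=img, case_id=case_id, tile_id=tile_id,
                     microns_per_pixel=config.microns_per_pixel, origin=origin)
    return tile, marks


def generate_tile(config: SyntheticConfig, case_id: str = "case0",
                  tile_id: str = "tile0") -> tuple[ImageTile, list[MarkPoint]]:
    """Generate one tile with ``config.n_cells`` halo cells plus negatives.

    Identical config (including seed) yields bit-identical pixels and
    marks. Raises :class:`PackingError` when the separation and margin
    constraints cannot be met.
    """
    rng = np.random.default_rng(config.seed)
    centres = _sample_positions(
        rng, config.n_cells, (config.tile_height, config.tile_width),
        margin=BORDER_MARGIN, min_sep=config.min_separation)
    positives = [
        (cx, cy, float(rng.uniform(*config.cell_radius_range)),
         _draw_intensity(rng, config))
        for (cx, cy) in centres
    ]
    return _render_tile(config, rng, positives, case_id, tile_id)


def generate_case(config: SyntheticConfig,
                  feature_spec: FeatureMapSpec | None = None,
                  n_tiles: int = 4,
                  case_id: str = "case0") -> SyntheticCase:
    """Generate a case of ``n_tiles`` tiles laid out left to right.

    Without a feature spec each tile gets ``config.n_cells`` cells. With
    a spec carrying per-class densities (cells/mm^2), per-class counts
    are Poisson with mean ``density x class area`` and cells are placed
    uniformly within their class region; the spec's raster is the
    companion feature map at heatmap resolution.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    rng = np.random.default_rng(config.seed)
    th, tw = config.tile_height, config.tile_width
    case_w = n_tiles * tw

    # decide global cell placements in case coordinates
    placements: list[tuple[int, int, float]] = []  # (x_case, y, intensity)
    if feature_spec is not None and feature_spec.densities:
        areas = feature_spec.class_area_mm2(config.microns_per_pixel)
        for ci, cname in enumerate(feature_spec.class_names):
            lam = feature_spec.densities.get(cname, 0.0) * areas[cname]
            n_c = int(rng.poisson(lam))
            cells_rc = np.argwhere(feature_spec.labels == ci)
            if n_c and not len(cells_rc):
                continue
            got = 0
            attempts = 0
            while got < n_c and attempts < 4000 * max(1, n_c):
                attempts += 1
                r, c = cells_rc[int(rng.integers(len(cells_rc)))]
                x = int(c * feature_spec.scale
                        + rng.integers(feature_spec.scale))
                y = int(r * feature_spec.scale
                        + rng.integers(feature_spec.scale))
                tx = x % tw
                if not (BORDER_MARGIN <= tx <= tw - BORDER_MARGIN
                        and BORDER_MARGIN <= y <= th - BORDER_MARGIN
                        and x < case_w):
                    continue
                if all((x - px) ** 2 + (y - py) ** 2
                       >= config.min_separation ** 2
                       for px, py, _ in placements):
                    placements.append((x, y, _draw_intensity(rng, config)))
                    got += 1
            if got < n_c:
                raise PackingError(
                    f"cannot place {n_c} cells in class {cname!r} under the "
                    f"separation/margin constraints")
    else:
        for t in range(n_tiles):
            centres = _sample_positions(
                rng, config.n_cells, (th, tw),
                margin=BORDER_MARGIN, min_sep=config.min_separation)
            placements.extend((cx + t * tw, cy, _draw_intensity(rng, config))
                              for cx, cy in centres)

    tiles: list[ImageTile] = []
    marks: list[MarkPoint] = []
    for t in range(n_tiles):
        tile_id = f"tile{t}"
        local = [
            (x - t * tw, y, float(rng.uniform(*config.cell_radius_range)), s)
            for (x, y, s) in placements if t * tw <= x < (t + 1) * tw
        ]
        tile, tile_marks = _render_tile(config, rng, local, case_id, tile_id,
                                        origin=(t * tw, 0))
        tiles.append(tile)
        marks.extend(tile_marks)
    return SyntheticCase(tiles=tiles, marks=marks, feature_map=feature_spec)


# ---------------------------------------------------------------------------
# read-back and I/O
# ---------------------------------------------------------------------------

def ring_mask_for_mark(tile: ImageTile, mark: MarkPoint,
                       config: SyntheticConfig) -> np.ndarray:
    """Boolean mask of a generous annulus around a positive mark."""
    lo = config.cell_radius_range[0]
    outer = _disc_mask(tile.shape, mark.x, mark.y, config.outer_radius)
    inner = _disc_mask(tile.shape, mark.x, mark.y, lo)
    return outer & ~inner

def measured_ring_intensity(tile: ImageTile, mark: MarkPoint,
                            config: SyntheticConfig) -> float:
    """Mean ``1 - luminance`` over clearly stained annulus pixels.

    Reads the rendered raster back; used to validate ground-truth
    fidelity of the generator.
    """
    mask = ring_mask_for_mark(tile, mark, config)
    px = tile.pixels[mask]
    # keep brown (blue-deficient) pixels only: excludes the pale background
    # (blue excess ~0) and counterstained nuclei (blue excess > 0)
    blue_excess = px[:, 2] - (px[:, 0] + px[:, 1]) / 2.0
    ring = blue_excess < -0.012
    if not ring.any():
        raise ValueError("no stained ring pixels found at this mark")
    stain = 1.0 - px[ring] @ _LUMA
    return float(stain.mean())


def write_tile(tile: ImageTile, path: str | Path) -> None:
    path = Path(path)
    arr = (np.clip(tile.pixels, 0, 1) * 255).round().astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_tile(path: str | Path, case_id: str = "", tile_id: str = "",
              microns_per_pixel: float = 0.25,
              origin: tuple[int, int] = (0, 0)) -> ImageTile:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return ImageTile(pixels=arr.astype(np.float64) / 255.0,
                     case_id=case_id or path.stem, tile_id=tile_id or path.stem,
                     microns_per_pixel=microns_per_pixel, origin=origin)


def write_feature_map(spec: FeatureMapSpec, png_path: str | Path,
                      json_path: str | Path) -> None:
    """Indexed PNG (pixel value = class index) plus JSON palette sidecar."""
    iio.imwrite(Path(png_path), spec.labels.astype(np.uint8))
    meta = {
        "class_names": list(spec.class_names),
        "palette": {k: list(v) for k, v in spec.palette.items()},
        "scale": spec.scale,
        "densities": spec.densities,
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def read_feature_map(png_path: str | Path, json_path: str | Path) -> FeatureMapSpec:
    meta = json.loads(Path(json_path).read_text())
    labels = np.asarray(iio.imread(Path(png_path)), dtype=np.int64)
    return FeatureMapSpec(
        labels=labels, class_names=tuple(meta["class_names"]),
        palette={k: tuple(v) for k, v in meta["palette"].items()},
        scale=int(meta["scale"]), densities=meta.get("densities"))
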