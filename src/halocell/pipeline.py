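"""End-to-end orchestration: simulate -> dataset -> train -> infer ->
filter -> measure -> fuse -> density.

One :class:`PipelineConfig` drives every stage; a single top-level seed
deterministically derives per-stage seeds so stages can be rerun
independently yet reproducibly. Every artefact lands under
``out_dir`` and is recorded (with its SHA-256) in ``manifest.json``;
rerunning a completed stage with an unchanged stage config is a no-op.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import imageio.v3 as iio

from . import annotations as ann
from . import bcnn as bc
from . import crossmodal as xm
from . import discriminability as disc
from . import fusion as fu
from . import heatmap as hm
from . import morphometry as mm
from . import synthetic as syn

logger = logging.getLogger(__name__)

STAGES = ("simulate", "dataset", "train", "infer", "filter", "measure",
          "fuse", "density")


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "halocell_run"
    seed: int = 0
    # synthetic data
    tile_width: int = 512
    tile_height: int = 512
    n_cells: int = 10
    n_tiles: int = 4                     # tiles per case (train and test)
    stain_intensity_range: tuple = (0.25, 0.70)
    stain_intensity_strata: tuple | None = None
    microns_per_pixel: float = 0.25
    feature_classes: tuple = syn.MORPHOLOGICAL_CLASSES[:3]
    # dataset
    augment: bool = False
    n_variants: int = 3
    hard_negatives: int = 2              # near-miss pairs per positive mark
    # model
    channels: tuple = (16, 32, 64)
    epochs: int = 15
    batch_size: int = 32
    learning_rate: float = 0.0005
    # inference / filtering / fusion
    stride: int = 10
    decision_threshold: float = 0.5
    gaussian_sigma: float = 1.0
    wavelet: str = "haar"
    stages: tuple = STAGES

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        for key in ("stain_intensity_range", "channels", "feature_classes",
                    "stages"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if data.get("stain_intensity_strata"):
            data["stain_intensity_strata"] = tuple(
                tuple(s) for s in data["stain_intensity_strata"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the top-level seed."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"config": {}, "stages": {}}
        self.manifest["config"] = _jsonable(asdict(config))

    # -- bookkeeping ------------------------------------------------------
    def _config_hash(self, stage: str) -> str:
        payload = json.dumps(_jsonable(asdict(self.config)), sort_keys=True)
        return hashlib.sha256(f"{stage}:{payload}".encode()).hexdigest()

    def _done(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry or entry.get("config_hash") != self._config_hash(stage):
            return False
        return all((self.out / rel).exists()
                   for rel in entry["artefacts"].values())

    def _record(self, stage: str, artefacts: dict[str, Path], **counts):
        self.manifest["stages"][stage] = {
            "config_hash": self._config_hash(stage),
            "artefacts": {k: str(p.relative_to(self.out))
                          for k, p in artefacts.items()},
            "hashes": {k: _sha256(p) for k, p in artefacts.items()},
            "counts": counts,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))
        logger.info("stage %-8s done: %s", stage,
                    ", ".join(f"{k}={v}" for k, v in counts.items()))

    def run(self) -> dict:
        for stage in STAGES:
            if stage not in self.config.stages:
                continue
            if self._done(stage):
                logger.info("stage %-8s up to date, skipping", stage)
                continue
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise StageError(f"stage {stage!r} failed: {exc}") from exc
        return self.manifest

    # -- helpers ----------------------------------------------------------
    def _synth_config(self, which: str) -> syn.SyntheticConfig:
        c = self.config
        return syn.SyntheticConfig(
            tile_width=c.tile_width, tile_height=c.tile_height,
            n_cells=c.n_cells,
            stain_intensity_range=tuple(c.stain_intensity_range),
            stain_intensity_strata=c.stain_intensity_strata,
            microns_per_pixel=c.microns_per_pixel,
            seed=stage_seed(c.seed, f"simulate:{which}"))

    def _load_case(self, which: str):
        marks = ann.read_marks(self.out / f"{which}_marks.csv")
        tiles = []
        for t in range(self.config.n_tiles):
            path = self.out / f"{which}_tile{t}.png"
            tiles.append(syn.read_tile(
                path, case_id=which, tile_id=f"tile{t}",
                microns_per_pixel=self.config.microns_per_pixel,
                origin=(t * self.config.tile_width, 0)))
        return tiles, marks

    # -- stages -----------------------------------------------------------
    def stage_simulate(self):
        c = self.config
        artefacts: dict[str, Path] = {}
        feature_map = None
        for which in ("train", "test"):
            spec = None
            if which == "test":
                case_shape = (c.tile_height, c.n_tiles * c.tile_width)
                spec = syn.FeatureMapSpec.vertical_bands(
                    c.feature_classes, case_shape, scale=c.stride)
            case = syn.generate_case(self._synth_config(which), spec,
                                     n_tiles=c.n_tiles, case_id=which)
            for tile in case.tiles:
                p = self.out / f"{which}_{tile.tile_id}.png"
                syn.write_tile(tile, p)
                artefacts[f"{which}_{tile.tile_id}"] = p
            mp = self.out / f"{which}_marks.csv"
            ann.write_marks(case.marks, mp)
            artefacts[f"{which}_marks"] = mp
            if spec is not None:
                fp, fj = self.out / "feature_map.png", self.out / "feature_map.json"
                syn.write_feature_map(spec, fp, fj)
                artefacts["feature_map"] = fp
                artefacts["feature_map_meta"] = fj
                feature_map = spec
        n_marks = sum(1 for _ in ann.read_marks(self.out / "train_marks.csv"))
        self._record("simulate", artefacts, train_marks=n_marks)

    def stage_dataset(self):
        c = self.config
        train_tiles, train_marks = self._load_case("train")
        _, test_marks = self._load_case("test")
        ann.check_split_disjoint(train_marks, test_marks)
        pairs = ann.build_training_set(
            train_tiles, train_marks, augment=c.augment,
            n_variants=c.n_variants,
            hard_negative_per_positive=c.hard_negatives,
            seed=stage_seed(c.seed, "dataset"))
        narrow, wide, labels = bc.pairs_to_arrays(pairs)
        p = self.out / "training_pairs.npz"
        np.savez_compressed(p, narrow=narrow, wide=wide, labels=labels)
        self._record("dataset", {"training_pairs": p}, pairs=len(pairs),
                     positives=int(labels.sum()))

    def stage_train(self):
        c = self.config
        with np.load(self.out / "training_pairs.npz") as data:
            arrays = (data["narrow"], data["wide"], data["labels"])
        cfg = bc.BCNNConfig(channels=tuple(c.channels), epochs=c.epochs,
                            batch_size=c.batch_size,
                            learning_rate=c.learning_rate,
                            seed=stage_seed(c.seed, "train"))
        model = bc.build_model(cfg)
        history = bc.train(model, arrays, cfg)
        model.save(self.out / "model")
        hp = self.out / "history.json"
        hp.write_text(json.dumps(history, indent=2))
        self._record("train", {"model": self.out / "model.npz",
                               "model_config": self.out / "model.json",
                               "history": hp},
                     epochs=c.epochs, final_loss=round(history["loss"][-1], 4))

    def stage_infer(self):
        c = self.config
        model = bc.BifocalNet.load(self.out / "model")
        tiles, _ = self._load_case("test")
        artefacts, all_records = {}, []
        for tile in tiles:
            grid = hm.sliding_inference(model, tile, stride=c.stride)
            grid.save(self.out / f"grid_{tile.tile_id}")
            png = self.out / f"heatmap_{tile.tile_id}.png"
            hm.save_heatmap_png(grid, png, threshold=c.decision_threshold)
            artefacts[f"grid_{tile.tile_id}"] = \
                self.out / f"grid_{tile.tile_id}.npz"
            artefacts[f"heatmap_{tile.tile_id}"] = png
            all_records.extend(
                hm.merge_detections(grid, threshold=c.decision_threshold,
                                    tile=tile))
        dp = self.out / "detections.csv"
        hm.write_detections(all_records, dp)
        artefacts["detections"] = dp
        self._record("infer", artefacts, detections=len(all_records))

    def _detections_with_crops(self):
        c = self.config
        tiles, _ = self._load_case("test")
        model = bc.BifocalNet.load(self.out / "model")
        records = []
        for tile in tiles:
            grid = hm.HeatmapGrid.load(self.out / f"grid_{tile.tile_id}")
            records.extend(hm.merge_detections(
                grid, threshold=c.decision_threshold, tile=tile))
        return tiles, records

    def stage_filter(self):
        c = self.config
        tiles, records = self._detections_with_crops()
        if not records:
            raise StageError("no detections to filter")
        disc.score_detections(records, gaussian_sigma=c.gaussian_sigma)
        keep, drop, summary = disc.filter_case(records)
        sp = self.out / "threshold_summary.json"
        summary.to_json(sp)
        dp = self.out / "detections.csv"
        hm.write_detections(records, dp)
        self._record("filter", {"detections": dp, "threshold_summary": sp},
                     detections=len(records), discriminable=len(keep),
                     discarded=len(drop), T=round(summary.T, 4))

    def stage_measure(self):
        c = self.config
        tiles, records = self._detections_with_crops()
        disc.score_detections(records, gaussian_sigma=c.gaussian_sigma)
        keep, _, _ = disc.filter_case(records)
        rows, cells = [], []
        for rec in keep:
            patch = disc.preprocess(rec.crop, gaussian_sigma=c.gaussian_sigma,
                                    enhance=False)
            try:
                cell = mm.measure_patch(patch, rec.sigma)
            except mm.MorphometryError:
                continue
            cells.append(cell)
            rows.append({"case_id": rec.case_id, "tile_id": rec.tile_id,
                         "x": rec.centre[0], "y": rec.centre[1],
                         "area_px": cell.area, "perimeter_px": cell.perimeter,
                         "compactness": cell.compactness,
                         "min_intensity": cell.min_intensity})
        mp = self.out / "morphometry.csv"
        pd.DataFrame(rows, columns=["case_id", "tile_id", "x", "y", "area_px",
                                    "perimeter_px", "compactness",
                                    "min_intensity"]).to_csv(mp, index=False)
        area_mm2 = (c.n_tiles * c.tile_width * c.tile_height
                    * (c.microns_per_pixel / 1000.0) ** 2)
        summary = mm.case_summary(cells, area_mm2)
        sp = self.out / "case_features.json"
        sp.write_text(json.dumps(dataclasses.asdict(summary), indent=2))
        self._record("measure", {"morphometry": mp, "case_features": sp},
                     cells=len(cells))

    def _case_cell_heatmap(self) -> np.ndarray:
        """Mosaic the per-tile rendered heatmaps into the case frame."""
        c = self.config
        canvas = np.zeros((c.tile_height, c.n_tiles * c.tile_width, 3),
                          dtype=np.uint8)
        for t in range(c.n_tiles):
            img = iio.imread(self.out / f"heatmap_tile{t}.png")
            canvas[:img.shape[0], t * c.tile_width:
                   t * c.tile_width + img.shape[1]] = img
        return canvas

    def stage_fuse(self):
        c = self.config
        spec = syn.read_feature_map(self.out / "feature_map.png",
                                    self.out / "feature_map.json")
        he = np.repeat(np.repeat(spec.render(), spec.scale, axis=0),
                       spec.scale, axis=1)
        he = he[:c.tile_height, :c.n_tiles * c.tile_width]
        cells = self._case_cell_heatmap()
        points = fu.ControlPointSet.identity_corners(he.shape[:2])
        fused, *_ = fu.fuse_case(he, cells, points, wavelet=c.wavelet,
                                 out_dir=self.out / "fusion")
        fp = self.out / "fused.png"
        iio.imwrite(fp, fused)
        self._record("fuse", {"fused": fp,
                              "he_frame": self.out / "fusion" / "fused.png"})

    def stage_density(self):
        c = self.config
        spec = syn.read_feature_map(self.out / "feature_map.png",
                                    self.out / "feature_map.json")
        df = pd.read_csv(self.out / "detections.csv")
        if "discriminable" in df.columns and df["discriminable"].notna().any():
            df = df[df["discriminable"].astype(bool)]
        origins = {f"tile{t}": (t * c.tile_width, 0)
                   for t in range(c.n_tiles)}
        pts = np.array([[row.x + origins[row.tile_id][0],
                         row.y + origins[row.tile_id][1]]
                        for row in df.itertuples()], dtype=float) \
            if len(df) else np.zeros((0, 2))
        assignments = xm.assign_classes(pts, spec)
        report = xm.density_report(assignments, spec, c.microns_per_pixel)
        cp, jp = self.out / "density.csv", self.out / "density.json"
        report.to_csv(cp)
        report.to_json(jp)
        self._record("density", {"density_csv": cp, "density_json": jp},
                     assigned=report.n_assigned,
                     unassigned=report.n_unassigned)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the artefact manifest."""
    return Pipeline(config).run()
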