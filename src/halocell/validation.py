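"""End-to-end synthetic recovery benchmark.

Runs the whole workflow against generated ground truth and reports how
well each stage recovers what the generator planted:

1. generate a training case (two stain-intensity strata: weak and
   strong rings) and build ~2,000 balanced, augmented bifocal pairs;
2. train the default bifocal CNN for a reduced number of epochs;
3. generate a held-out test case of four 512x512 tiles whose cells are
   placed by per-region densities over a three-band feature map;
4. slide the net over the test tiles (stride 10), merge detections,
   apply the per-case Otsu discriminability filter, measure retained
   cells and compile the per-region density report.

Reported metrics: held-out patch-pair AUC, fraction of planted cells
recovered within a 15 px radius, retention of strongly stained cells
versus rejection of weakly stained ones by the acceptance threshold T,
morphometry summaries, and the per-region cell-count proportions
against the planted density ratios.

The synthetic task is deliberately separable; the benchmark checks the
machinery end to end, not clinical-grade difficulty.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import annotations as ann
from . import bcnn as bc
from . import crossmodal as xm
from . import discriminability as disc
from . import heatmap as hm
from . import morphometry as mm
from . import synthetic as syn

# the two stain strata the generator plants: weak rings that should fail
# the discriminability filter, strong rings that should pass it
WEAK_RANGE = (0.05, 0.12)
STRONG_RANGE = (0.45, 0.70)
WEAK_CUTOFF = 0.20          # recorded intensity below this = weak stratum

# planted per-region density ratio across the three feature bands
REGION_CLASSES = ("normal brain", "viable tumour", "geographic necrosis")
REGION_DENSITY_RATIO = (3.0, 1.0, 2.0)


@dataclass
class BenchmarkResult:
    auc: float
    n_eval_pairs: int
    n_ground_truth: int
    n_detections: int
    recovery_rate: float           # fraction of planted cells found <= 15 px
    threshold_T: float
    n_retained: int
    strong_retention: float        # retained fraction among strong-stain hits
    weak_discard: float            # discarded fraction among weak-stain hits
    mean_compactness: float | None
    mean_area: float | None
    region_counts: dict[str, int] = field(default_factory=dict)
    region_expected_proportion: dict[str, float] = field(default_factory=dict)
    region_proportion_errors: dict[str, float] = field(default_factory=dict)
    region_proportion_tolerances: dict[str, float] = field(default_factory=dict)
    train_seconds: float = 0.0
    total_seconds: float = 0.0


def _training_pairs(seed: int, n_tiles: int = 10, n_cells: int = 25):
    tiles, marks = [], []
    for i in range(n_tiles):
        cfg = syn.SyntheticConfig(
            n_cells=n_cells, n_negatives=15, seed=(seed * 1000 + i) % 2**31,
            stain_intensity_strata=(WEAK_RANGE, STRONG_RANGE))
        tile, tile_marks = syn.generate_tile(cfg, case_id="train",
                                             tile_id=f"tile{i}")
        tiles.append(tile)
        marks.extend(tile_marks)
    # originals + 3 augmented variants per mark + 2 near-miss negatives per
    # positive -> ~2,000 roughly balanced pairs
    return ann.build_training_set(tiles, marks, augment=True, n_variants=3,
                                  hard_negative_per_positive=2,
                                  seed=seed + 17)


def _test_case(seed: int, n_tiles: int = 4, expected_cells: float = 100.0):
    cfg = syn.SyntheticConfig(
        n_cells=25, n_negatives=25, seed=(seed * 1000 + 555) % 2**31,
        stain_intensity_strata=(WEAK_RANGE, STRONG_RANGE))
    case_shape = (cfg.tile_height, n_tiles * cfg.tile_width)
    # densities scaled so the case plants ~expected_cells cells in total
    area_frac = np.array(REGION_DENSITY_RATIO) / np.sum(REGION_DENSITY_RATIO)
    total_mm2 = (case_shape[0] * case_shape[1]
                 * (cfg.microns_per_pixel / 1000.0) ** 2)
    base = expected_cells / total_mm2
    densities = {c: float(3 * base * f)
                 for c, f in zip(REGION_CLASSES, area_frac)}
    spec = syn.FeatureMapSpec.vertical_bands(
        REGION_CLASSES, case_shape, scale=10, densities=densities)
    case = syn.generate_case(cfg, spec, n_tiles=n_tiles, case_id="test")
    return cfg, case


def run_benchmark(seed: int = 1, epochs: int = 15,
                  decision_threshold: float = 0.5) -> BenchmarkResult:
    """Train, detect, filter, measure and report against ground truth."""
    t_start = time.time()
    pairs = _training_pairs(seed)
    cfg, case = _test_case(seed)
    ann.check_split_disjoint([p for p in case.marks],
                             [ann.MarkPoint("train", "t", 32, 32, "positive")])

    model_cfg = bc.BCNNConfig(epochs=epochs, seed=seed)
    model = bc.build_model(model_cfg)
    t0 = time.time()
    bc.train(model, pairs, model_cfg)
    train_seconds = time.time() - t0

    # held-out patch-pair evaluation on the test case's marks
    eval_pairs = ann.build_training_set(case.tiles, case.marks, seed=seed + 3)
    scores = bc.predict_pairs(model, eval_pairs)
    labels = np.array([1 if p.label == "positive" else 0 for p in eval_pairs])
    report = bc.evaluate(scores, labels, threshold=decision_threshold)

    # sliding-window detection over the four held-out tiles
    detections: list[hm.DetectionRecord] = []
    for tile in case.tiles:
        grid = hm.sliding_inference(model, tile, stride=10)
        detections.extend(hm.merge_detections(
            grid, threshold=decision_threshold, tile=tile))

    # match detections to planted cells (case frame, 15 px radius)
    origins = {t.tile_id: t.origin for t in case.tiles}
    gt = [(m, (m.x + origins[m.tile_id][0], m.y + origins[m.tile_id][1]))
          for m in case.marks if m.label == "positive"]
    det_xy = np.array([(d.centre[0] + origins[d.tile_id][0],
                        d.centre[1] + origins[d.tile_id][1])
                       for d in detections], dtype=float) \
        if detections else np.zeros((0, 2))
    matched_mark: list[ann.MarkPoint | None] = []
    recovered = 0
    for mark, (gx, gy) in gt:
        if len(det_xy) and np.min(np.hypot(det_xy[:, 0] - gx,
                                           det_xy[:, 1] - gy)) <= 15.0:
            recovered += 1
    for d, (dx, dy) in zip(detections, det_xy):
        best, best_dist = None, np.inf
        for mark, (gx, gy) in gt:
            dist = float(np.hypot(dx - gx, dy - gy))
            if dist < best_dist:
                best, best_dist = mark, dist
        matched_mark.append(best if best_dist <= 15.0 else None)

    # per-case discriminability filter
    disc.score_detections(detections)
    keep, drop, summary = disc.filter_case(detections)

    # per-cell verdict: a recovered cell is retained when any of its
    # matched detections passes the filter
    retained_by_mark: dict[int, bool] = {}
    for det, mark in zip(detections, matched_mark):
        if mark is None:
            continue
        key = id(mark)
        retained_by_mark[key] = retained_by_mark.get(key, False) \
            or bool(det.discriminable)

    def _retained_fraction(pred):
        verdicts = [retained_by_mark[id(m)] for m, _ in gt
                    if id(m) in retained_by_mark and pred(m)]
        return float(np.mean(verdicts)) if verdicts else float("nan")

    strong_retention = _retained_fraction(lambda m: m.intensity >= WEAK_CUTOFF)
    weak_retained = _retained_fraction(lambda m: m.intensity < WEAK_CUTOFF)
    weak_discard = float("nan") if np.isnan(weak_retained) else 1.0 - weak_retained

    # morphometry of the retained cells
    cells = []
    for rec in keep:
        patch = disc.preprocess(rec.crop, enhance=False)
        try:
            cells.append(mm.measure_patch(patch, rec.sigma))
        except mm.MorphometryError:
            continue
    area_mm2 = (len(case.tiles) * cfg.tile_width * cfg.tile_height
                * (cfg.microns_per_pixel / 1000.0) ** 2)
    features = mm.case_summary(cells, area_mm2)

    # per-region density report from the retained detections
    keep_xy = np.array([(d.centre[0] + origins[d.tile_id][0],
                         d.centre[1] + origins[d.tile_id][1])
                        for d in keep], dtype=float) if keep else np.zeros((0, 2))
    assignments = xm.assign_classes(keep_xy, case.feature_map)
    density = xm.density_report(assignments, case.feature_map,
                                cfg.microns_per_pixel)
    # planted expectation: counts proportional to density x area; bands
    # have equal areas, so proportions follow the density ratio
    areas = case.feature_map.class_area_mm2(cfg.microns_per_pixel)
    expected = {c: case.feature_map.densities[c] * areas[c]
                for c in REGION_CLASSES}
    total_expected = sum(expected.values())
    exp_prop = {c: expected[c] / total_expected for c in REGION_CLASSES}
    n_assigned = max(1, density.n_assigned)
    errors, tols = {}, {}
    for c in REGION_CLASSES:
        obs = density.counts.get(c, 0) / n_assigned
        errors[c] = abs(obs - exp_prop[c])
        tols[c] = 3.0 * np.sqrt(exp_prop[c] * (1 - exp_prop[c]) / n_assigned)

    return BenchmarkResult(
        auc=report.auc,
        n_eval_pairs=len(eval_pairs),
        n_ground_truth=len(gt),
        n_detections=len(detections),
        recovery_rate=recovered / len(gt) if gt else float("nan"),
        threshold_T=summary.T,
        n_retained=len(keep),
        strong_retention=strong_retention,
        weak_discard=weak_discard,
        mean_compactness=features.mean_compactness,
        mean_area=features.mean_area,
        region_counts=dict(density.counts),
        region_expected_proportion=exp_prop,
        region_proportion_errors=errors,
        region_proportion_tolerances=tols,
        train_seconds=train_seconds,
        total_seconds=time.time() - t_start,
    )
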