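"""Generator contracts: determinism, ground-truth fidelity, placement."""

import itertools

import numpy as np
import pytest

from halocell import synthetic as syn
from halocell.annotations import MarkPoint


class TestGenerateTile:
    def test_zero_cells_yields_no_positive_marks(self):
        cfg = syn.SyntheticConfig(n_cells=0, n_negatives=3, seed=1)
        _, marks = syn.generate_tile(cfg)
        assert [m for m in marks if m.label == "positive"] == []

    def test_same_seed_bit_identical(self, small_config):
        tile_a, marks_a = syn.generate_tile(small_config)
        tile_b, marks_b = syn.generate_tile(small_config)
        assert np.array_equal(tile_a.pixels, tile_b.pixels)
        assert marks_a == marks_b

    def test_different_seeds_differ(self, small_config):
        tile_a, _ = syn.generate_tile(small_config)
        other = syn.SyntheticConfig(tile_width=256, tile_height=256, n_cells=6,
                                    n_negatives=6, seed=43)
        tile_b, _ = syn.generate_tile(other)
        assert not np.array_equal(tile_a.pixels, tile_b.pixels)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_recorded_intensity_matches_rendered_ring(self, seed):
        cfg = syn.SyntheticConfig(n_cells=50, seed=seed, tile_width=1024,
                                  tile_height=1024,
                                  stain_intensity_range=(0.6, 0.75))
        tile, marks = syn.generate_tile(cfg)
        positives = [m for m in marks if m.label == "positive"]
        assert len(positives) == 50
        for m in positives:
            assert 0.6 <= m.intensity <= 0.75
            measured = syn.measured_ring_intensity(tile, m, cfg)
            assert measured == pytest.approx(m.intensity, abs=0.05)

    def test_centres_respect_margin_and_separation(self, small_tile, small_config):
        _, marks = small_tile
        pos = [m for m in marks if m.label == "positive"]
        for m in pos:
            assert 32 <= m.x <= small_config.tile_width - 32
            assert 32 <= m.y <= small_config.tile_height - 32
        for a, b in itertools.combinations(pos, 2):
            assert np.hypot(a.x - b.x, a.y - b.y) >= small_config.min_separation

    def test_negatives_clear_of_positives(self, small_tile):
        _, marks = small_tile
        pos = [m for m in marks if m.label == "positive"]
        neg = [m for m in marks if m.label == "negative"]
        assert neg
        for n in neg:
            for p in pos:
                assert np.hypot(n.x - p.x, n.y - p.y) >= syn.NEGATIVE_CLEARANCE

    def test_infeasible_packing_raises(self):
        cfg = syn.SyntheticConfig(tile_width=128, tile_height=128, n_cells=60,
                                  seed=0)
        with pytest.raises(syn.PackingError, match="separation"):
            syn.generate_tile(cfg)

    def test_intensity_outside_renderable_range_rejected(self):
        with pytest.raises(ValueError, match="renderable"):
            syn.SyntheticConfig(stain_intensity_range=(0.5, 0.9))

    def test_tile_too_small_rejected(self):
        with pytest.raises(ValueError, match="128"):
            syn.SyntheticConfig(tile_width=64)


class TestGenerateCase:
    def test_marks_add_up_across_tiles(self):
        cfg = syn.SyntheticConfig(n_cells=10, n_negatives=2, seed=5)
        case = syn.generate_case(cfg, n_tiles=4)
        positives = [m for m in case.marks if m.label == "positive"]
        assert len(positives) == 40
        assert {m.tile_id for m in case.marks} == {f"tile{i}" for i in range(4)}
        assert {m.case_id for m in case.marks} == {"case0"}

    def test_n_tiles_below_one_rejected(self):
        cfg = syn.SyntheticConfig(seed=0)
        with pytest.raises(ValueError):
            syn.generate_case(cfg, n_tiles=0)

    def test_density_ratio_recovered_under_poisson_sampling(self):
        # two equal-area classes at 3:1 planted density; with >= 200
        # expected cells the observed count ratio sits within 3 sigma
        cfg = syn.SyntheticConfig(tile_width=512, tile_height=512,
                                  cell_radius_range=(3.0, 5.0),
                                  halo_ring_width=2.0, n_negatives=0,
                                  nuclei_density=20, seed=11)
        case_shape = (512, 2 * 512)
        area_mm2 = case_shape[0] * case_shape[1] * (0.25 / 1000.0) ** 2 / 2
        d = 120.0 / area_mm2   # expect 240 + 80 cells
        spec = syn.FeatureMapSpec.vertical_bands(
            ("viable tumour", "normal brain"), case_shape, scale=10,
            densities={"viable tumour": 3 * d / 2, "normal brain": d / 2})
        case = syn.generate_case(cfg, spec, n_tiles=2)
        pos = [(m.x + (int(m.tile_id[4:]) * 512), m.y)
               for m in case.marks if m.label == "positive"]
        n_a = sum(1 for x, _ in pos if x < 512)
        n_b = len(pos) - n_a
        assert n_a + n_b >= 200
        ratio = n_a / n_b
        sd = 3.0 * np.sqrt(1 / 180 + 1 / 60)   # delta-method sd of the ratio
        assert abs(ratio - 3.0) <= 3.0 * sd

    def test_single_class_raster_covers_all_cells(self):
        cfg = syn.SyntheticConfig(n_cells=5, seed=2)
        spec = syn.FeatureMapSpec.vertical_bands(
            ("viable tumour",), (512, 1024), scale=10,
            densities={"viable tumour": 3000.0})
        case = syn.generate_case(cfg, spec, n_tiles=2)
        assert np.all(case.feature_map.labels == 0)


class TestFeatureMapSpec:
    def test_palette_must_be_injective(self):
        with pytest.raises(ValueError, match="injective"):
            syn.FeatureMapSpec(
                labels=np.zeros((4, 4), int), class_names=("a", "b"),
                palette={"a": (1, 2, 3), "b": (1, 2, 3)})

    def test_render_roundtrips_through_palette(self):
        spec = syn.FeatureMapSpec.vertical_bands(
            ("normal brain", "viable tumour"), (40, 80), scale=10)
        img = spec.render()
        for i, name in enumerate(spec.class_names):
            assert np.all(img[spec.labels == i] == spec.palette[name])

    def test_io_roundtrip(self, tmp_path):
        spec = syn.FeatureMapSpec.vertical_bands(
            ("normal brain", "viable tumour"), (40, 80), scale=10,
            densities={"normal brain": 1.0, "viable tumour": 2.0})
        syn.write_feature_map(spec, tmp_path / "fm.png", tmp_path / "fm.json")
        back = syn.read_feature_map(tmp_path / "fm.png", tmp_path / "fm.json")
        assert np.array_equal(back.labels, spec.labels)
        assert back.class_names == spec.class_names
        assert back.palette == spec.palette
        assert back.densities == spec.densities


class TestTileIO:
    @pytest.mark.parametrize("ext", ["png", "tiff"])
    def test_write_read_roundtrip(self, tmp_path, ext, small_tile):
        tile, _ = small_tile
        path = tmp_path / f"tile.{ext}"
        syn.write_tile(tile, path)
        back = syn.read_tile(path, case_id=tile.case_id, tile_id=tile.tile_id)
        # 8-bit quantisation is the only loss
        assert np.abs(back.pixels - tile.pixels).max() <= 1 / 255.0 + 1e-9
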