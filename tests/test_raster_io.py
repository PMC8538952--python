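import numpy as np
import pytest

from lodgeseg.raster_io import (
    LabelMask,
    Raster,
    TilePair,
    load_mask,
    load_raster,
    tile_pairs,
    write_mask,
    write_raster,
)


class TestRasterType:
    def test_band_count_must_match_names(self, rng):
        with pytest.raises(ValueError, match="channel names"):
            Raster(rng.random((4, 4, 3)), ("R", "G", "B", "DSM"))

    def test_channel_lookup(self, rgb_raster):
        assert np.array_equal(rgb_raster.channel("G"), rgb_raster.pixels[:, :, 1])
        with pytest.raises(KeyError):
            rgb_raster.channel("DSM")

    def test_mask_rejects_out_of_range_labels(self):
        with pytest.raises(ValueError, match="0,1,2"):
            LabelMask(np.full((4, 4), 3))

    def test_pair_rejects_mismatched_dims(self, rng):
        with pytest.raises(ValueError, match="dimensions"):
            TilePair(Raster(rng.random((4, 4, 3)), ("R", "G", "B")), LabelMask(np.zeros((5, 5), int)))


class TestLoadScaling:
    @pytest.mark.parametrize("dn,expected", [(255, 1.0), (0, 0.0), (51, 0.2)])
    def test_png_8bit_scaled_to_unit(self, tmp_path, dn, expected):
        from PIL import Image

        arr = np.full((4, 4, 3), dn, dtype=np.uint8)
        Image.fromarray(arr).save(tmp_path / "t.png")
        r = load_raster(tmp_path / "t.png", ("R", "G", "B"))
        assert r.pixels == pytest.approx(np.full((4, 4, 3), expected))

    def test_band_count_mismatch_is_an_error(self, tmp_path):
        from PIL import Image

        Image.fromarray(np.zeros((4, 4, 3), dtype=np.uint8)).save(tmp_path / "t.png")
        with pytest.raises(ValueError, match="bands"):
            load_raster(tmp_path / "t.png", ("R", "G", "B", "DSM"))

    def test_dsm_float_tiff_passthrough_with_geotransform(self, tmp_path):
        dsm = np.linspace(98.0, 103.0, 64).reshape(8, 8, 1)
        gt = (500000.0, 0.05, 0.0, 4100000.0, 0.0, -0.05)
        write_raster(Raster(dsm, ("DSM",), geotransform=gt), tmp_path / "d.tif")
        back = load_raster(tmp_path / "d.tif", ("DSM",))
        assert back.pixels[:, :, 0] == pytest.approx(dsm[:, :, 0], abs=1e-4)
        assert back.geotransform == pytest.approx(gt)

    def test_load_is_affine_monotone_on_8bit(self, tmp_path):
        from PIL import Image

        dns = np.arange(0, 256, dtype=np.uint8).reshape(16, 16)
        Image.fromarray(np.stack([dns] * 3, axis=-1)).save(tmp_path / "g.png")
        vals = load_raster(tmp_path / "g.png", ("R", "G", "B")).pixels[:, :, 0].ravel()
        assert np.all(np.diff(vals) > 0)
        assert vals == pytest.approx(np.arange(256) / 255.0)


class TestTiling:
    def test_4000x3000_yields_165_full_tiles(self, rng):
        # floor(4000/256) * floor(3000/256) = 15 * 11
        r = Raster(np.zeros((3000, 4000, 1)), ("DSM",))
        m = LabelMask(np.zeros((3000, 4000), int))
        assert len(tile_pairs(r, m, 256)) == 165

    @pytest.mark.parametrize("size,expected", [(256, 1), (255, 0)])
    def test_edge_cases(self, size, expected):
        r = Raster(np.zeros((size, size, 1)), ("DSM",))
        m = LabelMask(np.zeros((size, size), int))
        assert len(tile_pairs(r, m, 256)) == expected

    def test_single_tile_is_identity(self, rng):
        pix = rng.random((64, 64, 3))
        lab = rng.integers(0, 3, (64, 64))
        (pair,) = tile_pairs(Raster(pix, ("R", "G", "B")), LabelMask(lab), 64)
        assert np.array_equal(pair.image.pixels, pix)
        assert np.array_equal(pair.mask.labels, lab)

    def test_tiles_are_disjoint_and_conserve_pixels(self, rng):
        h, w, t = 130, 200, 64
        lab = rng.integers(0, 3, (h, w))
        pairs = tile_pairs(Raster(rng.random((h, w, 3)), ("R", "G", "B")), LabelMask(lab), t)
        n = (h // t) * (w // t)
        assert len(pairs) == n
        assert n * t * t <= h * w
        # row-major order: reassemble and compare against the source window
        grid = np.zeros((h // t * t, w // t * t), dtype=int)
        for k, p in enumerate(pairs):
            i, j = divmod(k, w // t)
            grid[i * t : (i + 1) * t, j * t : (j + 1) * t] = p.mask.labels
        assert np.array_equal(grid, lab[: h // t * t, : w // t * t])

    def test_pad_reflect_covers_everything(self, rng):
        r = Raster(rng.random((70, 70, 3)), ("R", "G", "B"))
        m = LabelMask(rng.integers(0, 3, (70, 70)))
        assert len(tile_pairs(r, m, 64, policy="pad_reflect")) == 4

    def test_mismatched_dims_rejected(self):
        r = Raster(np.zeros((64, 64, 1)), ("DSM",))
        m = LabelMask(np.zeros((64, 65), int))
        with pytest.raises(ValueError, match="differ"):
            tile_pairs(r, m, 64)


class TestMaskRoundTrip:
    def test_round_trip_identity(self, tmp_path, rng):
        lab = rng.integers(0, 3, (32, 32))
        write_mask(LabelMask(lab), tmp_path / "m.png")
        assert np.array_equal(load_mask(tmp_path / "m.png").labels, lab)

    def test_all_background_is_single_color(self, tmp_path):
        write_mask(LabelMask(np.zeros((8, 8), int)), tmp_path / "m.png")
        from PIL import Image

        with Image.open(tmp_path / "m.png") as im:
            assert len(im.convert("RGB").getcolors()) == 1

    def test_missing_palette_entry_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="palette"):
            write_mask(LabelMask(np.zeros((4, 4), int)), tmp_path / "m.png", palette={0: (0, 0, 0)})
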