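"""I/O round-trips, augmentation family, patching, and dataset splits."""

import numpy as np
import pytest

from tear.dataio import (ImageRecord, NoisyCleanPair, augment,
                         extract_patches, load_manifest, read_image,
                         read_rois, reassemble_patches, resize, split_dataset,
                         write_image, write_manifest, write_rois)
from tear.metrics import ROI, ROIPair
from tear.phantom import generate_pairs


def make_pair(rng, h=64, w=64):
    noisy = rng.random((h, w))
    clean = rng.random((h, w))
    rois = ROIPair(signal=ROI(40, 20, 8, 8), background=ROI(4, 20, 8, 8))
    return NoisyCleanPair(noisy=ImageRecord("n", noisy),
                          clean=ImageRecord("c", clean), rois=rois)


class TestResize:
    def test_constant_image_stays_constant(self):
        rec = ImageRecord("x", np.full((20, 30), 0.5))
        out = resize(rec, 37, 11)
        assert out.shape == (37, 11)
        assert np.allclose(out.pixels, 0.5)

    def test_identity_resize(self):
        rng = np.random.default_rng(0)
        rec = ImageRecord("x", rng.random((16, 16)))
        out = resize(rec, 16, 16)
        assert np.allclose(out.pixels, rec.pixels, atol=1e-6)

    def test_round_trip_through_upsample(self):
        checker = np.array([[0.0, 1.0], [1.0, 0.0]])
        up = resize(ImageRecord("x", checker), 4, 4).pixels
        # area-mean back to 2x2 (independent downsample oracle)
        back = up.reshape(2, 2, 2, 2).mean(axis=(1, 3))
        assert np.abs(back - checker).max() <= 0.25

    def test_rejects_tiny_targets(self):
        with pytest.raises(ValueError):
            resize(ImageRecord("x", np.zeros((16, 16))), 1, 16)


class TestAugment:
    def test_exactly_seven_outputs(self):
        out = augment(make_pair(np.random.default_rng(1)))
        assert len(out) == 7

    def test_rot180_is_involution(self):
        pair = make_pair(np.random.default_rng(2))
        out = augment(pair)
        r180 = next(p for p in out if p.noisy.id.endswith("rot180"))
        again = augment(r180)
        back = next(p for p in again if p.noisy.id.endswith("rot180"))
        assert np.array_equal(back.noisy.pixels, pair.noisy.pixels)

    @pytest.mark.parametrize("name", ["rot90", "rot180", "rot270",
                                      "hflip", "vflip"])
    def test_roi_transport_matches_mask_transport(self, name):
        """Oracle: transform a mask with the ROI set, re-locate the set bits,
        and compare with the transported box."""
        pair = make_pair(np.random.default_rng(3), h=48, w=64)
        out = {p.noisy.id.rsplit("_", 1)[1]: p for p in augment(pair)}
        transformed = out[name]
        for which in ("signal", "background"):
            roi = getattr(pair.rois, which)
            mask = np.zeros((48, 64))
            mask[roi.slices()] = 1.0
            masked_pair = NoisyCleanPair(
                noisy=ImageRecord("m", mask), clean=ImageRecord("m2", mask),
                rois=pair.rois)
            tmask = {p.noisy.id.rsplit("_", 1)[1]: p
                     for p in augment(masked_pair)}[name].noisy.pixels
            got = getattr(transformed.rois, which)
            rows, cols = np.nonzero(tmask)
            assert got.row == rows.min() and got.col == cols.min()
            assert got.height == rows.max() - rows.min() + 1
            assert got.width == cols.max() - cols.min() + 1

    def test_isometries_preserve_histogram(self):
        pair = make_pair(np.random.default_rng(4))
        ref = np.sort(pair.noisy.pixels.ravel())
        for p in augment(pair):
            if p.noisy.id.endswith("zoom"):
                continue
            assert np.array_equal(np.sort(p.noisy.pixels.ravel()), ref)

    def test_zoom_keeps_shape_and_may_drop_rois(self):
        pair = make_pair(np.random.default_rng(5))
        zoomed = next(p for p in augment(pair) if p.noisy.id.endswith("zoom"))
        assert zoomed.noisy.shape == pair.noisy.shape
        # near-border ROI must be dropped, not crash
        edge = NoisyCleanPair(
            noisy=pair.noisy, clean=pair.clean,
            rois=ROIPair(signal=ROI(56, 56, 8, 8), background=ROI(0, 0, 8, 8)))
        zedge = next(p for p in augment(edge) if p.noisy.id.endswith("zoom"))
        assert zedge.rois is None


class TestPatches:
    def test_patch_count_64(self):
        grid = extract_patches(np.zeros((64, 64)), patch=32)
        assert grid.n_patches == 4 and grid.grid_shape == (2, 2)

    def test_round_trip(self):
        rng = np.random.default_rng(6)
        img = rng.random((96, 64))
        grid = extract_patches(img, patch=32)
        assert np.array_equal(reassemble_patches(grid), img)

    def test_non_divisible_image_edge_padded(self):
        img = np.random.default_rng(7).random((65, 64))
        grid = extract_patches(img, patch=32)
        assert grid.grid_shape == (3, 2) and grid.n_patches == 6
        assert grid.pad == (31, 0)
        assert np.array_equal(reassemble_patches(grid), img)
        padded = reassemble_patches(grid, unpad=False)
        assert np.array_equal(padded[64:, :], np.tile(img[64, :], (32, 1)))

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((16, 16)), patch=32)


class TestSplit:
    def test_ratio_arithmetic(self):
        pairs10 = generate_pairs(10, seed=0)
        s = split_dataset(pairs10, seed=1)
        assert (len(s.train), len(s.val), len(s.test)) == (6, 1, 3)
        pairs16 = generate_pairs(16, seed=0)
        s16 = split_dataset(pairs16, seed=1)
        assert (len(s16.train), len(s16.val), len(s16.test)) == (9, 1, 6)

    def test_partition_is_exact(self):
        pairs = generate_pairs(13, seed=2)
        s = split_dataset(pairs, seed=3)
        ids = [p.clean.id for p in s.train + s.val + s.test]
        assert sorted(ids) == sorted(p.clean.id for p in pairs)

    def test_seed_determinism_and_variation(self):
        pairs = generate_pairs(12, seed=4)
        a = split_dataset(pairs, seed=5)
        b = split_dataset(pairs, seed=5)
        assert [p.clean.id for p in a.train] == [p.clean.id for p in b.train]
        memberships = {tuple(p.clean.id for p in
                             split_dataset(pairs, seed=s).train)
                       for s in range(20)}
        assert len(memberships) > 1

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(generate_pairs(5, seed=0), ratios=(0.5, 0.2, 0.2))


class TestFileRoundTrips:
    @pytest.mark.parametrize("suffix,bits,tol", [
        (".png", 16, 1 / 65535), (".png", 8, 1 / 255),
        (".tif", 16, 1 / 65535),
    ])
    def test_image_round_trip(self, tmp_path, suffix, bits, tol):
        rng = np.random.default_rng(8)
        img = rng.random((32, 24))
        path = tmp_path / f"img{suffix}"
        write_image(img, path, bit_depth=bits)
        back = read_image(path)
        assert back.shape == img.shape
        assert np.abs(back.pixels - img).max() <= tol

    def test_roi_json_round_trip(self, tmp_path):
        rois = ROIPair(signal=ROI(10, 4, 6, 6), background=ROI(0, 4, 6, 6))
        write_rois(rois, tmp_path / "r.json")
        assert read_rois(tmp_path / "r.json") == rois

    def test_manifest_round_trip(self, tmp_path):
        pairs = generate_pairs(6, seed=9)
        split = split_dataset(pairs, seed=9)
        write_manifest(split, tmp_path / "data", tmp_path / "manifest.csv")
        back = load_manifest(tmp_path / "manifest.csv")
        assert (len(back.train), len(back.val), len(back.test)) == \
            (len(split.train), len(split.val), len(split.test))
        a = split.train[0]
        b = next(p for p in back.train
                 if p.clean.id.startswith(a.clean.id.rsplit("_", 1)[0]))
        assert np.abs(a.clean.pixels - b.clean.pixels).max() <= 1 / 65535
        assert b.rois == a.rois


def test_image_record_validation():
    with pytest.raises(ValueError):
        ImageRecord("bad", np.full((4, 4), 1.5))
    with pytest.raises(ValueError):
        ImageRecord("bad", np.zeros((4, 4, 3)))
    with pytest.raises(ValueError):
        NoisyCleanPair(noisy=ImageRecord("a", np.zeros((4, 4))),
                       clean=ImageRecord("b", np.zeros((5, 4))))
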