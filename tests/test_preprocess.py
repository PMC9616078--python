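"""Tissue masking, stain normalization, tiling and augmentation."""

import numpy as np
import pytest

from gastrograph.preprocess import (AugmentConfig, ChannelStats, Patch, augment,
                                    compute_channel_stats, extract_tissue_mask,
                                    normalize_stain, reassemble_patches, tile_slide)
from gastrograph.synthetic import SlideSpec, generate_slide


@pytest.fixture(scope="module")
def lgd_slide():
    return generate_slide(SlideSpec("LGD", width=256, height=256, lesion_count=2,
                                    lesion_area_fraction=0.2, seed=21))


class TestTissueMask:
    def test_recovers_synthetic_tissue(self, lgd_slide):
        img, mask = lgd_slide
        tm = extract_tissue_mask(img)
        gt = mask >= 1
        iou = (tm.mask & gt).sum() / (tm.mask | gt).sum()
        assert iou >= 0.95

    def test_all_white_image_gives_empty_mask(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.warns(UserWarning, match="degenerate"):
            tm = extract_tissue_mask(img)
        assert tm.tissue_fraction == 0.0

    def test_all_tissue_image(self, rng):
        img = np.clip(rng.normal([225, 160, 200], 6, size=(128, 128, 3)),
                      0, 255).astype(np.uint8)
        tm = extract_tissue_mask(img)
        assert tm.tissue_fraction >= 0.99


class TestChannelStats:
    def test_uniform_gray_tissue(self):
        img = np.full((32, 32, 3), 128, dtype=np.uint8)
        mask = np.ones((32, 32), dtype=bool)
        stats = compute_channel_stats(img, mask, role="source")
        assert stats.mean == (128.0, 128.0, 128.0)
        assert stats.std == (0.0, 0.0, 0.0)

    def test_target_is_mean_of_slide_means(self):
        a = np.full((16, 16, 3), 100, dtype=np.uint8)
        b = np.full((16, 16, 3), 140, dtype=np.uint8)
        mask = np.ones((16, 16), dtype=bool)
        stats = compute_channel_stats([a, b], [mask, mask], role="target")
        assert stats.mean == (120.0, 120.0, 120.0)

    def test_matches_per_pixel_recomputation(self, rng):
        img = rng.integers(0, 255, size=(40, 40, 3)).astype(np.uint8)
        mask = rng.random((40, 40)) > 0.4
        stats = compute_channel_stats(img, mask, role="source")
        for c in range(3):
            vals = [float(img[y, x, c]) for y in range(40) for x in range(40) if mask[y, x]]
            assert stats.mean[c] == pytest.approx(np.mean(vals))
            assert stats.std[c] == pytest.approx(np.std(vals))

    def test_no_tissue_anywhere_raises(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            compute_channel_stats(img, np.zeros((8, 8), bool), role="source")


class TestNormalizeStain:
    def test_identity_when_source_equals_target(self, lgd_slide):
        img, _ = lgd_slide
        tm = extract_tissue_mask(img)
        stats = compute_channel_stats(img, tm.mask, role="target")
        out = normalize_stain(img, tm, stats)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1  # rounding only

    def test_closed_form_value(self):
        # source (mu=100, sigma=10), target (mu=120, sigma=20): X=110 -> Z=140
        src = ChannelStats((100.0,) * 3, (10.0,) * 3, "source")
        tgt = ChannelStats((120.0,) * 3, (20.0,) * 3, "target")
        img = np.full((4, 4, 3), 110, dtype=np.uint8)
        out = normalize_stain(img, None, tgt, source=src)
        assert np.all(out == 140)

    def test_linearity_per_channel_before_clipping(self):
        src = ChannelStats((50.0,) * 3, (5.0,) * 3, "source")
        tgt = ChannelStats((100.0,) * 3, (10.0,) * 3, "target")
        x = np.arange(40, 61).astype(np.uint8)
        img = np.stack([np.tile(x[:, None], (1, 3))], axis=0).reshape(1, -1, 3)
        out = normalize_stain(img, None, tgt, source=src).astype(float)
        # Z = (X-50)/5*10+100 = 2X: exact linearity on this range
        assert np.array_equal(out, 2.0 * img.astype(float))

    def test_tissue_stats_reach_target_within_one_gray_level(self, lgd_slide):
        img, _ = lgd_slide
        tm = extract_tissue_mask(img)
        tgt = ChannelStats((180.0, 150.0, 170.0), (20.0, 18.0, 15.0), "target")
        out = normalize_stain(img, tm, tgt)
        got = compute_channel_stats(out, tm.mask, role="source")
        assert np.abs(np.array(got.mean) - np.array(tgt.mean)).max() <= 1.0
        assert np.abs(np.array(got.std) - np.array(tgt.std)).max() <= 1.0

    def test_degenerate_source_raises(self):
        src = ChannelStats((100.0,) * 3, (0.0,) * 3, "source")
        tgt = ChannelStats((120.0,) * 3, (20.0,) * 3, "target")
        with pytest.raises(ValueError, match="degenerate"):
            normalize_stain(np.zeros((4, 4, 3), np.uint8), None, tgt, source=src)

    def test_between_center_gap_shrinks(self):
        from gastrograph.synthetic import CenterStyle, generate_cohort
        styles = {"A": CenterStyle(gain=(1.15, 1.0, 0.9)), "B": CenterStyle()}
        slides = generate_cohort({c: {"NED": 2} for c in styles}, styles,
                                 seed=8, width=256, height=256)
        masks = [extract_tissue_mask(s.image) for s in slides]
        tgt = compute_channel_stats([s.image for s in slides],
                                    [m.mask for m in masks], role="target")
        means = {"A": [], "B": []}
        for s, m in zip(slides, masks):
            out = normalize_stain(s.image, m, tgt)
            means[s.center].append(out[m.mask].astype(float).mean(axis=0))
        gap = np.abs(np.mean(means["A"], axis=0) - np.mean(means["B"], axis=0))
        assert gap.max() < 2.0


class TestTileSlide:
    def test_exact_grid(self, rng):
        img = rng.integers(0, 255, size=(256, 256, 3)).astype(np.uint8)
        patches = tile_slide(img, np.ones((256, 256), bool), 128, 0.0)
        assert len(patches) == 4
        assert [(p.row, p.col) for p in patches] == [(0, 0), (0, 1), (1, 0), (1, 1)]
        assert all(p.x0 % 128 == 0 and p.y0 % 128 == 0 for p in patches)

    def test_remainders_are_padded_white(self, rng):
        img = rng.integers(0, 255, size=(250, 250, 3)).astype(np.uint8)
        patches = tile_slide(img, np.ones((250, 250), bool), 128, 0.0)
        assert len(patches) == 4
        edge = patches[-1].image
        assert np.all(edge[-6:, :, :] == 255) and np.all(edge[:, -6:, :] == 255)

    def test_patch_larger_than_slide_gives_single_padded_patch(self, rng):
        img = rng.integers(0, 255, size=(50, 40, 3)).astype(np.uint8)
        patches = tile_slide(img, np.ones((50, 40), bool), 64, 0.0)
        assert len(patches) == 1 and patches[0].image.shape == (64, 64, 3)

    def test_low_tissue_patches_dropped(self):
        img = np.full((256, 256, 3), 255, dtype=np.uint8)
        tissue = np.zeros((256, 256), dtype=bool)
        tissue[:128, :128] = True  # one quadrant
        img[tissue] = 180
        patches = tile_slide(img, tissue, 128, 0.05)
        assert [(p.row, p.col) for p in patches] == [(0, 0)]

    def test_reassembly_is_identity_on_padded_canvas(self, rng):
        img = rng.integers(0, 255, size=(200, 310, 3)).astype(np.uint8)
        patches = tile_slide(img, np.ones((200, 310), bool), 64, 0.0)
        canvas = reassemble_patches(patches, (256, 320))
        assert np.array_equal(canvas[:200, :310], img)
        assert np.all(canvas[200:, :] == 255) and np.all(canvas[:, 310:] == 255)


class TestAugment:
    def _patch(self, rng) -> Patch:
        img = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        mask = rng.integers(0, 5, size=(64, 64)).astype(np.uint8)
        return Patch("s", 0, 0, 0, 0, img, 1.0, mask=mask)

    def test_disabled_transforms_are_identity(self, rng):
        pt = self._patch(rng)
        out = augment(pt, AugmentConfig())
        assert np.array_equal(out.image, pt.image)
        assert np.array_equal(out.mask, pt.mask)

    def test_horizontal_flip_is_involution(self, rng):
        pt = self._patch(rng)
        cfg = AugmentConfig(hflip_prob=1.0)
        out = augment(augment(pt, cfg), cfg)
        assert np.array_equal(out.image, pt.image)
        assert np.array_equal(out.mask, pt.mask)

    def test_mask_follows_spatial_transform(self, rng):
        pt = self._patch(rng)
        out = augment(pt, AugmentConfig(hflip_prob=1.0))
        assert np.array_equal(out.image, pt.image[:, ::-1])
        assert np.array_equal(out.mask, pt.mask[:, ::-1])

    def test_random_erasing_fraction_in_band(self, rng):
        pt = self._patch(rng)
        out = augment(pt, AugmentConfig(erase_prob=1.0, erase_area=(0.1, 0.2), seed=3))
        frac = (out.mask == 0).mean() - (pt.mask == 0).mean()
        changed = (out.image != pt.image).any(axis=2).mean()
        assert 0.08 <= changed <= 0.22
        assert frac >= 0.0

    def test_seeded_reproducibility(self, rng):
        pt = self._patch(rng)
        cfg = AugmentConfig(hflip_prob=0.5, vflip_prob=0.5, rot90=True,
                            erase_prob=0.5, brightness=0.2, saturation=0.2,
                            contrast=0.2, seed=77)
        a = augment(pt, cfg)
        b = augment(pt, cfg)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
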