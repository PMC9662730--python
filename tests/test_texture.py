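import numpy as np
import pytest

from conftest import random_images
from reference_textures import (ref_ccentrist, ref_census, ref_clbp, ref_ltp,
                                ref_riu2, ref_tcentrist)
from spectrotex.errors import ValidationError
from spectrotex.spectrogram import SpectrogramImage
from spectrotex.texture import (RIU2_TABLE, ccentrist_descriptor,
                                census_transform, centrist_descriptor,
                                clbp_codes, descriptor_length,
                                extract_descriptor, ltp_codes, pyramid_blocks,
                                tcentrist_descriptor)


class TestCensusTransform:
    def test_constant_image_codes_255(self):
        cm = census_transform(np.full((5, 5), 7, dtype=np.uint8))
        assert np.all(cm.codes == 255)

    def test_center_below_all_neighbors_codes_0(self):
        img = np.full((3, 3), 10)
        img[1, 1] = 1
        assert census_transform(img).codes[0, 0] == 0

    def test_matches_reference_loop(self, rng):
        for img in random_images(rng, 25, (8, 8)):
            np.testing.assert_array_equal(census_transform(img).codes,
                                          ref_census(img))

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError):
            census_transform(np.zeros((2, 5)))


class TestRiu2Mapping:
    def test_known_codes(self):
        assert RIU2_TABLE[0] == 0
        assert RIU2_TABLE[255] == 8
        assert RIU2_TABLE[0b01010101] == 9  # alternating: 8 transitions
        assert RIU2_TABLE[0b00000111] == 3  # one run of 3: uniform

    def test_matches_reference_for_all_codes(self):
        np.testing.assert_array_equal(RIU2_TABLE,
                                      [ref_riu2(c) for c in range(256)])


class TestClbp:
    def test_constant_image(self):
        s, m, c = clbp_codes(np.full((6, 6), 42, dtype=np.uint8))
        assert np.all(s.codes == 8)  # raw 255 -> riu2 8
        assert np.all(m.codes == 8)  # m_p = 0 >= c = 0 everywhere
        assert np.all(c.codes == 1)  # g_c >= image mean

    @pytest.mark.parametrize("riu2", [True, False])
    def test_matches_reference_loop(self, rng, riu2):
        for img in random_images(rng, 15, (8, 8)):
            s, m, c = clbp_codes(img, riu2=riu2)
            rs, rm, rc = ref_clbp(img, riu2=riu2)
            np.testing.assert_array_equal(s.codes, rs)
            np.testing.assert_array_equal(m.codes, rm)
            np.testing.assert_array_equal(c.codes, rc)

    def test_gray_offset_invariance(self, rng):
        # difference-based codes ignore a constant gray offset; the center
        # code is invariant too because the mean shifts with g_c
        img = rng.integers(0, 200, (10, 10)).astype(np.float64)
        a = clbp_codes(img)
        b = clbp_codes(img + 50)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.codes, y.codes)

    def test_gray_mean_threshold_mode(self, rng):
        img = rng.integers(0, 256, (8, 8))
        _, m, _ = clbp_codes(img, m_threshold="gray_mean")
        # magnitudes rarely exceed the gray mean, so codes skew low
        assert m.codes.max() <= 9


class TestLtp:
    def test_constant_image_all_zero_codes(self):
        up, lo = ltp_codes(np.full((5, 5), 9, dtype=np.uint8))
        assert np.all(up.codes == 0) and np.all(lo.codes == 0)

    def test_boundary_mu_inclusive(self):
        img = np.zeros((3, 3))
        img[0, 0] = 5.0  # top-left neighbor exceeds center by exactly mu
        up, lo = ltp_codes(img, mu=5.0)
        assert up.codes[0, 0] == 0b10000000  # first offset -> MSB
        assert lo.codes[0, 0] == 0

    def test_matches_reference_loop(self, rng):
        for img in random_images(rng, 25, (8, 8)):
            up, lo = ltp_codes(img, mu=5.0)
            ru, rl = ref_ltp(img, mu=5.0)
            np.testing.assert_array_equal(up.codes, ru)
            np.testing.assert_array_equal(lo.codes, rl)

    def test_gray_offset_invariance(self, rng):
        img = rng.integers(0, 200, (10, 10)).astype(np.float64)
        a = ltp_codes(img)
        b = ltp_codes(img + 31)
        np.testing.assert_array_equal(a[0].codes, b[0].codes)
        np.testing.assert_array_equal(a[1].codes, b[1].codes)

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(ValidationError):
            ltp_codes(np.zeros((5, 5)), mu=0.0)


class TestPyramid:
    def test_level0_is_full_image(self):
        layout = pyramid_blocks(50, 70, levels=[0])
        assert layout.n_blocks == 1
        b = layout.blocks[0]
        assert (b.r0, b.r1, b.c0, b.c1) == (0, 50, 0, 70)

    def test_default_21_blocks_on_128(self):
        layout = pyramid_blocks(128, 128)
        assert layout.n_blocks == 21
        lv2 = [b for b in layout.blocks if b.level == 2]
        assert len(lv2) == 16
        assert all(b.r1 - b.r0 == 32 and b.c1 - b.c0 == 32 for b in lv2)

    def test_odd_size_coverage_and_disjointness(self):
        layout = pyramid_blocks(65, 65, levels=[1])
        sizes = sorted({(b.r1 - b.r0) for b in layout.blocks})
        assert sizes == [32, 33]
        cover = np.zeros((65, 65), dtype=int)
        for b in layout.blocks:
            cover[b.r0:b.r1, b.c0:b.c1] += 1
        assert np.all(cover == 1)

    def test_too_small_for_level_rejected(self):
        with pytest.raises(ValidationError):
            pyramid_blocks(3, 3, levels=[2])


class TestDescriptors:
    def test_ccentrist_default_length(self):
        layout = pyramid_blocks(128, 128)
        assert descriptor_length("ccentrist", layout) == 21 * 200 == 4200
        img = np.random.default_rng(0).integers(0, 256, (128, 128))
        assert ccentrist_descriptor(img).values.size == 4200

    def test_tcentrist_default_length(self):
        layout = pyramid_blocks(128, 128)
        assert descriptor_length("tcentrist", layout) == 21 * 512 == 10752
        img = np.random.default_rng(0).integers(0, 256, (128, 128))
        assert tcentrist_descriptor(img).values.size == 10752

    def test_constant_image_mass_in_predicted_bins(self):
        img = np.full((128, 128), 100, dtype=np.uint8)
        d = ccentrist_descriptor(img, normalize=False)
        blocks = d.values.reshape(21, 200)
        # all mass in the joint bin (S=8, M=8, C=1)
        hot = (8 * 10 + 8) * 2 + 1
        assert np.all(blocks[:, hot] == blocks.sum(axis=1))
        assert blocks.sum() > 0
        t = tcentrist_descriptor(img, normalize=False).values.reshape(21, 512)
        assert np.all(t[:, 0] == t[:, :256].sum(axis=1))   # upper bin 0
        assert np.all(t[:, 256] == t[:, 256:].sum(axis=1))  # lower bin 0

    def test_unnormalized_block_mass_equals_coded_pixels(self, rng):
        img = rng.integers(0, 256, (16, 16))
        d = tcentrist_descriptor(img, normalize=False)
        per_block = d.values.reshape(21, 512)
        # level-0 block: all 14x14 coded pixels, counted once per histogram
        assert per_block[0, :256].sum() == 14 * 14
        assert per_block[0, 256:].sum() == 14 * 14

    def test_normalized_blocks_sum_to_one(self, rng):
        img = rng.integers(0, 256, (32, 32))
        d = ccentrist_descriptor(img, normalize=True)
        sums = d.values.reshape(21, 200).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    @pytest.mark.parametrize("extractor,ref", [
        ("ccentrist", ref_ccentrist), ("tcentrist", ref_tcentrist)])
    def test_matches_naive_per_block_reference(self, rng, extractor, ref):
        for img in random_images(rng, 8, (16, 16)):
            got = extract_descriptor(img, extractor).values
            np.testing.assert_allclose(got, ref(img), atol=1e-12)

    def test_level0_histogram_depends_only_on_code_multiset(self, rng):
        # rearranging pixels inside the image leaves the level-0 histogram
        # of CT codes unchanged only if the code multiset is unchanged;
        # assert the histogram is a pure function of the code multiset
        img = rng.integers(0, 256, (16, 16))
        d = centrist_descriptor(img, pyramid_blocks(16, 16, levels=[0]),
                                normalize=False)
        codes = census_transform(img).codes
        np.testing.assert_array_equal(
            d.values, np.bincount(codes.ravel(), minlength=256))

    def test_length_constant_across_images(self, rng):
        lens = {extract_descriptor(img, "tcentrist").values.size
                for img in random_images(rng, 5, (64, 64))}
        assert len(lens) == 1

    def test_descriptor_carries_image_metadata(self, rng):
        img = SpectrogramImage(
            pixels=rng.integers(0, 256, (16, 16)).astype(np.uint8),
            meta={"label": "EP", "subject_id": "S1"})
        d = tcentrist_descriptor(img)
        assert d.label == "EP" and d.subject_id == "S1"

    def test_unknown_extractor_rejected(self, rng):
        with pytest.raises(ValidationError):
            extract_descriptor(np.zeros((8, 8)), "gabor")
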