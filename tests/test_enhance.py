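"""Channel selection, entropy, Lab conversion and Otsu thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermseg import (
    ContractError,
    GrayImage,
    binarize,
    channel_entropy,
    corner_mask,
    extract_channel,
    luminance,
    otsu,
    split_lab,
)
from dermseg.enhance import threshold_value


def _solid(r, g, b, shape=(8, 8)):
    img = np.zeros((*shape, 3), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return img


class TestLuminance:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((0, 0, 0), 0.0), ((255, 0, 0), 76.2195), ((100, 100, 100), 99.99)],
    )
    def test_known_values(self, rgb, expected):
        assert luminance(_solid(*rgb)).pixels[0, 0] == pytest.approx(expected, abs=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.tuples(st.integers(0, 254), st.integers(0, 255), st.integers(0, 255)),
        st.integers(0, 2),
    )
    def test_monotone_in_every_channel(self, rgb, ch):
        base = list(rgb)
        raised = list(rgb)
        raised[ch] += 1
        assert luminance(_solid(*raised)).pixels[0, 0] > luminance(_solid(*base)).pixels[0, 0]


class TestChannelEntropy:
    def test_constant_channel_zero_entropy(self):
        assert channel_entropy(_solid(7, 7, 7)).per_channel == (0.0, 0.0, 0.0)

    def test_two_equal_levels_one_bit(self):
        img = _solid(0, 0, 0, shape=(8, 8))
        img[:4, :, 0] = 200  # red half/half
        assert channel_entropy(img).per_channel[0] == pytest.approx(1.0)

    def test_uniform_blue_wins_with_eight_bits(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[..., 2] = np.arange(256, dtype=np.uint8).reshape(16, 16)
        ce = channel_entropy(img)
        assert ce.argmax_channel == 2
        assert ce.per_channel[2] == pytest.approx(8.0)

    def test_permutation_invariance(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        flat = img.reshape(-1, 3)
        shuffled = flat[rng.permutation(len(flat))].reshape(img.shape)
        assert channel_entropy(img).per_channel == channel_entropy(shuffled).per_channel

    def test_tie_breaks_toward_blue(self):
        img = _solid(0, 0, 0)
        img[:4, :, 0] = 10
        img[:4, :, 2] = 10  # red and blue both 1 bit
        assert channel_entropy(img).argmax_channel == 2


class TestLab:
    def test_white_black_neutral(self):
        L, a, b = split_lab(_solid(255, 255, 255))
        assert L.pixels[0, 0] == pytest.approx(100.0, abs=0.01)
        L, a, b = split_lab(_solid(0, 0, 0))
        assert (L.pixels[0, 0], a.pixels[0, 0], b.pixels[0, 0]) == pytest.approx((0, 0, 0), abs=0.01)

    def test_mid_gray_on_neutral_axis(self):
        _L, a, b = split_lab(_solid(119, 119, 119))
        assert abs(a.pixels[0, 0]) < 0.5
        assert abs(b.pixels[0, 0]) < 0.5


class TestExtractChannel:
    def test_blue_is_third_component(self):
        assert extract_channel(_solid(10, 20, 30), "blue").pixels[0, 0] == 30

    def test_luminance_delegates(self):
        img = _solid(12, 200, 3)
        assert np.array_equal(extract_channel(img, "luminance").pixels, luminance(img).pixels)

    def test_max_entropy_selects_uniform_blue(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[..., 2] = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert np.array_equal(extract_channel(img, "max_entropy").pixels, img[..., 2].astype(float))

    def test_unknown_selector_lists_valid_ones(self):
        with pytest.raises(ContractError, match="blue"):
            extract_channel(_solid(0, 0, 0), "chartreuse")


def _brute_force_otsu(levels: np.ndarray) -> tuple[int, float]:
    """Independent exhaustive minimization of the intra-class variance."""
    best_t, best_obj = None, np.inf
    total = levels.size
    for t in range(255):
        c1 = levels[levels <= t]
        c2 = levels[levels > t]
        if c1.size == 0 or c2.size == 0:
            continue
        obj = (c1.size / total) * c1.var() + (c2.size / total) * c2.var()
        if obj < best_obj - 1e-12:
            best_obj, best_t = obj, t
    return best_t, best_obj


class TestOtsu:
    def test_two_value_image_perfectly_separable(self):
        px = np.array([[10.0, 200.0]] * 32)
        res = otsu(GrayImage(px))
        assert res.objective == pytest.approx(0.0, abs=1e-12)
        assert res.threshold == 10  # smallest minimizer

    def test_extreme_values_zero_objective(self):
        px = np.array([[0.0, 255.0]] * 8)
        assert otsu(GrayImage(px)).objective == pytest.approx(0.0, abs=1e-12)

    def test_bimodal_gaussians_threshold_in_valley(self, rng):
        vals = np.concatenate(
            [rng.normal(60, 10, 5000), rng.normal(180, 10, 5000)]
        ).clip(0, 255)
        res = otsu(GrayImage(vals.reshape(100, 100)))
        assert 100 <= res.threshold <= 140

    def test_constant_image_rejected(self):
        with pytest.raises(ContractError, match="degenerate"):
            otsu(GrayImage(np.full((8, 8), 42.0)))

    def test_matches_brute_force_on_seeded_random_images(self, rng):
        for _ in range(10):
            px = rng.integers(0, 256, (24, 24)).astype(float)
            res = otsu(GrayImage(px))
            bf_t, bf_obj = _brute_force_otsu(px.astype(int))
            assert res.threshold == bf_t
            assert res.objective == pytest.approx(bf_obj, rel=1e-9)

    def test_class_weights_sum_to_one(self, rng):
        res = otsu(GrayImage(rng.integers(0, 256, (16, 16)).astype(float)))
        assert sum(res.class_weights) == pytest.approx(1.0, abs=1e-9)


class TestBinarize:
    def test_full_range_threshold_all_true(self):
        gi = GrayImage(np.arange(64, dtype=float).reshape(8, 8))
        assert binarize(gi, 255.0, dark_is_foreground=True).all()

    def test_below_range_threshold_rejected(self):
        gi = GrayImage(np.arange(64, dtype=float).reshape(8, 8))
        with pytest.raises(ContractError):
            binarize(gi, -1.0)

    def test_polarity(self):
        gi = GrayImage(np.array([[5.0, 250.0], [5.0, 250.0]]))
        assert np.array_equal(binarize(gi, 100.0, True), [[True, False], [True, False]])
        assert np.array_equal(binarize(gi, 100.0, False), [[False, True], [False, True]])


class TestCornerMask:
    def test_cornerless_phantom_gives_empty_mask(self):
        from dermseg import PhantomSpec, generate_phantom

        case = generate_phantom(PhantomSpec(corner_radius=0))
        assert not corner_mask(extract_channel(case.image, "blue")).any()

    def test_recovers_ground_truth_corners(self, clean_case):
        got = corner_mask(extract_channel(clean_case.image, "blue"))
        gt = clean_case.corner_mask
        dice = 2 * (got & gt).sum() / (got.sum() + gt.sum())
        assert dice >= 0.9

    def test_central_dark_lesion_excluded(self, clean_case):
        got = corner_mask(extract_channel(clean_case.image, "blue"))
        assert not (got & clean_case.lesion_mask).any()

    def test_degenerate_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = corner_mask(GrayImage(np.full((16, 16), 100.0)))
        assert not out.any()


def test_threshold_value_bin_edge_consistency():
    gi = GrayImage(np.array([[0.0, 255.0]] * 4))
    # level t and value threshold_value(t) select the same pixels
    t = otsu(gi).threshold
    v = threshold_value(gi, t)
    assert np.array_equal(binarize(gi, v), gi.pixels <= v)
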