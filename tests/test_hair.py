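"""Directional hair filters, hair segmentation and inpainting."""

import numpy as np
import pytest

from dermseg import (
    ContractError,
    DoGParams,
    GrayImage,
    PhantomSpec,
    directional_response,
    dog_kernel,
    generate_phantom,
    inpaint,
    line_image,
    median_smooth,
    remove_hairs,
    rotate_kernel,
    segment_hairs,
)


class TestDogKernel:
    def test_identical_gaussians_cancel(self):
        p = DoGParams(k1=1.0, k2=1.0, sigma_x1=2, sigma_y1=5, sigma_x2=2, sigma_y2=5)
        assert np.abs(dog_kernel(p)).max() == 0.0

    def test_center_value_before_mean_subtraction(self):
        # the unsubtracted kernel peaks at k1 - k2 at the origin; the
        # shipped kernel equals it minus the subtracted mean
        p = DoGParams(k1=1.0, k2=0.4)
        k = dog_kernel(p)
        half = p.min_half_size
        x, y = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
        g1 = np.exp(-(x**2 / (2 * p.sigma_x1**2) + y**2 / (2 * p.sigma_y1**2)))
        g2 = 0.4 * np.exp(-(x**2 / (2 * p.sigma_x2**2) + y**2 / (2 * p.sigma_y2**2)))
        raw = g1 - g2
        assert raw[half, half] == pytest.approx(0.6)
        assert k[half, half] == pytest.approx(raw[half, half] - raw.mean())

    def test_kernel_sums_to_zero_and_is_point_symmetric(self):
        p = DoGParams(k1=1.0, k2=0.5, sigma_x1=1, sigma_y1=4, sigma_x2=2, sigma_y2=8)
        k = dog_kernel(p)
        assert k.sum() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(k, k[::-1, ::-1])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ContractError):
            dog_kernel(DoGParams(sigma_x1=0.0))


class TestRotateKernel:
    def test_zero_rotation_is_identity(self):
        k = dog_kernel(DoGParams())
        assert np.array_equal(rotate_kernel(k, 0), k)

    def test_ninety_degrees_equals_transpose(self):
        k = dog_kernel(DoGParams())
        assert np.abs(rotate_kernel(k, 90) - k.T).max() < 1e-6

    def test_two_45s_compose_to_90(self):
        # bilinear resampling twice costs accuracy at the sharp ridge;
        # the composition error stays a small fraction of the peak
        k = dog_kernel(DoGParams())
        err = np.abs(rotate_kernel(rotate_kernel(k, 45), 45) - rotate_kernel(k, 90)).max()
        assert err < 0.12 * np.abs(k).max()

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ContractError):
            rotate_kernel(dog_kernel(DoGParams()), 180.0)


class TestDirectionalResponse:
    def test_constant_image_zero_response(self):
        det = directional_response(np.full((64, 64), 137.0), DoGParams())
        assert np.abs(det.response).max() < 1e-8

    @pytest.mark.parametrize("angle", [0, 30, 45, 60, 90, 120, 135, 150])
    def test_modal_best_angle_matches_rendered_line(self, angle):
        img = line_image(angle)
        det = directional_response(img, DoGParams())
        on_line = img < 100
        vals, counts = np.unique(det.best_angle[on_line], return_counts=True)
        assert vals[np.argmax(counts)] == angle

    def test_rotation_equivariance_of_peak_response(self):
        p = DoGParams()
        r0 = directional_response(line_image(0), p).response.max()
        r90 = directional_response(line_image(90), p).response.max()
        assert abs(r0 - r90) / max(r0, r90) < 0.05

    def test_image_smaller_than_kernel_rejected(self):
        with pytest.raises(ContractError):
            directional_response(np.zeros((10, 10)), DoGParams())


class TestSegmentHairs:
    def test_all_below_fixed_threshold_gives_empty_mask(self):
        assert not segment_hairs(np.full((32, 32), 5.0), "fixed:10").any()

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ContractError, match="strategy"):
            segment_hairs(np.zeros((32, 32)), "psychic")

    def test_phantom_hair_recall(self):
        case = generate_phantom(PhantomSpec(n_hairs=10, seed=21))
        p = DoGParams()
        det = directional_response(
            case.image.astype(float) @ np.array([0.2989, 0.5870, 0.1140]), p
        )
        mask = segment_hairs(det.response, params=p)
        from skimage.morphology import dilation, disk

        recall = (dilation(mask, disk(2)) & case.hair_mask).sum() / case.hair_mask.sum()
        assert recall >= 0.7

    def test_hairless_phantom_nearly_empty_mask(self):
        case = generate_phantom(PhantomSpec(n_hairs=0, n_bubbles=3, seed=21))
        p = DoGParams()
        det = directional_response(
            case.image.astype(float) @ np.array([0.2989, 0.5870, 0.1140]), p
        )
        mask = segment_hairs(det.response, params=p)
        assert mask.mean() < 0.01


class TestInpaint:
    def test_empty_mask_returns_image_unchanged(self):
        img = generate_phantom(PhantomSpec()).image
        out = inpaint(img, np.zeros(img.shape[:2], dtype=bool))
        assert np.array_equal(out, img)

    def test_constant_region_fills_exactly(self):
        px = np.full((40, 40), 77.0)
        mask = np.zeros((40, 40), dtype=bool)
        mask[15:25, 15:25] = True
        out = inpaint(GrayImage(px), mask, dilation_radius=0)
        assert np.abs(out.pixels - 77.0).max() < 1e-6

    def test_pixels_outside_dilated_mask_untouched(self):
        case = generate_phantom(PhantomSpec(n_hairs=5, seed=2))
        from skimage.morphology import dilation, disk

        out = inpaint(case.image, case.hair_mask, dilation_radius=2)
        outside = ~dilation(case.hair_mask, disk(2))
        assert np.array_equal(out[outside], case.image[outside])

    def test_reduces_error_to_hairfree_twin(self):
        hairy = generate_phantom(PhantomSpec(n_hairs=8, seed=3))
        bald = generate_phantom(PhantomSpec(n_hairs=0, seed=3))
        m = hairy.hair_mask
        out = inpaint(hairy.image, m)
        before = np.abs(hairy.image[m].astype(float) - bald.image[m].astype(float)).mean()
        after = np.abs(out[m].astype(float) - bald.image[m].astype(float)).mean()
        assert after <= 0.5 * before

    def test_all_true_mask_rejected(self):
        with pytest.raises(ContractError, match="nothing to inpaint"):
            inpaint(GrayImage(np.zeros((16, 16))), np.ones((16, 16), dtype=bool))


class TestMedianSmooth:
    def test_constant_unchanged(self):
        out = median_smooth(GrayImage(np.full((16, 16), 9.0)), 3)
        assert np.array_equal(out.pixels, np.full((16, 16), 9.0))

    def test_impulse_removed(self):
        px = np.full((16, 16), 50.0)
        px[8, 8] = 250.0
        out = median_smooth(GrayImage(px), 3)
        assert out.pixels[8, 8] == 50.0

    def test_step_edge_preserved(self):
        px = np.zeros((16, 16))
        px[:, 8:] = 100.0
        out = median_smooth(GrayImage(px), 3)
        assert np.array_equal(out.pixels, px)

    def test_even_window_rejected(self):
        with pytest.raises(ContractError):
            median_smooth(GrayImage(np.zeros((8, 8))), 4)


class TestRemoveHairs:
    def test_hairless_phantom_barely_modified(self):
        case = generate_phantom(PhantomSpec(n_hairs=0, seed=6))
        out, mask = remove_hairs(case.image)
        changed = (out != case.image).any(axis=2).mean()
        assert changed < 0.02

    def test_second_pass_changes_little(self):
        case = generate_phantom(PhantomSpec(n_hairs=6, seed=6))
        once, _ = remove_hairs(case.image)
        twice, _ = remove_hairs(once)
        assert (twice != once).any(axis=2).mean() < 0.005

    def test_returns_cleaned_image_and_mask_pair(self):
        case = generate_phantom(PhantomSpec(n_hairs=6, seed=8))
        out, mask = remove_hairs(case.image)
        assert out.shape == case.image.shape and out.dtype == np.uint8
        assert mask.shape == case.image.shape[:2] and mask.dtype == bool
        assert mask.any()
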