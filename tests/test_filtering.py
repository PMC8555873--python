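"""Filter application, fixed-point arithmetic model, threshold, depth, cycles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from veinmf import (
    GrayImage,
    KernelSpec,
    PipelineCostModel,
    build_bank,
    build_kernel,
    convolve_fixed,
    convolve_float,
    cycle_count,
    depth_render,
    extract_veins,
    respond,
    shiftadd_multiply,
    threshold_from_max,
    tree_sum,
)
from veinmf.filtering import apply_threshold, frame_time_s, frames_per_second
from veinmf.kernels import KernelBank
from veinmf.synth import generate_phantom, single_bar_config


class TestConvolveFloat:
    def test_constant_image_gives_zero_response(self, default_bank):
        img = np.full((40, 40), 137.0)
        for k in default_bank:
            assert np.allclose(convolve_float(img, k), 0.0, atol=1e-6)

    def test_1x1_identity_kernel(self, rng):
        img = rng.integers(0, 256, (12, 17)).astype(float)
        out = convolve_float(img, np.array([[1.0]]))
        assert np.allclose(out, img, atol=1e-9)

    def test_3x3_single_valid_value_is_dot_product(self):
        img = np.arange(9, dtype=float).reshape(3, 3)
        ker = np.array([[1.0, -2.0, 0.5], [0.0, 3.0, -1.0], [2.0, 0.0, 1.0]])
        # correlation, no flip: elementwise product summed
        expected = float(np.sum(img * ker))
        out = convolve_float(img, ker)
        assert out.shape == (1, 1)
        assert np.allclose(out[0, 0], expected, atol=1e-9)

    def test_border_modes_and_size_check(self, default_bank):
        img = np.zeros((30, 25))
        k = default_bank[0]
        assert convolve_float(img, k, border="valid").shape == (10, 5)
        assert convolve_float(img, k, border="same").shape == (30, 25)
        with pytest.raises(ValueError, match="smaller"):
            convolve_float(np.zeros((10, 10)), k)
        with pytest.raises(ValueError, match="border"):
            convolve_float(img, k, border="wrap")


class TestShiftAdd:
    @pytest.mark.parametrize("p,c,expected", [(7, -33, -231), (0, 5, 0), (255, 127, 32385), (255, -128, -32640)])
    def test_examples(self, p, c, expected):
        assert shiftadd_multiply(p, c) == expected

    def test_matches_builtin_on_random_operands(self, rng):
        p = rng.integers(0, 256, 500)
        c = rng.integers(-128, 128, 500)
        assert np.array_equal(shiftadd_multiply(p, c), p * c)

    def test_out_of_range_operands_rejected(self):
        with pytest.raises(ValueError):
            shiftadd_multiply(256, 1)
        with pytest.raises(ValueError):
            shiftadd_multiply(1, 128)


class TestTreeSum:
    @pytest.mark.parametrize("values,expected", [([5], 5), ([1, 2, 3, 4], 10), ([1, 2, 3], 6)])
    def test_examples(self, values, expected):
        assert tree_sum(values) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-32768, 32767), min_size=1, max_size=441))
    def test_equals_sequential_sum(self, values):
        assert tree_sum(values) == sum(values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tree_sum([])


class TestConvolveFixed:
    def test_matches_direct_integer_correlation(self, default_bank, rng):
        for _ in range(5):
            img = rng.integers(0, 256, (32, 32))
            for k in default_bank:
                direct = signal.correlate(img.astype(np.int64), k.int_grid.astype(np.int64), mode="valid")
                assert np.array_equal(convolve_fixed(img, k), direct)

    def test_constant_image_zero_sum_kernel(self):
        ker = np.array([[1, -2, 1], [0, 0, 0], [-1, 2, -1]], dtype=np.int16)
        assert ker.sum() == 0
        out = convolve_fixed(np.full((10, 10), 200, dtype=np.int64), ker)
        assert np.all(out == 0)

    def test_scaled_relation_to_float_path(self, default_bank, rng):
        # |fixed/scale - float| bounded by the per-coefficient quantization
        # residue (<1/scale) times the max pixel value times the area
        img = rng.integers(0, 256, (32, 32))
        for k in default_bank:
            fx = convolve_fixed(img, k) / 100.0
            fl = convolve_float(img, k)
            bound = 255.0 * k.area_A / 100.0
            assert np.max(np.abs(fx - fl)) <= bound

    def test_same_border_shape(self, default_bank, rng):
        img = rng.integers(0, 256, (32, 32))
        assert convolve_fixed(img, default_bank[0], border="same").shape == (32, 32)

    def test_non_integer_image_rejected(self, default_bank):
        with pytest.raises(ValueError, match="integer"):
            convolve_fixed(np.full((25, 25), 0.5), default_bank[0])


class TestRespond:
    def test_single_kernel_bank_argmax_zero(self, default_spec, rng):
        k = build_kernel(default_spec, 0.0)
        bank = KernelBank(spec=default_spec, kernels=(k,))
        img = rng.integers(0, 256, (30, 30)).astype(float)
        fr = respond(img, bank)
        assert np.allclose(fr.response, convolve_float(img, k))
        assert np.all(fr.arg_orientation == 0)

    def test_empty_bank_rejected(self, default_spec):
        with pytest.raises(ValueError, match="empty"):
            respond(np.zeros((30, 30)), KernelBank(spec=default_spec, kernels=()))

    def test_tie_breaks_to_lowest_index(self, default_spec, rng):
        # duplicate kernels respond identically everywhere: index 0 must win
        k = build_kernel(default_spec, 0.0)
        bank = KernelBank(spec=default_spec, kernels=(k, k, k))
        fr = respond(rng.integers(0, 256, (30, 30)).astype(float), bank)
        assert np.all(fr.arg_orientation == 0)

    @pytest.mark.parametrize("phi,expected_idx", [(0, 0), (45, 1), (90, 2), (135, 3)])
    def test_bar_phantom_selects_matching_orientation(self, default_bank, bar_phantoms, phi, expected_idx):
        ph = bar_phantoms[phi]
        fr = respond(ph.image.pixels, default_bank)
        cl = ph.centerline_mask[10:-10, 10:-10]
        assert np.mean(fr.arg_orientation[cl] == expected_idx) >= 0.9

    def test_fixed_and_float_paths_agree_on_argmax(self, default_bank):
        ph = generate_phantom(single_bar_config(45, size=48))
        fr_f = respond(ph.image.pixels, default_bank, path="float")
        fr_x = respond(ph.image.pixels, default_bank, path="fixed")
        cl = ph.centerline_mask[10:-10, 10:-10]
        assert np.array_equal(fr_f.arg_orientation[cl], fr_x.arg_orientation[cl])


class TestThresholdAndDepth:
    def test_alpha_one_keeps_only_argmax_pixels(self, rng):
        resp = rng.random((20, 20))
        resp[5, 7] = 2.0
        thr = threshold_from_max(resp, alpha=1.0)
        mask = apply_threshold(resp, thr)
        assert mask.sum() == 1 and mask[5, 7]

    def test_uniform_response_half_alpha_full_mask(self):
        resp = np.full((10, 10), 10.0)
        thr = threshold_from_max(resp, alpha=0.5)
        assert thr == 5.0
        assert apply_threshold(resp, thr).all()

    def test_non_positive_response_warns_and_empties_mask(self):
        resp = -np.ones((5, 5))
        with pytest.warns(UserWarning, match="non-positive"):
            thr = threshold_from_max(resp)
        assert not apply_threshold(resp, thr).any()

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            threshold_from_max(np.ones((3, 3)), alpha=0.0)
        with pytest.raises(ValueError):
            threshold_from_max(np.array([]))

    def test_depth_render_empty_mask(self):
        out = depth_render(np.ones((4, 4)), np.zeros((4, 4), bool))
        assert np.all(out == 0)

    def test_depth_render_uniform_masked_response(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        out = depth_render(np.full((4, 4), 7.0), mask)
        assert np.all(out[mask] == 255.0)
        assert np.all(out[~mask] == 0.0)

    def test_depth_render_preserves_ordering_and_raw_mode(self, rng):
        resp = rng.random((8, 8)) * 100
        mask = resp > 20
        out = depth_render(resp, mask)
        vals, outs = resp[mask], out[mask]
        order = np.argsort(vals)
        assert np.all(np.diff(outs[order]) >= -1e-12)
        raw = depth_render(resp, mask, rescale=False)
        assert np.allclose(raw, resp * mask)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            depth_render(np.ones((3, 3)), np.ones((4, 4), bool))


class TestPipeline:
    def test_extract_veins_populates_all_fields(self, default_bank, two_vessel_phantom):
        fr = extract_veins(two_vessel_phantom.image.pixels, default_bank)
        assert fr.threshold_value == pytest.approx(0.5 * fr.response.max())
        assert fr.binary_mask.dtype == bool
        assert np.all(fr.depth_image[~fr.binary_mask] == 0)
        assert fr.binary_mask.any()

    def test_depth_ordering_on_two_vessel_phantom(self, default_bank, two_vessel_phantom):
        from veinmf.synth import vessel_distance_field

        ph = two_vessel_phantom
        cfg = ph.config
        fr = extract_veins(ph.image.pixels, default_bank, alpha=0.45)
        m = 10
        d1 = vessel_distance_field(cfg.vessels[0], cfg.height, cfg.width)[m:-m, m:-m]
        d2 = vessel_distance_field(cfg.vessels[1], cfg.height, cfg.width)[m:-m, m:-m]
        c1, c2 = d1 <= 0.5, d2 <= 0.5
        # at alpha=0.45 both vessels are segmented; the deep one renders brighter
        assert fr.binary_mask[c1].all() and fr.binary_mask[c2].all()
        assert fr.depth_image[c1].mean() > fr.depth_image[c2].mean()

    def test_segmentation_dice_matches_frozen_oracle_value(self, default_bank, two_vessel_phantom):
        """Dice vs the dilated ground-truth mask, pinned from the packaged
        noiseless fixture (independently computed by direct scipy correlation)."""
        ph = two_vessel_phantom
        fr = extract_veins(ph.image.pixels, default_bank, alpha=0.5)
        vm = ph.vessel_mask[10:-10, 10:-10]
        dice = 2 * (fr.binary_mask & vm).sum() / (fr.binary_mask.sum() + vm.sum())
        assert dice == pytest.approx(0.375, abs=1e-12)


class TestCycles:
    @pytest.mark.parametrize("h,w,total", [(480, 752, 360974), (1, 1, 15), (1, 2, 16)])
    def test_frame_totals(self, h, w, total):
        assert cycle_count(h, w) == total

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(h=st.integers(1, 2000), w=st.integers(1, 2000))
    def test_default_model_is_hw_plus_14(self, h, w):
        assert cycle_count(h, w) == h * w + 14

    def test_custom_model_and_validation(self):
        model = PipelineCostModel(clocks_multiply=2, clocks_add=3, clocks_max=1)
        assert model.latency == 6
        assert cycle_count(10, 10, model) == 105
        with pytest.raises(ValueError):
            PipelineCostModel(clocks_multiply=0)
        with pytest.raises(ValueError):
            cycle_count(0, 5)

    def test_frame_time_and_fps(self):
        t = frame_time_s(480, 752)
        assert t == pytest.approx(360974 / 24e6)
        assert frames_per_second(480, 752) == pytest.approx(1 / t)
        assert 66 < frames_per_second(480, 752) < 67


class TestGrayImage:
    def test_validation(self):
        with pytest.raises(ValueError):
            GrayImage(np.array([1, 2, 3]))
        with pytest.raises(ValueError):
            GrayImage(np.array([[300.0]]))
        img = GrayImage(np.array([[0, 255], [128, 1]], dtype=np.uint8))
        assert img.height == 2 and img.width == 2
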