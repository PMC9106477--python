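import numpy as np
import pytest

from fdcnet.image import (
    LandmarkPair,
    PreprocessConfig,
    Preprocessor,
    RawImage,
    compute_base,
    compute_origin,
    default_landmarks,
    deskew,
    equalize_histogram,
    highpass_components,
    highpass_filter,
    load_image,
    median_filter,
    resize_to_standard,
    rgb_to_gray,
    rotation_angle,
    save_image,
)


class TestIO:
    def test_png_zeros_roundtrip(self, tmp_path):
        img = RawImage(np.zeros((4, 4)), max_value=255)
        save_image(img, tmp_path / "z.png")
        back = load_image(tmp_path / "z.png")
        assert back.max_value == 255
        assert np.all(back.data == 0)

    def test_png_random_roundtrip_bit_identical(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(9, 7)).astype(np.float64)
        save_image(RawImage(arr), tmp_path / "r.png")
        back = load_image(tmp_path / "r.png")
        assert np.array_equal(back.data, arr)

    def test_nifti_constant_volume(self, tmp_path):
        vol = np.full((8, 8, 4), 7.0)
        save_image(RawImage(vol, max_value=255), tmp_path / "v.nii")
        back = load_image(tmp_path / "v.nii")
        assert back.data.shape == (8, 8, 4)
        assert np.all(back.data == 7)

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(IOError, match="nope.png"):
            load_image(tmp_path / "nope.png")

    def test_unsupported_format(self, tmp_path):
        p = tmp_path / "data.xyz"
        p.write_text("junk")
        with pytest.raises(ValueError, match="unsupported"):
            load_image(p)


class TestRawImage:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            RawImage(np.array([[300.0]]), max_value=255)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            RawImage(np.array([[np.nan, 0.0]]))

    def test_rejects_wrong_rank(self):
        with pytest.raises(ValueError):
            RawImage(np.zeros(5))


class TestLandmarkGeometry:
    def test_base_345_triangle(self):
        lm = LandmarkPair(p5=(6, 8), p10=(0, 0))
        assert compute_base(lm) == pytest.approx(5.0)

    def test_base_coincident_is_zero(self):
        lm = LandmarkPair(p5=(3, 4), p10=(3, 4))
        assert compute_base(lm) == 0.0

    def test_base_is_half_euclidean_distance(self, rng):
        for _ in range(50):
            p5, p10 = rng.uniform(-50, 50, 2), rng.uniform(-50, 50, 2)
            lm = LandmarkPair(p5=tuple(p5), p10=tuple(p10))
            assert compute_base(lm) == pytest.approx(
                0.5 * np.linalg.norm(p5 - p10))

    def test_origin_as_printed(self):
        assert compute_origin(LandmarkPair((6, 8), (0, 0))) == (3, 4)
        assert compute_origin(LandmarkPair((1, 1), (1, 1))) == (0, 0)
        # integer landmarks may give half-integer origins, no rounding
        assert compute_origin(LandmarkPair((3, 0), (0, 0))) == (1.5, 0)

    @pytest.mark.parametrize("p5,p10,expect", [
        ((1, 1), (0, 0), np.pi / 4),
        ((5, 2), (1, 2), 0.0),
        ((1, -1), (0, 0), -np.pi / 4),
    ])
    def test_rotation_angle(self, p5, p10, expect):
        assert rotation_angle(LandmarkPair(p5, p10)) == pytest.approx(expect)

    def test_vertical_baseline_rejected(self):
        with pytest.raises(ValueError, match="vertical"):
            rotation_angle(LandmarkPair((2, 5), (2, 0)))


class TestDeskew:
    def test_zero_angle_is_identity(self, rng):
        img = RawImage(rng.uniform(0, 255, (32, 32)))
        out = deskew(img, 0.0)
        assert np.allclose(out.data, img.data)

    def test_rotation_roundtrip_away_from_borders(self, rng):
        data = np.zeros((64, 64))
        data[16:48, 16:48] = rng.uniform(50, 200, (32, 32))
        from scipy import ndimage
        data = ndimage.gaussian_filter(data, 3.0)  # band-limit: bilinear error scales with curvature
        img = RawImage(np.clip(data, 0, 255))
        theta = 0.3
        back = deskew(deskew(img, theta), -theta)
        inner = (slice(12, 52), slice(12, 52))
        assert np.max(np.abs(back.data[inner] - img.data[inner])) <= 2.0

    def test_centered_disk_rotation_invariant(self):
        # radius large enough that rasterization noise stays below the band
        yy, xx = np.mgrid[:128, :128]
        disk = ((yy - 63.5) ** 2 + (xx - 63.5) ** 2 <= 40 ** 2)
        img = RawImage(disk * 200.0)
        for theta in (0.4, -0.9, 1.2):
            out = deskew(img, theta)
            m = out.data > 100
            iou = (m & disk).sum() / (m | disk).sum()
            assert iou >= 0.98


class TestResize:
    def test_same_size_noop(self, rng):
        img = RawImage(rng.uniform(0, 255, (32, 32)))
        assert np.array_equal(resize_to_standard(img, 32).data, img.data)

    def test_constant_preserved(self):
        out = resize_to_standard(RawImage(np.full((10, 14), 42.0)), 24)
        assert out.data.shape == (24, 24)
        assert np.allclose(out.data, 42.0)

    def test_checkerboard_mean_preserved(self):
        board = np.indices((128, 128)).sum(axis=0) % 2 * 255.0
        out = resize_to_standard(RawImage(board), 256)
        assert out.data.shape == (256, 256)
        assert abs(out.data.mean() - board.mean()) <= 0.01 * 255

    def test_volume_resizes_slices_only(self):
        vol = RawImage(np.full((10, 10, 3), 5.0))
        out = resize_to_standard(vol, 16)
        assert out.data.shape == (16, 16, 3)


class TestEqualize:
    def test_constant_stays_constant(self):
        out = equalize_histogram(RawImage(np.full((8, 8), 99.0)))
        assert np.ptp(out.data) == 0

    def test_two_level_cdf_mapping(self):
        data = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)])
        out = equalize_histogram(RawImage(data.reshape(10, 10)))
        levels = np.unique(out.data)
        assert len(levels) == 2
        assert levels[1] == pytest.approx(255.0)
        assert levels[0] == pytest.approx(0.5 * 255.0)

    def test_rank_order_preserved(self, rng):
        data = rng.uniform(0, 255, (32, 32))
        out = equalize_histogram(RawImage(data))
        flat_in, flat_out = data.ravel(), out.data.ravel()
        idx = rng.integers(0, flat_in.size, size=(300, 2))
        for i, j in idx:
            if flat_in[i] < flat_in[j]:
                assert flat_out[i] <= flat_out[j]


class TestMedian:
    def test_constant_unchanged(self):
        img = RawImage(np.full((6, 6), 17.0))
        assert np.array_equal(median_filter(img, 3).data, img.data)

    def test_lone_salt_pixel_removed(self):
        data = np.zeros((5, 5))
        data[2, 2] = 255.0
        assert np.all(median_filter(RawImage(data), 3).data == 0)

    def test_matches_bruteforce_sliding_window(self, rng):
        data = rng.uniform(0, 255, (9, 9))
        out = median_filter(RawImage(data), 3).data
        padded = np.pad(data, 1, mode="symmetric")  # edge-duplicating reflection
        for i in range(9):
            for j in range(9):
                window = padded[i:i + 3, j:j + 3]
                assert out[i, j] == pytest.approx(np.median(window))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_filter(RawImage(np.zeros((4, 4))), 4)


class TestHighpass:
    def test_constant_gives_flat_zero(self):
        out = highpass_filter(RawImage(np.full((8, 8), 120.0)))
        assert np.all(out.data == 0)

    def test_step_edge_peak_at_edge(self):
        data = np.zeros((16, 32))
        data[:, 16:] = 200.0
        out = highpass_filter(RawImage(data))
        profile = np.abs(out.data - out.data.mean()).mean(axis=0)
        assert abs(int(np.argmax(profile)) - 16) <= 1

    def test_lowpass_plus_highpass_reconstructs(self, rng):
        img = RawImage(rng.uniform(0, 255, (16, 16)))
        low, high = highpass_components(img, sigma=2.0)
        assert np.allclose(low + high, img.data, atol=1e-6)


class TestRgbToGray:
    def test_white_is_255(self):
        img = RawImage(np.full((2, 2, 3), 255.0), channels="rgb")
        assert np.allclose(rgb_to_gray(img).data, 255.0)

    def test_pure_red(self):
        data = np.zeros((2, 2, 3))
        data[..., 0] = 255.0
        gray = rgb_to_gray(RawImage(data, channels="rgb")).data
        assert int(round(gray[0, 0])) == 76

    def test_achromatic_identity(self):
        data = np.full((3, 3, 3), 111.0)
        gray = rgb_to_gray(RawImage(data, channels="rgb")).data
        assert np.allclose(gray, 111.0)

    def test_gray_input_passthrough_warns(self):
        img = RawImage(np.zeros((4, 4)))
        with pytest.warns(UserWarning):
            out = rgb_to_gray(img)
        assert out is img


class TestPreprocessor:
    def test_chain_preserves_validity(self, rng):
        cfg = PreprocessConfig(target_size=48, deskew=True)
        img = RawImage(rng.uniform(0, 255, (64, 64)))
        out = Preprocessor(cfg).run(img)
        assert out.data.shape == (48, 48)
        assert np.all(np.isfinite(out.data))
        assert out.data.min() >= 0 and out.data.max() <= out.max_value

    def test_default_landmarks_need_foreground(self):
        assert default_landmarks(RawImage(np.zeros((16, 16)))) is None

    def test_default_landmarks_on_blob(self):
        data = np.zeros((32, 32))
        data[10:20, 8:26] = 200.0
        lm = default_landmarks(RawImage(data))
        assert lm is not None and lm.p5 != lm.p10

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(median_kernel=2)
        with pytest.raises(ValueError):
            PreprocessConfig(target_size=0)
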