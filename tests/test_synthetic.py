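"""Synthetic eye-image generator: rendering, I/O, preprocessing, splits."""

import numpy as np
import pandas as pd
import pytest

from vimsa.synthetic import (EyeImageSample, SyntheticEyeConfig, easy_config,
                             generate_dataset, generate_eye_image, load_dataset,
                             original_frame_coords, preprocess_image,
                             save_dataset, split_dataset)


class TestGenerateEyeImage:
    def test_noise_free_midpoint_centroid(self):
        cfg = SyntheticEyeConfig(noise_std=0, glint_probability=0,
                                 occluder_probability=0,
                                 illumination_gradient_amplitude=0)
        s = generate_eye_image(cfg, np.random.default_rng(0),
                               center=((cfg.image_width - 1) / 2, (cfg.image_height - 1) / 2))
        assert s.pixels.min() == cfg.pupil_intensity
        ys, xs = np.where(s.pixels == cfg.pupil_intensity)
        assert abs(xs.mean() - (cfg.image_width - 1) / 2) < 0.5
        assert abs(ys.mean() - (cfg.image_height - 1) / 2) < 0.5

    def test_bit_identical_given_same_rng_state(self):
        cfg = SyntheticEyeConfig()
        a = generate_eye_image(cfg, np.random.default_rng(42))
        b = generate_eye_image(cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert (a.center_x, a.center_y) == (b.center_x, b.center_y)

    def test_dark_mask_centroid_tracks_label(self):
        """Brute-force centroid of the darkest-10% mask recovers the label.

        The pupil geometry is sized so pupil+iris always covers more than
        10% of the frame and the margin keeps the whole iris disc in frame,
        so the mask (pupil plus concentric iris) stays centered on the
        label."""
        cfg = SyntheticEyeConfig(
            image_width=128, image_height=96, pupil_radius_range=(10.0, 14.0),
            margin=31.0, noise_std=0, glint_probability=0,
            occluder_probability=0, illumination_gradient_amplitude=0)
        rng = np.random.default_rng(11)
        hits = 0
        n = 120
        for _ in range(n):
            s = generate_eye_image(cfg, rng)
            thresh = np.quantile(s.pixels, 0.10)
            ys, xs = np.where(s.pixels <= thresh)
            if np.hypot(xs.mean() - s.center_x, ys.mean() - s.center_y) <= 2.0:
                hits += 1
        assert hits / n >= 0.95

    def test_intensity_ordering_in_regions(self):
        cfg = SyntheticEyeConfig(noise_std=0, glint_probability=0,
                                 occluder_probability=0,
                                 illumination_gradient_amplitude=0)
        s = generate_eye_image(cfg, np.random.default_rng(1))
        a = s.metadata["pupil_a"]
        yy, xx = np.mgrid[0:cfg.image_height, 0:cfg.image_width]
        r = np.hypot(xx - s.center_x, yy - s.center_y)
        pupil = s.pixels[r < 0.5 * s.metadata["pupil_b"]]
        iris = s.pixels[(r > 1.3 * a) & (r < 2.0 * a)]
        sclera = s.pixels[r > 2.8 * a]
        assert pupil.mean() < iris.mean() < sclera.mean()

    def test_label_stays_clear_of_border(self):
        cfg = SyntheticEyeConfig()
        rng = np.random.default_rng(2)
        for _ in range(50):
            s = generate_eye_image(cfg, rng)
            assert cfg.margin <= s.center_x <= cfg.image_width - 1 - cfg.margin
            assert cfg.margin <= s.center_y <= cfg.image_height - 1 - cfg.margin

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="margin"):
            generate_eye_image(SyntheticEyeConfig(margin=5.0), np.random.default_rng(0))
        with pytest.raises(ValueError, match="intensity ordering"):
            generate_eye_image(SyntheticEyeConfig(pupil_intensity=150, iris_intensity=100),
                               np.random.default_rng(0))
        with pytest.raises(ValueError, match="glint_probability"):
            generate_eye_image(SyntheticEyeConfig(glint_probability=1.5),
                               np.random.default_rng(0))


class TestGenerateDataset:
    def test_sizes_and_unique_filenames(self):
        samples, labels = generate_dataset(SyntheticEyeConfig(), 10,
                                           np.random.default_rng(0))
        assert len(samples) == 10 and len(labels) == 10
        assert labels.filename.is_unique
        assert list(labels.columns) == ["filename", "center_x", "center_y"]

    def test_same_seed_identical_label_tables(self):
        cfg = SyntheticEyeConfig(seed=9)
        _, a = generate_dataset(cfg, 6)
        _, b = generate_dataset(cfg, 6)
        pd.testing.assert_frame_equal(a, b)

    def test_glint_fraction_within_binomial_band(self):
        cfg = SyntheticEyeConfig(noise_std=0, glint_probability=0.3)
        n = 400
        samples, _ = generate_dataset(cfg, n, np.random.default_rng(5))
        frac = np.mean([s.metadata["has_glint"] for s in samples])
        sigma = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) <= 3 * sigma

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(SyntheticEyeConfig(), 0)


class TestImageIO:
    def test_png_round_trip(self, tmp_path):
        cfg = easy_config(64, 48, seed=0)
        samples, labels = generate_dataset(cfg, 3)
        save_dataset(samples, labels, tmp_path)
        loaded, labels2 = load_dataset(tmp_path)
        assert len(loaded) == 3
        pd.testing.assert_frame_equal(labels, labels2)
        # 8-bit quantization only
        assert np.max(np.abs(loaded[0].pixels - np.rint(samples[0].pixels))) <= 0.5

    def test_pgm_accepted_on_read(self, tmp_path):
        from PIL import Image

        arr = np.random.default_rng(0).integers(0, 255, size=(48, 64)).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(tmp_path / "eye_00000.pgm")
        pd.DataFrame({"filename": ["eye_00000.pgm"], "center_x": [10.0],
                      "center_y": [20.0]}).to_csv(tmp_path / "labels.csv", index=False)
        loaded, _ = load_dataset(tmp_path)
        np.testing.assert_array_equal(loaded[0].pixels, arr)


class TestPreprocess:
    def test_proportional_downscale_by_two(self, rng):
        s = EyeImageSample(rng.uniform(0, 255, size=(480, 640)), 320.0, 240.0)
        out = preprocess_image(s)
        assert out.pixels.shape == (240, 320)
        assert (out.center_x, out.center_y) == (160.0, 120.0)
        # area averaging over exact 2x2 cells
        np.testing.assert_allclose(out.pixels[0, 0], s.pixels[:2, :2].mean())

    def test_center_crop_offsets(self, rng):
        s = EyeImageSample(rng.uniform(0, 255, size=(288, 384)), 192.0, 144.0)
        out = preprocess_image(s)
        assert out.pixels.shape == (240, 320)
        assert (out.center_x, out.center_y) == (160.0, 120.0)
        np.testing.assert_array_equal(out.pixels, s.pixels[24:264, 32:352])

    def test_already_target_size_identity(self, rng):
        s = EyeImageSample(rng.uniform(0, 255, size=(240, 320)), 7.0, 9.0)
        out = preprocess_image(s)
        np.testing.assert_array_equal(out.pixels, s.pixels)
        assert (out.center_x, out.center_y) == (7.0, 9.0) and not out.discarded

    def test_label_outside_crop_is_discarded_not_clamped(self, rng):
        s = EyeImageSample(rng.uniform(0, 255, size=(288, 384)), 5.0, 5.0)
        out = preprocess_image(s)
        assert out.discarded
        assert out.center_x == 5.0 - 32  # translated, not clamped

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            preprocess_image(EyeImageSample(np.zeros((100, 100)), 1, 1))

    def test_label_consistency_after_each_path(self):
        """Noise-free pupil centroid recomputed from pixels matches the
        transformed label within a pixel, for both preprocessing paths."""
        base = easy_config(640, 480, seed=0)
        thresh = (base.pupil_intensity + base.iris_intensity) / 2  # pupil-only mask
        rng = np.random.default_rng(3)
        for _ in range(5):
            s = generate_eye_image(base, rng)
            out = preprocess_image(s)
            ys, xs = np.where(out.pixels <= thresh)
            assert np.hypot(xs.mean() - out.center_x, ys.mean() - out.center_y) < 1.0

    def test_original_frame_inverse(self):
        assert original_frame_coords(160, 120, {"mode": "scale", "factor": 2}) == (320, 240)
        assert original_frame_coords(160, 120, {"mode": "crop", "offset": (32, 24)}) == (192, 144)


class TestSplitDataset:
    def test_default_85_15_split(self):
        train, test = split_dataset(list(range(100)), 0.85, np.random.default_rng(0))
        assert (len(train), len(test)) == (85, 15)

    def test_partition_is_disjoint_and_exhaustive(self):
        items = list(range(37))
        train, test = split_dataset(items, 0.85, np.random.default_rng(1))
        assert sorted(train + test) == items
        assert not set(train) & set(test)

    def test_degenerate_single_sample_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="vimsa.synthetic"):
            train, test = split_dataset([0], 0.85, np.random.default_rng(0))
        assert (len(train), len(test)) == (1, 0)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_deterministic_given_rng(self):
        a = split_dataset(list(range(20)), 0.85, np.random.default_rng(7))
        b = split_dataset(list(range(20)), 0.85, np.random.default_rng(7))
        assert a == b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([], 0.85)
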