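"""Synthetic paired-data generator: determinism, effects, round trips."""

import dataclasses
import io

import numpy as np
import pytest
from PIL import Image

from pearfuse.synthetic_data import (
    SyntheticConfig, generate_image, generate_paired_dataset,
    generate_raw_scan_set, generate_spectrum,
)


def small(**kw) -> SyntheticConfig:
    base = dict(n_per_class=4, image_size_px=48, seed=9)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_bands": 1},
            {"wavelength_end_nm": 800.0},
            {"image_size_px": 8},
            {"spectral_effect_size": -0.1},
            {"image_effect_size": -0.2},
            {"scans_per_region": 0},
            {"spectral_noise_sd": -1e-3},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            small(**kw)

    def test_wavelength_grid_even_and_increasing(self):
        wl = small(n_bands=228).wavelengths
        assert len(wl) == 228
        steps = np.diff(wl)
        assert np.all(steps > 0) and np.allclose(steps, steps[0])


class TestGenerateSpectrum:
    def test_zero_effect_classes_identical_per_seed(self):
        cfg = small().null()
        a = generate_spectrum(cfg, "healthy", np.random.default_rng(5))
        b = generate_spectrum(cfg, "diseased", np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_deterministic_without_noise_and_scatter(self):
        cfg = small(spectral_noise_sd=0.0, scatter_sd=0.0, dip_scatter_sd=0.0)
        a = generate_spectrum(cfg, "diseased", np.random.default_rng(1))
        b = generate_spectrum(cfg, "diseased", np.random.default_rng(2))
        assert np.array_equal(a, b)

    def test_effect_concentrates_at_absorption_band(self):
        """Class difference peaks at the 1450 nm dip, not 100 bands away."""
        cfg = small(n_bands=228, spectral_effect_size=0.2)
        idx_dip = int(np.argmin(np.abs(cfg.wavelengths - 1450.0)))
        idx_far = idx_dip - 100
        means = {}
        for label in ("healthy", "diseased"):
            rng = np.random.default_rng(77)
            means[label] = np.mean(
                [generate_spectrum(cfg, label, rng) for _ in range(1000)], axis=0)
        diff = np.abs(means["healthy"] - means["diseased"])
        assert diff[idx_dip] > diff[idx_far]
        assert diff[idx_dip] > 0.1  # close to the injected 0.2 effect

    def test_effect_monotonicity(self):
        """Between-class spectral distance grows with the effect size."""
        dists = []
        for effect in (0.05, 0.15, 0.3):
            cfg = small(spectral_effect_size=effect)
            rng = np.random.default_rng(123)
            h = np.mean([generate_spectrum(cfg, "healthy", rng)
                         for _ in range(300)], axis=0)
            d = np.mean([generate_spectrum(cfg, "diseased", rng)
                         for _ in range(300)], axis=0)
            dists.append(np.linalg.norm(h - d))
        assert dists[0] < dists[1] < dists[2]

    def test_non_negative(self):
        cfg = small(spectral_noise_sd=0.5)
        rng = np.random.default_rng(0)
        assert np.all(generate_spectrum(cfg, "healthy", rng) >= 0.0)


class TestRawScanSet:
    def test_noiseless_round_trip_exact(self):
        cfg = small(spectral_noise_sd=0.0)
        direct = generate_spectrum(cfg, "diseased", np.random.default_rng(4))
        scans = generate_raw_scan_set(cfg, "diseased", np.random.default_rng(4))
        assert len(scans.scans) == cfg.scans_per_region
        assert np.allclose(scans.calibrated_mean(), direct, atol=1e-12)

    def test_single_scan_is_identity(self):
        cfg = small(scans_per_region=1, spectral_noise_sd=0.0)
        scans = generate_raw_scan_set(cfg, "healthy", np.random.default_rng(2))
        one = np.asarray(scans.scans[0])
        from pearfuse.acquisition import compute_reflectance
        direct = compute_reflectance(one, scans.white_reference,
                                     scans.dark_reference)
        assert np.allclose(scans.calibrated_mean(), direct)

    def test_round_trip_error_bounded_by_averaged_noise(self):
        """Residual after 5-scan averaging < 3*sd/sqrt(5) on >= 99% of bands."""
        cfg = SyntheticConfig(n_per_class=1, seed=7)
        bound = 3 * cfg.spectral_noise_sd / np.sqrt(cfg.scans_per_region)
        within = 0
        total = 0
        for i in range(100):
            truth = generate_spectrum(
                dataclasses.replace(cfg, spectral_noise_sd=0.0),
                "healthy", np.random.default_rng(1000 + i))
            scans = generate_raw_scan_set(cfg, "healthy",
                                          np.random.default_rng(1000 + i))
            err = np.abs(scans.calibrated_mean() - truth)
            within += np.sum(err < bound)
            total += err.size
        assert within / total >= 0.99


class TestGenerateImage:
    def test_zero_effect_identical_per_seed(self):
        cfg = small().null()
        a = generate_image(cfg, "healthy", np.random.default_rng(8))
        b = generate_image(cfg, "diseased", np.random.default_rng(8))
        assert np.array_equal(a, b)

    def test_png_bytes_bit_identical(self):
        cfg = small()
        imgs = []
        for _ in range(2):
            buf = io.BytesIO()
            Image.fromarray(
                generate_image(cfg, "diseased", np.random.default_rng(3))
            ).save(buf, format="PNG")
            imgs.append(buf.getvalue())
        assert imgs[0] == imgs[1]

    def test_classes_differ_in_fruit_color(self):
        """Diseased fruit is darker: lower mean channel intensity inside."""
        cfg = small(image_size_px=64)
        sums = {}
        for label in ("healthy", "diseased"):
            rng = np.random.default_rng(21)
            acc = []
            for _ in range(200):
                img = generate_image(cfg, label, rng).astype(float)
                interior = img[24:40, 24:40]  # center of the fruit
                acc.append(interior.mean(axis=(0, 1)))
            sums[label] = np.mean(acc, axis=0)
        # the colour shift lowers green strongly and blue visibly
        assert sums["diseased"][1] < sums["healthy"][1] - 5.0
        assert sums["diseased"][2] < sums["healthy"][2]

    def test_uint8_rgb_shape(self):
        img = generate_image(small(), "healthy", np.random.default_rng(0))
        assert img.shape == (48, 48, 3) and img.dtype == np.uint8


class TestPairedDataset:
    def test_study_scale_counts(self):
        cfg = SyntheticConfig(n_per_class=240, image_size_px=16, n_bands=4)
        # counts only; tiny images keep this cheap
        ds = generate_paired_dataset(cfg)
        assert len(ds) == 480
        assert np.sum(ds.labels == "diseased") == 240
        assert np.sum(ds.labels == "healthy") == 240

    def test_minimal_dataset(self):
        ds = generate_paired_dataset(small(n_per_class=1))
        assert len(ds) == 2 and set(ds.labels) == {"healthy", "diseased"}

    def test_manifest_balanced_and_unique(self, tiny_dataset):
        man = tiny_dataset.manifest()
        assert man["label"].value_counts().nunique() == 1
        assert man["sample_id"].is_unique

    def test_bit_identical_across_runs(self):
        cfg = small()
        a = generate_paired_dataset(cfg)
        b = generate_paired_dataset(cfg)
        assert np.array_equal(a.spectra, b.spectra)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.sample_ids, b.sample_ids)

    def test_save_load_round_trip(self, tmp_path):
        from pearfuse.synthetic_data import PairedDataset

        ds = generate_paired_dataset(small(n_per_class=2), tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        back = PairedDataset.load(tmp_path)
        assert np.array_equal(back.images, ds.images)  # PNG is lossless
        assert np.allclose(back.spectra, ds.spectra, atol=1e-7)
        assert list(back.labels) == list(ds.labels)
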