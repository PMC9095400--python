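"""Phantom generation and the a + e = b noise decomposition."""

import numpy as np
import pytest
from scipy import stats

from usdenoise import (GrayImage, NoiseSpec, NoisySample, PhantomSpec,
                       add_noise, generate_phantom, make_dataset)
from usdenoise.phantom import _ellipse_mask


class TestGeneratePhantom:
    def test_deterministic_for_fixed_seed(self):
        spec = PhantomSpec(seed=42)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_output_quantized_8bit(self):
        img = generate_phantom(PhantomSpec(seed=1))
        assert img.quantized
        assert img.pixels.min() >= 0 and img.pixels.max() <= 255
        assert np.array_equal(img.pixels, np.rint(img.pixels))

    def test_cyst_darker_than_background(self):
        spec = PhantomSpec(seed=2)
        img = generate_phantom(spec)
        mask = _ellipse_mask(spec.size, spec.center, spec.cyst_semiaxes)
        assert img.pixels[mask].mean() < img.pixels[~mask].mean()

    def test_interior_exterior_means_near_spec(self):
        spec = PhantomSpec(size=(64, 64), cyst_mean=40.0,
                           background_mean=160.0, n_spots=0, seed=9)
        img = generate_phantom(spec)
        mask = _ellipse_mask(spec.size, spec.center, spec.cyst_semiaxes)
        assert abs(img.pixels[mask].mean() - 40.0) <= 10.0
        assert abs(img.pixels[~mask].mean() - 160.0) <= 10.0

    def test_no_spots_means_no_bright_interior(self):
        spec = PhantomSpec(n_spots=0, seed=4)
        img = generate_phantom(spec)
        mask = _ellipse_mask(spec.size, spec.center, spec.cyst_semiaxes)
        assert img.pixels[mask].max() <= spec.cyst_mean + 3 * spec.texture_sd

    @pytest.mark.parametrize("bad", [
        dict(size=(0, 64)),
        dict(size=(64, -1)),
        dict(cyst_center=(2.0, 32.0)),                  # ellipse pokes out
        dict(cyst_semiaxes=(40.0, 14.0)),
        dict(cyst_mean=200.0, background_mean=100.0),   # not hypoechoic
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomSpec(**bad)


class TestAddNoise:
    def test_zero_sigma_is_identity(self, phantom):
        s = add_noise(phantom, NoiseSpec(sigma=0.0, seed=1))
        assert np.array_equal(s.noisy.pixels, s.clean.pixels)
        assert not s.noise.any()

    @pytest.mark.parametrize("model", ["additive_gaussian",
                                       "multiplicative_speckle"])
    def test_conservation_identity(self, phantom, model):
        s = add_noise(phantom, NoiseSpec(model=model, sigma=2.5, seed=3))
        err = np.abs(s.noisy.pixels + s.noise - s.clean.pixels)
        assert err.max() <= np.finfo(np.float64).eps * 255

    def test_noisy_clipped_to_range(self, phantom):
        s = add_noise(phantom, NoiseSpec(sigma=2.5, seed=3))
        assert s.noisy.pixels.min() >= 0 and s.noisy.pixels.max() <= 255

    def test_additive_sigma_measured_on_constant_image(self):
        # sigma = 1.0 maps to 25.5 pixel units on an 8-bit constant image
        const = GrayImage(np.full((256, 256), 128.0)).quantize()
        s = add_noise(const, NoiseSpec(model="additive_gaussian",
                                       sigma=1.0, seed=11))
        assert 24.5 <= s.noise.std(ddof=1) <= 26.5

    def test_additive_noise_is_gaussian_ks(self):
        const = GrayImage(np.full((256, 256), 128.0)).quantize()
        s = add_noise(const, NoiseSpec(model="additive_gaussian",
                                       sigma=1.0, seed=13))
        stat, p = stats.kstest(s.noise.ravel() / 25.5, "norm")
        assert p > 0.01

    def test_deterministic(self, phantom):
        spec = NoiseSpec(sigma=1.5, seed=8)
        a = add_noise(phantom, spec)
        b = add_noise(phantom, spec)
        assert np.array_equal(a.noisy.pixels, b.noisy.pixels)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(sigma=-0.1)

    def test_sample_invariant_enforced(self, phantom):
        s = add_noise(phantom, NoiseSpec(sigma=1.0, seed=2))
        with pytest.raises(ValueError):
            NoisySample(noisy=s.noisy, clean=s.clean,
                        noise=s.noise + 1.0, noise_spec=s.noise_spec)


class TestMakeDataset:
    def test_count_and_invariants(self):
        samples, tr, va = make_dataset(10, NoiseSpec(sigma=1.0), seed=0)
        assert len(samples) == 10
        for s in samples:
            err = np.abs(s.noisy.pixels + s.noise - s.clean.pixels)
            assert err.max() <= np.finfo(np.float64).eps * 255

    def test_default_split_80_20_disjoint(self):
        _, tr, va = make_dataset(10, NoiseSpec(sigma=1.0), seed=0)
        assert len(tr) == 8 and len(va) == 2
        assert not set(tr) & set(va)

    def test_same_master_seed_reproduces(self):
        a, _, _ = make_dataset(5, NoiseSpec(sigma=1.0), seed=3)
        b, _, _ = make_dataset(5, NoiseSpec(sigma=1.0), seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.noisy.pixels, y.noisy.pixels)

    def test_samples_vary_across_dataset(self):
        samples, _, _ = make_dataset(4, NoiseSpec(sigma=1.0), seed=3)
        assert not np.array_equal(samples[0].clean.pixels,
                                  samples[1].clean.pixels)

    def test_n_images_validated(self):
        with pytest.raises(ValueError):
            make_dataset(0, NoiseSpec(sigma=1.0), seed=0)
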