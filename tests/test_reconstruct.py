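"""Monte Carlo sampler, posterior estimate and BLS reconstruction."""
import numpy as np
import pytest
from scipy.special import i0

from acer import (
    CoilModel,
    NoiseScaleField,
    SamplerConfig,
    acceptance_probability,
    acer_reconstruct,
    bls_estimate,
    draw_samples,
    posterior_estimate,
)
from acer.errors import DomainError, InvalidParameterError
from acer.image import ImageRecord
from acer.reconstruct import SampleSet


def constant_field(shape, phi):
    return NoiseScaleField(phi=np.full(shape, float(phi)), base_scale=float(phi),
                           distance=np.zeros(shape))


def rician_pdf_direct(x, nu, phi):
    """Plain textbook density, no log-space tricks (oracle arithmetic)."""
    return x / phi**2 * np.exp(-(x**2 + nu**2) / (2 * phi**2)) * i0(x * nu / phi**2)


class TestAcceptanceProbability:
    def test_duplicate_neighbourhood_scores_one(self, rng):
        patch = rng.uniform(1, 50, 9)
        assert acceptance_probability(patch, patch, 3.0) == 1.0

    def test_deviation_cannot_exceed_self_likelihood(self):
        h0 = np.array([10.0, 10.0, 10.0])
        hk = np.array([10.0, 10.0, 10.0 + 3.0 * 10])
        assert acceptance_probability(hk, h0, 3.0) < 1.0

    def test_single_pixel_matches_direct_formula(self):
        # one-pixel patches evaluated with the plain density ratio
        expected = min(1.0, rician_pdf_direct(15.0, 12.0, 3.0) / rician_pdf_direct(12.0, 12.0, 3.0))
        assert acceptance_probability([15.0], [12.0], 3.0) == pytest.approx(expected, rel=1e-12)

    def test_patch_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            acceptance_probability([1.0, 2.0], [1.0], 2.0)

    def test_invalid_scale_rejected(self):
        with pytest.raises(InvalidParameterError):
            acceptance_probability([1.0], [1.0], 0.0)


class TestDrawSamples:
    def test_constant_image_accepts_every_draw(self):
        img = np.full((24, 24), 7.0)
        cfg = SamplerConfig(patch_radius=1, search_radius=5, n_accept=16, max_draws=64, seed=0)
        ss = draw_samples(img, (12, 12), constant_field(img.shape, 2.0), cfg)
        assert len(ss.weights) == cfg.n_accept
        assert np.all(ss.weights == 1.0)

    def test_n_accept_one_returns_center_only(self, rng):
        img = rng.uniform(1, 10, (16, 16))
        cfg = SamplerConfig(patch_radius=1, search_radius=4, n_accept=1, max_draws=8, seed=3)
        ss = draw_samples(img, (8, 8), constant_field(img.shape, 1.0), cfg)
        assert ss.locations.tolist() == [[8, 8]]
        assert ss.weights.tolist() == [1.0]

    def test_seeded_runs_are_identical(self, rng):
        img = rng.uniform(0, 40, (32, 32))
        cfg = SamplerConfig(seed=11)
        field = constant_field(img.shape, 5.0)
        a = draw_samples(img, (16, 16), field, cfg)
        b = draw_samples(img, (16, 16), field, cfg)
        np.testing.assert_array_equal(a.locations, b.locations)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_corner_pixel_uses_mirror_padding(self, rng):
        img = rng.uniform(1, 20, (16, 16))
        cfg = SamplerConfig(patch_radius=2, search_radius=4, n_accept=8, max_draws=32, seed=5)
        ss = draw_samples(img, (0, 0), constant_field(img.shape, 50.0), cfg)
        assert ss.locations[0].tolist() == [0, 0]
        assert np.all(ss.weights > 0)

    def test_out_of_image_center_rejected(self):
        with pytest.raises(DomainError):
            draw_samples(np.ones((8, 8)), (9, 0), constant_field((8, 8), 1.0),
                         SamplerConfig(patch_radius=1, search_radius=2, n_accept=4, max_draws=4))

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidParameterError):
            SamplerConfig(patch_radius=3, search_radius=3)
        with pytest.raises(InvalidParameterError):
            SamplerConfig(n_accept=0)
        with pytest.raises(InvalidParameterError):
            SamplerConfig(n_accept=64, max_draws=32)


class TestPosteriorAndBls:
    def test_single_sample_degenerate_posterior(self):
        ss = SampleSet(center=(0, 0), locations=[[0, 0]], weights=[1.0], values=[42.0])
        post = posterior_estimate(ss)
        assert post.normalizer == 1.0
        assert bls_estimate(post) == 42.0

    def test_symmetric_masses(self):
        ss = SampleSet(center=(0, 0), locations=[[0, 0], [0, 1]],
                       weights=[0.5, 0.5], values=[10.0, 20.0])
        post = posterior_estimate(ss)
        np.testing.assert_allclose(post.masses, [0.5, 0.5])
        assert post.normalizer == pytest.approx(1.0)
        assert bls_estimate(post) == pytest.approx(15.0)

    def test_hand_normalization(self):
        ss = SampleSet(center=(0, 0), locations=[[0, 0], [0, 1]],
                       weights=[0.2, 0.6], values=[10.0, 20.0])
        post = posterior_estimate(ss)
        np.testing.assert_allclose(post.masses, [0.25, 0.75])
        assert bls_estimate(post) == pytest.approx(17.5)

    def test_mean_is_convex_combination(self, rng):
        vals = rng.uniform(0, 100, 12)
        ss = SampleSet(center=(0, 0), locations=[[0, i] for i in range(12)],
                       weights=rng.uniform(0.01, 1.0, 12), values=vals)
        est = bls_estimate(posterior_estimate(ss))
        assert vals.min() <= est <= vals.max()

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(InvalidParameterError):
            SampleSet(center=(0, 0), locations=[[0, 0]], weights=[0.0], values=[1.0])


class TestReconstruct:
    def test_constant_image_is_a_fixed_point(self):
        img = ImageRecord(np.full((28, 28), 9.0), spacing=(1.0, 1.0))
        cfg = SamplerConfig(patch_radius=1, search_radius=4, n_accept=8, max_draws=32, seed=1)
        out = acer_reconstruct(img, CoilModel(), cfg,
                               scale_field=constant_field(img.shape, 2.0))
        np.testing.assert_allclose(out.data, 9.0)

    def test_range_preservation_and_determinism(self, phantom_bundle):
        b = phantom_bundle
        crop = ImageRecord(b["cor"].data[:48, 40:88], spacing=b["cor"].spacing)
        cfg = SamplerConfig(patch_radius=1, search_radius=5, n_accept=16, max_draws=64, seed=9)
        field = constant_field(crop.shape, 8.0)
        out1 = acer_reconstruct(crop, b["coil"], cfg, scale_field=field)
        out2 = acer_reconstruct(crop, b["coil"], cfg, scale_field=field)
        np.testing.assert_array_equal(out1.data, out2.data)
        assert out1.data.min() >= crop.data.min() - 1e-12
        assert out1.data.max() <= crop.data.max() + 1e-12
        out3 = acer_reconstruct(crop, b["coil"],
                                SamplerConfig(patch_radius=1, search_radius=5, n_accept=16,
                                              max_draws=64, seed=10),
                                scale_field=field)
        assert not np.array_equal(out1.data, out3.data)

    def test_exhaustive_forced_sampling_matches_brute_force(self, rng):
        """With the search window covering the image and acceptance forced,
        the reconstruction must equal the direct weighted mean over all
        pixels computed without the accept/reject machinery."""
        img = rng.uniform(1.0, 20.0, (8, 8))
        phi = 2.5
        cfg = SamplerConfig(patch_radius=1, search_radius=8, n_accept=64, max_draws=64, seed=2)
        out = acer_reconstruct(img, CoilModel(), cfg,
                               scale_field=constant_field(img.shape, phi),
                               force_accept=True)

        padded = np.pad(img, 1, mode="reflect")
        patches = np.array([[padded[r:r + 3, c:c + 3].ravel() for c in range(8)]
                            for r in range(8)])
        expected = np.empty_like(img)
        for r in range(8):
            for c in range(8):
                h0 = patches[r, c]
                num = 0.0
                den = 0.0
                for rr in range(8):
                    for cc in range(8):
                        hk = patches[rr, cc]
                        alpha = min(1.0, np.prod(rician_pdf_direct(hk, h0, phi))
                                    / np.prod(rician_pdf_direct(h0, h0, phi)))
                        num += alpha * img[rr, cc]
                        den += alpha
                expected[r, c] = num / den
        np.testing.assert_allclose(out.data, expected, atol=1e-10)
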