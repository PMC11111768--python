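"""Clipping, robust z-scoring, bias correction, affine registration."""

import numpy as np
import pytest

from neuroquant.core import Volume
from neuroquant.phantom import PhantomSpec, make_template, render_phantom
from neuroquant.preprocess import (
    AffineTransform,
    NormalizationParams,
    clip_percentiles,
    correct_bias,
    preprocess_pipeline,
    register_affine,
    robust_zscore,
)


def _vol(data):
    return Volume(data=np.asarray(data, np.float32).reshape(10, 10, 10), affine=np.eye(4))


class TestClip:
    def test_constant_volume_unchanged(self):
        vol = _vol(np.full(1000, 7.0))
        np.testing.assert_array_equal(clip_percentiles(vol).data, vol.data)

    def test_order_statistics_oracle(self):
        values = np.arange(1.0, 1001.0)
        rng = np.random.default_rng(3)
        vol = _vol(rng.permutation(values))
        out = clip_percentiles(vol)
        # independent percentile computation
        lo, hi = np.percentile(values, [1, 99])
        assert out.data.min() == pytest.approx(lo)
        assert out.data.max() == pytest.approx(hi)

    def test_outlier_suppressed(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal(1000)
        data[17] = 1e6
        out = clip_percentiles(_vol(data))
        assert out.data.max() <= np.percentile(data, 99) + 1e-5

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            clip_percentiles(_vol(np.full(1000, np.nan)))


class TestRobustZscore:
    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, 1.0, 1000)
        a = robust_zscore(_vol(x)).data
        b = robust_zscore(_vol(3.7 * x + 11.0)).data
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_median_above_floor_is_zero(self):
        rng = np.random.default_rng(2)
        out = robust_zscore(_vol(rng.standard_normal(1000)))
        p10 = np.percentile(out.data, 10)
        assert np.median(out.data[out.data > p10]) == pytest.approx(0.0, abs=1e-7)

    def test_hand_computed_oracle(self):
        values = np.arange(100.0)
        vol = Volume(data=values.reshape(4, 5, 5), affine=np.eye(4))
        out = robust_zscore(vol)
        p10, p90 = np.percentile(values, [10, 90])
        above = values[values > p10]
        m = np.median(above)
        s = np.std(above[above <= p90])
        np.testing.assert_allclose(out.data.ravel(), (values - m) / s, rtol=1e-6)

    def test_constant_band_rejected(self):
        data = np.ones(1000)
        data[:100] = 0.0  # above-floor set exists but is constant
        with pytest.raises(ValueError, match="scale"):
            robust_zscore(_vol(data))


class TestBiasCorrection:
    def test_bias_free_phantom_unchanged(self):
        vol, tissue, _ = render_phantom(PhantomSpec(noise_sd=0.0, bias_amplitude=0.0))
        out = correct_bias(vol, tissue.labels > 0)
        brain = tissue.labels > 0
        rel = np.abs(out.data[brain] - vol.data[brain]) / np.abs(vol.data[brain])
        assert rel.max() < 0.01

    def test_known_bias_reduces_wm_cov(self):
        spec = PhantomSpec(noise_sd=0.0, bias_amplitude=0.2, seed=4)
        vol, tissue, _ = render_phantom(spec)
        out = correct_bias(vol, tissue.labels > 0)
        wm = tissue.labels == 1
        cov_before = vol.data[wm].std() / vol.data[wm].mean()
        cov_after = out.data[wm].std() / out.data[wm].mean()
        assert cov_after < cov_before

    def test_maskless_whole_volume_fit(self):
        vol, _, _ = render_phantom(PhantomSpec.small(48, noise_sd=0.0, bias_amplitude=0.1))
        out = correct_bias(vol, mask=None)
        assert out.shape == vol.shape


class TestRegistration:
    def test_self_registration_is_identity(self):
        tpl = make_template(96)
        xfm = register_affine(tpl, tpl)
        assert np.abs(xfm.matrix[:3, 3]).max() < 0.1
        rot = xfm.matrix[:3, :3]
        assert abs(xfm.determinant - 1.0) < 0.01
        # off-diagonal terms bounded by ~0.1 degree rotation equivalents
        assert np.abs(rot - np.diag(np.diag(rot))).max() < 2e-3

    def test_translation_recovery(self):
        tpl = make_template(96)
        T = np.eye(4)
        T[:3, 3] = [4.0, -3.0, 2.0]
        vol, _, _ = render_phantom(PhantomSpec(noise_sd=0.0, bias_amplitude=0.0),
                                   anatomy_transform=T)
        xfm = register_affine(vol, tpl)
        # moving->template must undo the +[4,-3,2] anatomy shift
        np.testing.assert_allclose(xfm.matrix[:3, 3], [-4.0, 3.0, -2.0], atol=0.5)

    def test_uniform_scale_determinant(self):
        tpl = make_template(96)
        S = np.diag([1.2, 1.2, 1.2, 1.0])
        vol, _, _ = render_phantom(PhantomSpec(noise_sd=0.0, bias_amplitude=0.0),
                                   anatomy_transform=S)
        xfm = register_affine(vol, tpl)
        target = 1.2**-3
        assert abs(xfm.determinant - target) / target < 0.05

    def test_rigid_and_scale_recovery_over_seeds(self):
        # moments+NCC must recover mixed simulated transforms
        tpl = make_template(64)
        rng = np.random.default_rng(0)
        for _ in range(3):
            s = rng.uniform(0.9, 1.1)
            T = np.diag([s, s, s, 1.0])
            T[:3, 3] = rng.uniform(-3, 3, 3)
            vol, _, _ = render_phantom(
                PhantomSpec.small(64, noise_sd=0.0, bias_amplitude=0.0),
                anatomy_transform=T,
            )
            xfm = register_affine(vol, tpl)
            target_det = s**-3
            assert abs(xfm.determinant - target_det) / target_det < 0.05

    def test_zero_determinant_transform_rejected(self):
        with pytest.raises(ValueError, match="determinant"):
            AffineTransform(matrix=np.zeros((4, 4)))


class TestPipeline:
    def test_output_on_template_grid_and_deterministic(self):
        tpl = make_template(64)
        vol, _, _ = render_phantom(PhantomSpec.small(64, seed=8))
        out1, xfm1 = preprocess_pipeline(vol, tpl)
        out2, xfm2 = preprocess_pipeline(vol, tpl)
        assert out1.shape == tpl.shape
        np.testing.assert_array_equal(out1.data, out2.data)
        np.testing.assert_array_equal(xfm1.matrix, xfm2.matrix)

    def test_normalized_output_median_zero(self):
        tpl = make_template(64)
        vol, _, _ = render_phantom(PhantomSpec.small(64, seed=9))
        out, _ = preprocess_pipeline(vol, tpl, register=False)
        p10 = np.percentile(out.data, 10)
        assert np.median(out.data[out.data > p10]) == pytest.approx(0.0, abs=1e-6)
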