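import numpy as np
import pytest

from cutsct.hu_codec import partition_edges
from cutsct.inference_metrics import (
    CapabilityError, FoldSummary, SSIMParams, aggregate_folds, evaluate_volume,
    feature_extractor, fid, mae, rmse, ssim, translate_volume, volume_fid,
)
from cutsct.datasets import PELVIC_CV_RESULTS, PELVIC_CV_SUMMARY
from cutsct.preprocess import BodyMask, DegenerateInputError, extract_body_mask, apply_mask
from cutsct.volume_io import CTVolume, clip_hu


def _vol(arr):
    return CTVolume(np.asarray(arr, np.float32))


def _full_mask(shape):
    return BodyMask(np.ones(shape, np.uint8))


class TestMAERMSE:
    def test_identity_zero(self, rng):
        v = _vol(rng.normal(size=(4, 4, 2)))
        m = _full_mask(v.shape)
        assert mae(v, v, m) == 0.0
        assert rmse(v, v, m) == 0.0

    def test_hand_arithmetic(self):
        a = _vol([[[0.0, 10.0]]])
        b = _vol([[[2.0, 6.0]]])
        m = _full_mask((1, 1, 2))
        assert mae(a, b, m) == pytest.approx(3.0)
        assert rmse(a, b, m) == pytest.approx(np.sqrt(10.0))

    def test_constant_offset(self, rng):
        v = _vol(rng.normal(size=(4, 4, 2)))
        w = _vol(v.voxels - 17.0)
        assert mae(v, w, _full_mask(v.shape)) == pytest.approx(17.0, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_mae_le_rmse(self, seed):
        rng = np.random.default_rng(seed)
        a = _vol(rng.normal(0, 300, (6, 6, 3)))
        b = _vol(rng.normal(0, 300, (6, 6, 3)))
        m = _full_mask(a.shape)
        assert mae(a, b, m) <= rmse(a, b, m) + 1e-9

    def test_empty_mask_rejected(self, rng):
        v = _vol(rng.normal(size=(3, 3, 2)))
        with pytest.raises(DegenerateInputError):
            mae(v, v, BodyMask(np.zeros(v.shape, np.uint8)))

    def test_mask_restricts_support(self):
        a = _vol(np.zeros((2, 2, 1)))
        b = _vol([[[100.0], [0.0]], [[0.0], [0.0]]])
        m = BodyMask(np.array([[[0], [1]], [[1], [1]]], np.uint8))
        assert mae(a, b, m) == 0.0


class TestSSIM:
    def test_identity_is_one(self, rng):
        v = _vol(rng.normal(0, 200, (5, 5, 2)))
        assert ssim(v, v, _full_mask(v.shape)) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = _vol(rng.normal(0, 200, (5, 5, 2)))
        b = _vol(rng.normal(0, 200, (5, 5, 2)))
        m = _full_mask(a.shape)
        assert ssim(a, b, m) == pytest.approx(ssim(b, a, m), abs=1e-12)

    def test_direct_formula_oracle(self, rng):
        a = _vol(rng.normal(0, 200, (6, 6, 2)))
        b = _vol(rng.normal(50, 150, (6, 6, 2)))
        m = _full_mask(a.shape)
        p = SSIMParams()
        x, y = a.voxels.astype(np.float64).ravel(), b.voxels.astype(np.float64).ravel()
        mx, my = x.mean(), y.mean()
        cov = np.mean((x - mx) * (y - my))
        expect = ((2 * mx * my + p.c1) * (2 * cov + p.c2)) / (
            (mx**2 + my**2 + p.c1) * (x.var() + y.var() + p.c2))
        assert ssim(a, b, m, p) == pytest.approx(expect, abs=1e-12)

    def test_scaled_signal_below_one(self, rng):
        x = rng.normal(0, 400, (6, 6, 2))
        a, b = _vol(x), _vol(2 * x)
        val = ssim(a, b, _full_mask(a.shape))
        assert val < 1.0

    def test_singleton_mask_rejected(self, rng):
        v = _vol(rng.normal(size=(3, 3, 1)))
        m = np.zeros(v.shape, np.uint8)
        m[0, 0, 0] = 1
        with pytest.raises(DegenerateInputError):
            ssim(v, v, BodyMask(m))


class TestFID:
    def test_identical_sets_zero(self, rng):
        f = rng.normal(size=(40, 5))
        assert fid(f, f) == pytest.approx(0.0, abs=1e-8)

    def test_one_dimensional_closed_form(self, rng):
        a = rng.normal(2.0, 1.5, size=(4000, 1))
        b = rng.normal(-1.0, 0.5, size=(4000, 1))
        mu1, mu2 = a.mean(), b.mean()
        s1, s2 = a.std(ddof=1), b.std(ddof=1)
        expect = (mu1 - mu2) ** 2 + (s1 - s2) ** 2
        assert fid(a, b) == pytest.approx(expect, rel=1e-9)

    def test_symmetry(self, rng):
        a = rng.normal(size=(30, 4))
        b = rng.normal(1.0, 2.0, size=(25, 4))
        assert fid(a, b) == pytest.approx(fid(b, a), rel=1e-8)

    def test_matches_matrix_square_root_oracle(self, rng):
        from scipy.linalg import sqrtm

        a = rng.normal(size=(60, 3)) @ rng.normal(size=(3, 3))
        b = rng.normal(size=(50, 3)) + 1.0
        mu_a, mu_b = a.mean(0), b.mean(0)
        sa, sb = np.cov(a, rowvar=False), np.cov(b, rowvar=False)
        covmean = sqrtm(sa @ sb)
        expect = np.sum((mu_a - mu_b) ** 2) + np.trace(sa + sb - 2 * np.real(covmean))
        assert fid(a, b) == pytest.approx(expect, abs=1e-6)

    def test_too_few_vectors(self, rng):
        with pytest.raises(DegenerateInputError):
            fid(rng.normal(size=(1, 3)), rng.normal(size=(5, 3)))


class TestFeatureExtractor:
    def test_deterministic(self, rng):
        imgs = [rng.normal(size=(32, 32)) for _ in range(3)]
        f1 = feature_extractor(imgs, seed=7)
        f2 = feature_extractor(imgs, seed=7)
        np.testing.assert_array_equal(f1, f2)

    def test_output_width(self, rng):
        f = feature_extractor([rng.normal(size=(20, 20))] * 2, out_dim=12)
        assert f.shape == (2, 12)

    def test_inception_backend_capability_error(self, rng):
        with pytest.raises(CapabilityError, match="fixed-projection"):
            feature_extractor([rng.normal(size=(8, 8))], backend="inception-imagenet")

    def test_volume_fid_smoke(self, phantom):
        vol, _ = phantom
        mask = extract_body_mask(vol)
        assert volume_fid(vol, vol, mask, mask) == pytest.approx(0.0, abs=1e-6)


class _IdentityGenerator:
    """Stub translator that returns its input unchanged."""

    def eval(self):
        return self

    def __call__(self, x):
        return x


class TestTranslateVolume:
    def test_identity_generator_within_codec_bound(self, phantom):
        vol, _ = phantom
        mask = extract_body_mask(vol)
        masked = apply_mask(clip_hu(vol), mask)
        out = translate_volume(masked, _IdentityGenerator(), mask)
        assert out.shape == masked.shape
        inside = mask.voxels.astype(bool)
        assert np.abs(out.voxels[inside] - masked.voxels[inside]).max() <= 2.7

    def test_outside_mask_is_air(self, phantom):
        vol, _ = phantom
        mask = extract_body_mask(vol)
        out = translate_volume(apply_mask(vol, mask), _IdentityGenerator(), mask)
        assert (out.voxels[~mask.voxels.astype(bool)] == -1024.0).all()

    def test_grid_mismatch_rejected(self, phantom, small_phantom):
        vol, _ = phantom
        other, _ = small_phantom
        with pytest.raises(ValueError):
            translate_volume(vol, _IdentityGenerator(), extract_body_mask(other))

    def test_report_invariant(self, phantom):
        vol, _ = phantom
        mask = extract_body_mask(vol)
        rep = evaluate_volume(vol, vol, mask)
        assert rep.mae_hu == 0.0 and rep.ssim == pytest.approx(1.0)
        assert rep.n_voxels == mask.n_foreground


class TestAggregateFolds:
    def test_reproduces_published_summary_cells(self):
        for metric, methods in PELVIC_CV_RESULTS.items():
            for method, folds in methods.items():
                mean, se = PELVIC_CV_SUMMARY[metric][method]
                s = aggregate_folds(folds)
                assert round(s.mean, 2) == pytest.approx(mean, abs=5e-3), (metric, method)
                assert round(s.se, 2) == pytest.approx(se, abs=5e-3), (metric, method)

    def test_identical_values_zero_se(self):
        s = aggregate_folds([4.0, 4.0, 4.0])
        assert s.mean == 4.0 and s.se == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(DegenerateInputError):
            aggregate_folds([1.0])
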