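import numpy as np
import pytest

from cutsct.phantom_sim import LABELS
from cutsct.preprocess import (
    BodyMask, DegenerateInputError, apply_mask, extract_body_mask, otsu_threshold,
)
from cutsct.volume_io import CTVolume


def brute_force_otsu(values: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Independent oracle: scan every interior bin edge, maximize w0*w1*(mu0-mu1)^2."""
    values = np.asarray(values, dtype=np.float64)
    hist, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    cand = []
    for k in range(1, n_bins):
        w0, w1 = p[:k].sum(), p[k:].sum()
        if w0 == 0 or w1 == 0:
            cand.append(-np.inf)
            continue
        mu0 = (p[:k] * centers[:k]).sum() / w0
        mu1 = (p[k:] * centers[k:]).sum() / w1
        cand.append(w0 * w1 * (mu0 - mu1) ** 2)
    cand = np.asarray(cand)
    vmax = cand.max()
    # smallest edge among numerically tied maxima (float summation-order noise)
    k = int(np.argmax(cand >= vmax - 1e-12 * abs(vmax)))
    return float(edges[k + 1]), float(cand[k])


class TestOtsu:
    def test_two_group_separation(self):
        vals = np.r_[np.full(50, -1000.0), np.zeros(50)]
        res = otsu_threshold(vals, 256)
        assert -1000.0 < res.threshold <= 0.0
        assert (vals[vals < res.threshold] == -1000.0).all()
        assert (vals[vals >= res.threshold] == 0.0).all()

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full(10, 5.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.r_[rng.normal(-800, 120, 300), rng.normal(100, 200, 200)]
        res = otsu_threshold(vals, 128)
        t, v = brute_force_otsu(vals, 128)
        assert res.threshold == pytest.approx(t, abs=1e-9)
        assert res.between_class_variance == pytest.approx(v, rel=1e-9)

    def test_agrees_with_skimage_on_bimodal_data(self, rng):
        # independent library cross-check (bin conventions differ slightly,
        # so agreement is to one bin width)
        skfilters = pytest.importorskip("skimage.filters")
        vals = np.r_[rng.normal(-900, 60, 500), rng.normal(50, 90, 500)]
        ours = otsu_threshold(vals, 256).threshold
        theirs = skfilters.threshold_otsu(vals, nbins=256)
        bin_w = (vals.max() - vals.min()) / 256
        assert abs(ours - theirs) <= bin_w

    def test_threshold_within_range(self, rng):
        vals = rng.uniform(-500, 1500, 1000)
        res = otsu_threshold(vals)
        assert vals.min() <= res.threshold <= vals.max()
        assert res.between_class_variance >= 0


def _couch_phantom() -> tuple[CTVolume, np.ndarray]:
    """Tissue ellipsoid on air plus a detached couch slab; returns (vol, body label)."""
    grid = np.full((40, 40, 8), -1000.0, dtype=np.float32)
    xx, yy = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
    body = ((xx - 20) / 12.0) ** 2 + ((yy - 16) / 10.0) ** 2 <= 1.0
    grid[body] = 40.0
    grid[8:32, 32:35, :] = 200.0  # couch, separated by air rows 26..31
    return CTVolume(grid), body


class TestBodyMask:
    def test_couch_excluded(self):
        vol, body = _couch_phantom()
        mask = extract_body_mask(vol)
        expected = np.broadcast_to(body[:, :, None], vol.shape)
        np.testing.assert_array_equal(mask.voxels.astype(bool), expected)

    def test_all_air_rejected(self):
        with pytest.raises(DegenerateInputError):
            extract_body_mask(CTVolume(np.full((10, 10, 4), -1000.0)))

    def test_cavity_filled(self):
        vol, body = _couch_phantom()
        vox = vol.voxels.copy()
        cavity = np.zeros_like(vox, dtype=bool)
        cavity[18:23, 14:19, :] = True
        vox[cavity] = -1000.0  # interior gas pocket
        mask = extract_body_mask(CTVolume(vox))
        assert mask.voxels[cavity].all()

    def test_idempotent_on_masked_volume(self):
        vol, _ = _couch_phantom()
        mask = extract_body_mask(vol)
        masked = apply_mask(vol, mask)
        mask2 = extract_body_mask(masked)
        np.testing.assert_array_equal(mask.voxels, mask2.voxels)

    def test_phantom_body_without_couch(self, phantom):
        vol, labels = phantom
        mask = extract_body_mask(vol)
        assert not mask.voxels[labels == LABELS["couch"]].any()
        assert mask.voxels[labels == LABELS["muscle"]].all()
        assert mask.voxels[labels == LABELS["bladder"]].all()


class TestApplyMask:
    def test_all_ones_identity(self, small_phantom):
        vol, _ = small_phantom
        mask = BodyMask(np.ones(vol.shape, np.uint8))
        np.testing.assert_array_equal(apply_mask(vol, mask).voxels, vol.voxels)

    def test_all_zeros_fill(self, small_phantom):
        vol, _ = small_phantom
        mask = BodyMask(np.zeros(vol.shape, np.uint8))
        assert (apply_mask(vol, mask).voxels == -1024.0).all()

    def test_couch_voxels_filled(self):
        vol, body = _couch_phantom()
        out = apply_mask(vol, extract_body_mask(vol))
        couch = vol.voxels == 200.0
        assert (out.voxels[couch] == -1024.0).all()
        assert (out.voxels[body] == vol.voxels[body]).all()

    def test_shape_mismatch(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(ValueError):
            apply_mask(vol, BodyMask(np.ones((2, 2, 2), np.uint8)))

    def test_mask_values_validated(self):
        with pytest.raises(ValueError):
            BodyMask(np.full((2, 2, 2), 3, np.uint8))
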