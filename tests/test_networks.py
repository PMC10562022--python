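import numpy as np
import pytest

from cutsct.networks import (
    DiscriminatorSpec, GeneratorSpec, ProjectorSpec,
    build_discriminator, build_generator, build_projector,
    count_parameters, extract_features, projector_spec_for, sample_patches,
)
from cutsct.nn import Sequential
from cutsct.nn.autograd import Tensor


class TestParameterCounts:
    """Layer-exact parameter accounting for the pinned reference architectures."""

    def test_generator(self):
        assert count_parameters(build_generator()) == 11_378_179

    def test_discriminator(self):
        assert count_parameters(build_discriminator()) == 2_764_737

    def test_projector(self):
        assert count_parameters(build_projector()) == 560_384

    def test_contrastive_model_total(self):
        total = (count_parameters(build_generator())
                 + count_parameters(build_discriminator())
                 + count_parameters(build_projector()))
        assert total == 14_703_300

    def test_cycle_consistency_accounting(self):
        pair = count_parameters(build_generator()) + count_parameters(build_discriminator())
        assert 2 * pair == 28_285_832

    def test_single_tap_projector(self):
        assert count_parameters(build_projector(ProjectorSpec((0,), (3,), 256))) == 66_816

    def test_empty_network(self):
        assert count_parameters(Sequential()) == 0
        assert count_parameters(None) == 0


@pytest.fixture(scope="module")
def small_gen():
    return build_generator(GeneratorSpec(base_filters=8, n_resblocks=2), seed=5)


class TestGenerator:
    def test_shape_preserving(self, small_gen, rng):
        x = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        assert small_gen(x).shape == (1, 3, 32, 32)

    def test_output_bounded(self, small_gen, rng):
        y = small_gen(Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32)))
        assert np.abs(y.data).max() <= 1.0

    def test_seeded_build_determinism(self):
        spec = GeneratorSpec(base_filters=8, n_resblocks=2)
        a, b = build_generator(spec, seed=9), build_generator(spec, seed=9)
        for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            build_generator(GeneratorSpec(n_resblocks=0))


class TestDiscriminator:
    def test_patch_map_stride_arithmetic(self, rng):
        d = build_discriminator(DiscriminatorSpec(base_filters=8), seed=0)
        out = d(Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32)))
        # 64 -> 32 -> 16 -> 8 -> 7 -> 6 through strides 2,2,2,1,1 with 4x4 kernels
        assert out.shape == (1, 1, 6, 6)

    def test_constant_input_finite(self):
        d = build_discriminator(DiscriminatorSpec(base_filters=8), seed=0)
        out = d(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        assert np.isfinite(out.data).all()


class TestFeatureTaps:
    def test_tap0_is_identity(self, small_gen, rng):
        x = Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32))
        feats = extract_features(small_gen, x, (0,))
        np.testing.assert_array_equal(feats[0].data, x.data)

    def test_deeper_taps_are_coarser(self, small_gen, rng):
        x = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        feats = extract_features(small_gen, x, (0, 4, 8))
        assert feats[0].shape[2] > feats[4].shape[2] > feats[8].shape[2]

    def test_tap_dims_match_projector_spec(self, small_gen):
        spec = projector_spec_for(small_gen)
        assert spec.tap_channel_dims == (3, 16, 32, 32, 32)

    def test_deterministic(self, small_gen, rng):
        x = Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32))
        f1 = extract_features(small_gen, x, (4,))
        f2 = extract_features(small_gen, x, (4,))
        np.testing.assert_array_equal(f1[4].data, f2[4].data)

    def test_unknown_tap_rejected(self, small_gen, rng):
        x = Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32))
        with pytest.raises(ValueError):
            extract_features(small_gen, x, (0, 99))


class TestPatchSampling:
    def _feats(self, small_gen, rng):
        x = Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32))
        return extract_features(small_gen, x, (4, 8))

    def test_location_reuse(self, small_gen, rng):
        feats = self._feats(small_gen, rng)
        _, locs = sample_patches(feats, 4, seed=1)
        _, locs2 = sample_patches(feats, 4, locations=locs)
        for t in locs:
            np.testing.assert_array_equal(locs[t], locs2[t])

    def test_seed_determinism(self, small_gen, rng):
        feats = self._feats(small_gen, rng)
        _, l1 = sample_patches(feats, 4, seed=3)
        _, l2 = sample_patches(feats, 4, seed=3)
        for t in l1:
            np.testing.assert_array_equal(l1[t], l2[t])

    def test_full_grid_is_permutation(self, small_gen, rng):
        feats = self._feats(small_gen, rng)
        grid = feats[8].shape[2] * feats[8].shape[3]
        _, locs = sample_patches({8: feats[8]}, grid, seed=0)
        assert sorted(locs[8].tolist()) == list(range(grid))

    def test_too_many_patches_rejected(self, small_gen, rng):
        feats = self._feats(small_gen, rng)
        with pytest.raises(ValueError):
            sample_patches(feats, 10_000, seed=0)

    def test_patch_vectors_match_grid_values(self, small_gen, rng):
        feats = self._feats(small_gen, rng)
        patches, locs = sample_patches({4: feats[4]}, 5, seed=2)
        C, H, W = feats[4].shape[1:]
        flat = feats[4].data.reshape(C, H * W)
        np.testing.assert_array_equal(patches[4].data, flat[:, locs[4]].T)


class TestProjector:
    def test_unit_normalized_outputs(self, small_gen, rng):
        proj = build_projector(projector_spec_for(small_gen), seed=0)
        v = Tensor(rng.normal(size=(7, 16)).astype(np.float32))
        out = proj(4, v)
        np.testing.assert_allclose(np.linalg.norm(out.data, axis=1), 1.0, atol=1e-6)

    def test_unknown_tap(self, small_gen, rng):
        proj = build_projector(projector_spec_for(small_gen), seed=0)
        with pytest.raises(ValueError):
            proj(3, Tensor(np.zeros((2, 16), np.float32)))

    def test_mismatched_spec_rejected(self):
        with pytest.raises(ValueError):
            ProjectorSpec((0, 4), (3,), 256).validate()
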