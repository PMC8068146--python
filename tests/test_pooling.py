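"""Strip pooling, SPM and MPM against brute-force oracles."""

import numpy as np
import pytest

from spinet.grad import Tensor
from spinet.pooling import (
    MixedPoolingModule,
    StripPoolingModule,
    pyramid_pooling_reference_param_count,
    strip_pool,
)


def loop_strip_pool(x, direction):
    """Naive double-loop row/column means (the independent oracle)."""
    b, c, h, w = x.shape
    if direction == "horizontal":
        out = np.zeros((b, c, h))
        for i in range(h):
            for j in range(w):
                out[:, :, i] += x[:, :, i, j]
        return out / w
    out = np.zeros((b, c, w))
    for i in range(h):
        for j in range(w):
            out[:, :, j] += x[:, :, i, j]
    return out / h


class TestStripPool:
    def test_hand_computed_2x2_profiles(self):
        x = np.array([[1.0, 3.0], [2.0, 4.0]]).reshape(1, 1, 2, 2)
        np.testing.assert_allclose(strip_pool(x, "horizontal")[0, 0], [2.0, 3.0])
        np.testing.assert_allclose(strip_pool(x, "vertical")[0, 0], [1.5, 3.5])

    def test_constant_map_pools_to_the_constant(self):
        x = np.full((2, 3, 4, 5), 7.25)
        for d in ("horizontal", "vertical"):
            np.testing.assert_allclose(strip_pool(x, d), 7.25)

    def test_agrees_with_double_loop_oracle_on_random_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            shape = (rng.integers(1, 3), rng.integers(1, 4),
                     rng.integers(1, 9), rng.integers(1, 9))
            x = rng.normal(size=shape)
            for d in ("horizontal", "vertical"):
                np.testing.assert_allclose(strip_pool(x, d), loop_strip_pool(x, d),
                                           atol=1e-6)

    def test_both_directions_preserve_the_global_mean(self):
        x = np.random.default_rng(1).normal(size=(2, 3, 6, 7))
        for d in ("horizontal", "vertical"):
            np.testing.assert_allclose(strip_pool(x, d).mean(axis=-1),
                                       x.mean(axis=(2, 3)), atol=1e-12)

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            strip_pool(np.zeros((1, 1, 2, 2)), "diagonal")


class TestSPM:
    def test_output_shape_equals_input_shape(self):
        spm = StripPoolingModule(8, rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(size=(2, 8, 16, 16)))
        assert spm(x).shape == (2, 8, 16, 16)

    def test_identity_configuration_matches_loop_oracle(self):
        """With pass-through convolutions, no normalization and no gate, the
        output is x ⊙ (broadcast y^h + broadcast y^v), checked element-wise."""
        spm = StripPoolingModule(3, gate="identity", normalize=False,
                                 rng=np.random.default_rng(0))
        spm.set_identity()
        x = np.random.default_rng(2).normal(size=(1, 3, 4, 5))
        got = spm(Tensor(x)).data
        expect = np.empty_like(x)
        for c in range(3):
            yh = x[0, c].mean(axis=1)
            yv = x[0, c].mean(axis=0)
            for i in range(4):
                for j in range(5):
                    expect[0, c, i, j] = x[0, c, i, j] * (yh[i] + yv[j])
        np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_constant_input_with_identity_convs_is_spatially_constant(self):
        spm = StripPoolingModule(2, gate="identity", normalize=False,
                                 rng=np.random.default_rng(0))
        spm.set_identity()
        out = spm(Tensor(np.full((1, 2, 5, 6), 3.0))).data
        np.testing.assert_allclose(out, np.broadcast_to(out[:, :, :1, :1], out.shape), atol=1e-6)

    def test_multiplicative_fusion_flag(self):
        spm = StripPoolingModule(2, gate="identity", normalize=False, fusion="mul",
                                 rng=np.random.default_rng(0))
        spm.set_identity()
        x = np.full((1, 2, 3, 3), 2.0)
        np.testing.assert_allclose(spm(Tensor(x)).data, 2.0 * (2.0 * 2.0), atol=1e-6)

    def test_channel_mismatch_rejected(self):
        spm = StripPoolingModule(4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            spm(Tensor(np.zeros((1, 5, 4, 4))))

    def test_every_weight_receives_gradient(self):
        spm = StripPoolingModule(6, rng=np.random.default_rng(3))
        x = Tensor(np.random.default_rng(4).normal(size=(2, 6, 5, 5)), requires_grad=True)
        (spm(x) ** 2.0).sum().backward()
        for name, p in spm.named_parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name

    def test_spm_is_cheaper_than_pyramid_pooling_at_equal_channels(self):
        for c in (64, 256, 1024):
            spm = StripPoolingModule(c, rng=np.random.default_rng(0))
            assert spm.parameter_count() < pyramid_pooling_reference_param_count(c)


class TestMPM:
    @pytest.fixture()
    def mpm(self):
        return MixedPoolingModule(32, 16, gn_groups=8, rng=np.random.default_rng(0))

    def test_spatial_size_preserved(self, mpm):
        x = Tensor(np.random.default_rng(1).normal(size=(2, 32, 8, 8)))
        out = mpm(x)
        assert out.shape == (2, 16, 8, 8)

    def test_global_pool_branch_equals_global_mean(self, mpm):
        """The 1×1-grid pyramid branch reduces to the per-channel global mean
        before upsampling, matching a brute-force mean."""
        from spinet.grad import adaptive_avg_pool
        x = np.random.default_rng(2).normal(size=(2, 16, 6, 7))
        pooled = adaptive_avg_pool(Tensor(x), 1, 1).data
        np.testing.assert_allclose(pooled[:, :, 0, 0], x.mean(axis=(2, 3)), atol=1e-6)

    def test_constant_input_gives_constant_pyramid(self, mpm):
        # normalization at zero variance amplifies float noise, hence the
        # modest tolerance on spatial flatness
        reduced = Tensor(np.full((1, 16, 8, 8), 1.5))
        fused = mpm.pyramid(reduced).data
        np.testing.assert_allclose(fused, np.broadcast_to(fused[:, :, :1, :1], fused.shape),
                                   atol=1e-3)
        # without convolutions in the way, pooling + upsampling of a constant
        # is exactly constant
        from spinet.grad import adaptive_avg_pool, upsample_bilinear
        for grid in (1, 2, 3):
            y = upsample_bilinear(adaptive_avg_pool(reduced, grid, grid), 8, 8).data
            np.testing.assert_allclose(y, 1.5, atol=1e-6)

    def test_channel_mismatch_rejected(self, mpm):
        with pytest.raises(ValueError, match="channels"):
            mpm(Tensor(np.zeros((1, 12, 8, 8))))

    def test_every_weight_receives_gradient(self, mpm):
        x = Tensor(np.random.default_rng(5).normal(size=(1, 32, 8, 8)), requires_grad=True)
        (mpm(x) ** 2.0).sum().backward()
        for name, p in mpm.named_parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name
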