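"""Contract tests for the enhancement network."""

import numpy as np
import pytest

from nir2a import autodiff as ad
from nir2a import network as net
from nir2a import nn
from nir2a import phantom as pf
from nir2a.autodiff import Tensor
from nir2a.errors import DivisibilityError, ValidationError


@pytest.fixture(scope="module")
def model120():
    return net.SwinUNet(net.NetworkConfig(), (120, 120), seed=0)


def rand_image(shape, seed=0, channels_last=True):
    rng = np.random.default_rng(seed)
    return Tensor(rng.random(shape, dtype=np.float32))


class TestEncoder:
    def test_feature_ladder_shapes_120(self, model120):
        x = rand_image((2, 120, 120, 1))
        fs = model120.encode(x)
        assert fs.f1.shape == (2, 60, 60, 32)
        assert fs.f2.shape == (2, 30, 30, 64)
        assert fs.f3.shape == (2, 15, 15, 128)

    def test_feature_shapes_40(self):
        m = net.SwinUNet(net.NetworkConfig(), (40, 40), seed=1)
        fs = m.encode(rand_image((1, 40, 40, 1)))
        assert fs.f3.shape == (1, 5, 5, 128)

    def test_zero_input_zero_features_in_eval(self, model120):
        # conv biases and BN shifts are zero-initialised, so in inference
        # mode an all-zero frame propagates to an all-zero deepest feature
        m = net.SwinUNet(net.NetworkConfig(), (120, 120), seed=3)
        m.eval()
        fs = m.encode(Tensor(np.zeros((1, 120, 120, 1), np.float32)))
        assert float(np.abs(fs.f3.data).max()) == 0.0

    def test_rejects_nonfinite_and_indivisible(self, model120):
        bad = np.zeros((1, 120, 120, 1), np.float32)
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            model120.encode(Tensor(bad))
        with pytest.raises(DivisibilityError):
            model120.encode(rand_image((1, 44, 44, 1)))


class TestPatches:
    def test_counts_and_lengths(self):
        f3 = rand_image((1, 15, 15, 128))
        tokens = net.partition_patches(f3, 5)
        assert tokens.shape == (1, 9, 3200)

    def test_round_trip_exact(self):
        f3 = rand_image((2, 15, 15, 128), seed=5)
        tokens = net.partition_patches(f3, 5)
        back = net.merge_patches(tokens, (3, 3), 128, 5)
        np.testing.assert_array_equal(back.data, f3.data)

    def test_constant_map_gives_constant_vectors(self):
        f3 = Tensor(np.full((1, 10, 10, 4), 0.7, np.float32))
        tokens = net.partition_patches(f3, 5)
        np.testing.assert_allclose(tokens.data, 0.7)

    def test_indivisible_rejected(self):
        with pytest.raises(ValidationError):
            net.partition_patches(rand_image((1, 14, 15, 8)), 5)


class TestSwinBottleneck:
    def test_shape_preserved(self, model120):
        f3 = rand_image((1, 15, 15, 128), seed=2)
        out = model120.stm_forward(f3)
        assert out.shape == f3.shape

    def test_attention_rows_sum_to_one(self, model120):
        attn = []
        model120.stm_forward(rand_image((2, 15, 15, 128), seed=3),
                             collect_attn=attn)
        assert len(attn) == 3
        for a in attn:
            np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-5)

    def test_shifted_windows_mask_keeps_rows_normalized(self):
        # grid 10x10 -> window 5, the middle block shifts by 2
        m = net.SwinUNet(net.NetworkConfig(), (400, 400), seed=0)
        (wh, ww), (sh, sw) = m.blocks[1]._geometry((10, 10), m.config)
        assert (wh, ww) == (5, 5) and (sh, sw) == (2, 2)
        attn = []
        m.stm_forward(rand_image((1, 50, 50, 128), seed=1),
                      collect_attn=attn)
        for a in attn:
            np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-5)
        # masked (cross-region) attention weights are effectively zero
        mask = net._shift_mask((10, 10), (5, 5), (2, 2))
        shifted = attn[1].reshape(1, 4, -1, 25, 25)
        dead = np.broadcast_to(mask[None, :, None] < 0, shifted.shape)
        assert shifted[dead].max() < 1e-6

    def test_residual_identity_when_transform_weights_zeroed(self):
        m = net.SwinUNet(net.NetworkConfig(), (120, 120), seed=4)
        for blk in m.blocks:
            blk.proj.weight.data[:] = 0
            blk.proj.bias.data[:] = 0
            blk.fc2.weight.data[:] = 0
            blk.fc2.bias.data[:] = 0
        f3 = rand_image((1, 15, 15, 128), seed=6)
        out = m.stm_forward(f3)
        # blocks reduce to identity: output equals the pure
        # embed -> +position -> unembed -> merge path
        tokens = net.partition_patches(f3, 5)
        ref = m.unembed(m.embed(tokens) + m.pos)
        ref = net.merge_patches(ref, (3, 3), 128, 5)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-5)


class TestFullForward:
    def test_shape_conservation_and_codomain(self, model120):
        x = rand_image((1, 120, 120, 1), seed=7)
        y = model120(x)
        assert y.shape == x.shape
        assert 0.0 < y.data.min() and y.data.max() < 1.0

    def test_parameter_count_reproducible(self):
        a = net.SwinUNet(net.NetworkConfig(), (120, 120), seed=0)
        b = net.SwinUNet(net.NetworkConfig(), (120, 120), seed=0)
        assert a.n_parameters() == b.n_parameters()
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_gradient_reaches_every_parameter(self):
        m = net.SwinUNet(net.NetworkConfig(), (80, 80), seed=2)
        opt = nn.Adam(m.parameters())
        x = rand_image((2, 80, 80, 1), seed=8)
        target = np.zeros((2, 80, 80, 1), np.float32)
        loss = ad.l1_loss(m(x), target)
        opt.zero_grad()
        loss.backward()
        for name, p in m.named_parameters():
            assert p.grad is not None, name
            assert float(np.abs(p.grad).max()) > 0.0, name

    def test_embed_dim_head_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            net.NetworkConfig(embed_dim=100, n_heads=3).validate()


# sparser trees for small 80x80 frames (defaults are sized for 120x120)
SMALL_TREES = pf.BranchingConfig(n_stems=2, max_depth=6)


@pytest.fixture(scope="module")
def tiny_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("ds") / "tiny"
    return pf.generate_dataset(out, n_pairs=6, size=(80, 80), base_seed=11,
                               tree_params=SMALL_TREES,
                               split_fractions=(0.5, 0.25, 0.25))


class TestTrainingAndInference:

    def test_identity_task_training_improves_val_loss(self, tmp_path):
        # degradation disabled: nir1 == nir2a, a feasible identity mapping
        params = pf.DegradationParams(
            psf_sigma_nir1=0.6 + 1e-6, psf_sigma_nir2a=0.6,
            autofluor_amplitude=0.0, hotspot_amplitude=0.0,
            noise_gaussian_sd=0.0, noise_poisson_scale=0.0)
        man = pf.generate_dataset(tmp_path / "ident", n_pairs=6,
                                  size=(80, 80), base_seed=3, params=params,
                                  tree_params=SMALL_TREES,
                                  split_fractions=(0.5, 0.25, 0.25))
        tc = net.TrainConfig(epochs=4, batch_size=3, seed=0)
        xva, yva = net._load_split(man, "val")
        untrained = net.SwinUNet(net.NetworkConfig(), (80, 80), seed=0)
        untrained.eval()
        base = float(ad.l1_loss(untrained(Tensor(xva)), yva).data)
        result = net.train(man, net.NetworkConfig(), tc, tmp_path / "m")
        assert result.best_val_loss <= base

    def test_training_is_deterministic(self, tiny_manifest, tmp_path):
        tc = net.TrainConfig(epochs=2, batch_size=2, seed=5)
        r1 = net.train(tiny_manifest, net.NetworkConfig(), tc, tmp_path / "a")
        r2 = net.train(tiny_manifest, net.NetworkConfig(), tc, tmp_path / "b")
        assert r1.loss_log == r2.loss_log

    def test_checkpoint_round_trip_and_enhance(self, tiny_manifest,
                                               tmp_path):
        tc = net.TrainConfig(epochs=1, batch_size=2, seed=1)
        result = net.train(tiny_manifest, net.NetworkConfig(), tc,
                           tmp_path / "m")
        model = net.load_checkpoint(result.checkpoint_path)
        frame = np.random.default_rng(0).random((80, 80), dtype=np.float32)
        out1 = net.enhance(frame, model)
        out2 = net.enhance(frame, model)
        assert out1.shape == frame.shape
        np.testing.assert_array_equal(out1, out2)
        assert 0.0 < out1.min() and out1.max() < 1.0

    def test_enhance_shape_contract(self, tiny_manifest, tmp_path):
        tc = net.TrainConfig(epochs=1, batch_size=2, seed=1)
        result = net.train(tiny_manifest, net.NetworkConfig(), tc,
                           tmp_path / "m2")
        model = net.load_checkpoint(result.checkpoint_path)
        odd = np.random.default_rng(1).random((70, 90), dtype=np.float32)
        with pytest.raises(DivisibilityError, match="reflect-pad"):
            net.enhance(odd, model)
        out = net.enhance(odd, model, pad=True)
        assert out.shape == odd.shape

    def test_empty_split_rejected(self, tmp_path):
        man = pf.generate_dataset(tmp_path / "nosplit", n_pairs=3,
                                  size=(80, 80), base_seed=0,
                                  tree_params=SMALL_TREES,
                                  split_fractions=(1.0, 0.0, 0.0))
        with pytest.raises(ValidationError):
            net.train(man, net.NetworkConfig(),
                      net.TrainConfig(epochs=1))
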