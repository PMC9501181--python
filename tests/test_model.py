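"""Full-network tests: decoder blocks, assembly, prediction, checkpoints."""

import numpy as np
import pytest

from irisseg import autodiff as ad
from irisseg.autodiff import Tensor, sigmoid
from irisseg.metrics import dice_loss
from irisseg.model import (DecodeBlock, IrisSegNet, ModelConfig,
                           load_checkpoint, predict_mask, save_checkpoint)
from irisseg.nn import Adam, DimensionError
from irisseg.synthetic import SyntheticEyeSpec, generate_eye_sample


class TestDecodeBlock:
    @pytest.mark.parametrize("cin,cout,hw,out_hw", [
        (768, 384, 7, 14), (96, 48, 56, 112)])
    def test_doubles_resolution_and_projects_channels(self, cin, cout, hw,
                                                      out_hw, rng):
        blk = DecodeBlock(cin, cout, np.random.default_rng(0))
        x = Tensor(rng.random((1, cin, hw, hw), dtype=np.float32))
        with ad.no_grad():
            assert blk(x).shape == (1, cout, out_hw, out_hw)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            DecodeBlock(3, 8, np.random.default_rng(0))


class TestModelConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelConfig.from_dict({"input_size": 64, "bogus": 1})

    def test_roundtrip(self):
        cfg = ModelConfig.scaled(4, 64, random_seed=9)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg

    def test_input_size_must_align_with_the_downsampling_pyramid(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=100)


class TestIrisSegNet:
    def test_scaled_trace_matches_expected_rows(self, tiny_model, rng):
        x = rng.random((1, 3, 64, 64), dtype=np.float32)
        trace = tiny_model.shape_trace(x)
        expected = tiny_model.config.layer_shapes()
        assert trace == expected
        assert len(trace) == 22

    def test_identical_samples_in_a_batch_give_identical_outputs(
            self, tiny_model, rng):
        one = rng.random((1, 3, 64, 64), dtype=np.float32)
        tiny_model.eval()
        with ad.no_grad():
            out = tiny_model(Tensor(np.concatenate([one, one]))).data
        np.testing.assert_array_equal(out[0], out[1])

    def test_doubled_input_keeps_shapes_and_finiteness(self, tiny_model, rng):
        x = rng.random((1, 3, 64, 64), dtype=np.float32)
        tiny_model.eval()
        with ad.no_grad():
            a = tiny_model(Tensor(x))
            b = tiny_model(Tensor(2 * x))
        assert a.shape == b.shape == (1, 1, 64, 64)
        assert np.isfinite(a.data).all() and np.isfinite(b.data).all()

    def test_wrong_input_resolution_rejected(self, tiny_model):
        with pytest.raises(DimensionError):
            tiny_model(Tensor(np.zeros((1, 3, 32, 32), dtype=np.float32)))

    def test_dice_gradients_flow_to_every_parameter(self, rng):
        model = IrisSegNet(ModelConfig.scaled(8, 32, random_seed=2))
        x = Tensor(rng.random((2, 3, 32, 32), dtype=np.float32))
        gt = (rng.random((2, 1, 32, 32)) > 0.8).astype(np.float32)
        loss = dice_loss(sigmoid(model(x)), gt)
        model.zero_grad()
        loss.backward()
        total = 0.0
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
            total += float(np.abs(p.grad).sum())
        assert total > 0

    def test_spot_gradients_match_finite_differences(self, rng):
        model = IrisSegNet(ModelConfig.scaled(8, 32, random_seed=2))
        for p in model.parameters():
            p.data = p.data.astype(np.float64)
        x = rng.random((1, 3, 32, 32))
        gt = (rng.random((1, 1, 32, 32)) > 0.8).astype(np.float64)

        def loss_value():
            return float(dice_loss(sigmoid(model(Tensor(x))), gt).data)

        loss = dice_loss(sigmoid(model(Tensor(x))), gt)
        model.zero_grad()
        loss.backward()
        named = dict(model.named_parameters())
        for key in ("semantic.block1.stage1.qkv.weight",
                    "detail.fem1.dw1.dw.conv.weight",
                    "head.weight"):
            p = named[key]
            flat = p.data.reshape(-1)
            i = int(rng.integers(flat.size))
            eps = 1e-6
            old = flat[i]
            flat[i] = old + eps
            fp = loss_value()
            flat[i] = old - eps
            fm = loss_value()
            flat[i] = old
            num = (fp - fm) / (2 * eps)
            # piecewise-linear activations make the numeric derivative only
            # approximate near kinks; 1% agreement is the right bar here
            assert abs(num - p.grad.reshape(-1)[i]) < 1e-2 * max(1.0, abs(num)), key


class TestPredictMask:
    def test_saturated_logits(self):
        assert predict_mask(np.full((4, 4), 10.0)).all()
        assert not predict_mask(np.full((4, 4), -10.0)).any()

    def test_zero_logit_ties_go_to_foreground(self):
        assert predict_mask(np.zeros((2, 2)), threshold=0.5).all()

    @pytest.mark.parametrize("thr", [0.0, 1.0, -0.3, 1.5])
    def test_invalid_threshold_rejected(self, thr):
        with pytest.raises(ValueError):
            predict_mask(np.zeros((2, 2)), threshold=thr)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path, tiny_model, rng):
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        tiny_model.eval()
        with ad.no_grad():
            want = tiny_model(x).data
        save_checkpoint(tmp_path / "ck.npz", tiny_model)
        loaded = load_checkpoint(tmp_path / "ck.npz")
        loaded.eval()
        with ad.no_grad():
            got = loaded(x).data
        np.testing.assert_array_equal(got, want)
        assert loaded.config == tiny_model.config


def test_fifty_steps_on_one_image_decrease_dice_loss():
    """Trainability: the 5-step moving average of the loss trends strictly
    downward over 50 single-image gradient steps."""
    spec = SyntheticEyeSpec(modality="nir", seed=5)
    img, mask = generate_eye_sample(spec)
    from PIL import Image
    im = Image.fromarray((img * 255).astype(np.uint8)).resize((64, 64),
                                                              Image.BILINEAR)
    mk = Image.fromarray(mask * np.uint8(255)).resize((64, 64), Image.NEAREST)
    x = np.repeat(np.asarray(im, dtype=np.float32)[None] / 255.0, 3, 0)[None]
    y = (np.asarray(mk) > 127).astype(np.float32)[None, None]
    model = IrisSegNet(ModelConfig.scaled(4, 64, random_seed=0))
    opt = Adam(model.parameters(), lr=1e-3)
    losses = []
    for _ in range(50):
        loss = dice_loss(sigmoid(model(Tensor(x))), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    ma = np.convolve(losses, np.ones(5) / 5, mode="valid")
    assert ma[-1] < ma[0]
    assert np.mean(np.diff(ma) < 0) > 0.8  # overwhelmingly decreasing
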