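"""Semantic-branch tests: windowing, attention, blocks, merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irisseg import autodiff as ad
from irisseg.autodiff import Tensor
from irisseg.nn import DimensionError
from irisseg.semantic import (MASK_VALUE, PatchEmbed, PatchMerging,
                              SemanticBranch, SwinBlock, SwinBlockConfig,
                              SwinStage, shift_attention_mask,
                              window_attention, window_partition,
                              window_reverse)


def rng_tensor(rng, *shape):
    return Tensor(rng.standard_normal(shape).astype(np.float64))


# ---------------------------------------------------------------- patch embed

class TestPatchEmbed:
    def test_partition_and_embedding_shapes(self, rng):
        pe = PatchEmbed(np.random.default_rng(0))
        img = Tensor(rng.random((1, 3, 224, 224), dtype=np.float32))
        assert pe.partition(img).shape == (1, 56, 56, 48)
        assert pe(img).shape == (1, 56, 56, 96)

    def test_zero_weights_propagate_zero(self):
        pe = PatchEmbed(np.random.default_rng(0))
        for p in pe.parameters():
            p.data = np.zeros_like(p.data)
        out = pe.embed(pe.partition(Tensor(np.zeros((1, 3, 8, 8)))))
        assert out.shape == (1, 2, 2, 96)
        np.testing.assert_array_equal(out.data, 0.0)

    @pytest.mark.parametrize("h,w,axis", [(225, 224, "height"), (224, 222, "width")])
    def test_indivisible_spatial_size_is_rejected(self, h, w, axis):
        pe = PatchEmbed(np.random.default_rng(0))
        with pytest.raises(DimensionError, match=axis):
            pe(Tensor(np.zeros((1, 3, h, w))))


# ------------------------------------------------------------- window algebra

class TestWindowPartition:
    def test_window_counts(self, rng):
        ws = window_partition(rng_tensor(rng, 1, 56, 56, 96), 7, 0)
        assert ws.num_windows == 64 and ws.tokens_per_window == 49
        assert ws.tokens.shape == (64, 49, 96)
        assert ws.num_windows * ws.tokens_per_window == 56 * 56

    @pytest.mark.parametrize("h,w,m,s", [
        (8, 8, 4, 0), (8, 8, 4, 2), (14, 14, 7, 3),
        (10, 6, 4, 1),          # needs right/bottom padding
        (3, 3, 7, 0),           # full-map fallback window
    ])
    def test_reverse_is_exact_inverse(self, h, w, m, s, rng):
        x = rng_tensor(rng, 2, h, w, 5)
        ws = window_partition(x, m, s)
        back = window_reverse(ws)
        np.testing.assert_array_equal(back.data, x.data)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(h=st.integers(2, 12), w=st.integers(2, 12),
           m=st.integers(2, 8), data=st.data())
    def test_reverse_inverts_partition_for_arbitrary_geometry(self, h, w, m,
                                                              data):
        wh = min(m, h) if (h < m and w < m) else m
        shift = data.draw(st.integers(0, max(wh, 1) - 1))
        x = Tensor(np.random.default_rng(h * 100 + w * 10 + m)
                   .standard_normal((1, h, w, 3)))
        ws = window_partition(x, m, shift if not (h < m and w < m) else 0)
        np.testing.assert_array_equal(window_reverse(ws).data, x.data)

    def test_fallback_single_window_when_map_smaller_than_m(self, rng):
        ws = window_partition(rng_tensor(rng, 1, 3, 3, 4), 7, 0)
        assert ws.num_windows == 1 and ws.tokens_per_window == 9

    def test_nonpositive_window_size_rejected(self, rng):
        with pytest.raises(ValueError):
            window_partition(rng_tensor(rng, 1, 4, 4, 2), 0)

    @pytest.mark.parametrize("h,w,m,s", [(8, 8, 4, 2), (14, 14, 7, 3),
                                         (12, 12, 4, 3), (8, 12, 4, 1)])
    def test_seam_mask_matches_wrap_oracle(self, h, w, m, s):
        """A pair is forbidden iff exactly one of the two tokens was carried
        across the image border by the cyclic roll (per axis)."""
        got = shift_attention_mask(h, w, m, m, s)
        nh, nw = h // m, w // m
        want = np.zeros_like(got)
        for wi in range(nh):
            for wj in range(nw):
                toks = []
                for a in range(m):
                    for b in range(m):
                        r, c = wi * m + a, wj * m + b
                        toks.append(((r + s) >= h, (c + s) >= w))
                for i in range(m * m):
                    for j in range(m * m):
                        if toks[i] != toks[j]:
                            want[wi * nw + wj, i, j] = MASK_VALUE
        np.testing.assert_array_equal(got, want)
        # the 14x14/M=7/shift=3 case of the example: 4 windows
        if (h, w, m) == (14, 14, 7):
            ws = window_partition(Tensor(np.zeros((1, 14, 14, 2))), 7, 3)
            assert ws.num_windows == 4 and ws.attn_mask is not None


# ----------------------------------------------------------- window attention

def dense_attention_oracle(q, k, v, bias, mask):
    """Literal dense evaluation: explicit score matrix, softmax by definition."""
    t, d = q.shape
    scores = np.zeros((t, t))
    for i in range(t):
        for j in range(t):
            scores[i, j] = float(q[i] @ k[j]) / np.sqrt(d) + bias[i, j]
            if mask is not None:
                scores[i, j] += mask[i, j]
    out = np.zeros((t, d))
    for i in range(t):
        e = np.exp(scores[i] - scores[i].max())
        w = e / e.sum()
        out[i] = w @ v
    return out


class TestWindowAttention:
    def test_uniform_when_scores_are_constant(self, rng):
        v = rng_tensor(rng, 4, 3)
        zero = Tensor(np.zeros((4, 3)))
        out = window_attention(zero, zero, v)
        np.testing.assert_allclose(out.data,
                                   np.tile(v.data.mean(axis=0), (4, 1)),
                                   atol=1e-12)

    def test_single_token_window_is_identity(self, rng):
        q = rng_tensor(rng, 1, 5)
        v = rng_tensor(rng, 1, 5)
        np.testing.assert_allclose(window_attention(q, q, v).data, v.data)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DimensionError):
            window_attention(rng_tensor(rng, 4, 3), rng_tensor(rng, 4, 2),
                             rng_tensor(rng, 4, 3))

    @pytest.mark.parametrize("m,d,masked", [(2, 3, False), (2, 3, True),
                                            (3, 2, False), (4, 8, True)])
    def test_matches_dense_oracle(self, m, d, masked):
        rng = np.random.default_rng(100 * m + d + masked)
        t = m * m
        q, k, v = (rng.standard_normal((t, d)) for _ in range(3))
        bias = rng.standard_normal((t, t))
        mask = None
        if masked:
            mask = np.where(rng.random((t, t)) < 0.3, MASK_VALUE, 0.0)
            np.fill_diagonal(mask, 0.0)
        out = window_attention(Tensor(q), Tensor(k), Tensor(v),
                               bias=Tensor(bias), mask=mask)
        np.testing.assert_allclose(
            out.data, dense_attention_oracle(q, k, v, bias, mask), atol=1e-5)

    def test_forbidden_pairs_get_negligible_weight(self):
        rng = np.random.default_rng(7)
        q = Tensor(rng.standard_normal((9, 4)))
        k = Tensor(rng.standard_normal((9, 4)))
        mask = np.where(rng.random((9, 9)) < 0.4, MASK_VALUE, 0.0)
        np.fill_diagonal(mask, 0.0)
        scores = ad.matmul(q, k.transpose(1, 0)) * 0.5 + Tensor(mask)
        weights = ad.softmax(scores).data
        assert weights[mask < 0].max() < 1e-6


# ------------------------------------------------------------------ the block

class TestSwinBlock:
    def test_output_shape_preserved(self, rng):
        blk = SwinBlock(24, 3, np.random.default_rng(0), window_size=4)
        x = rng_tensor(rng, 2, 8, 8, 24)
        assert blk(x).shape == x.shape

    def test_zeroed_residual_branches_give_identity(self, rng):
        stage = SwinStage(SwinBlockConfig(4, 12, 2, 0), np.random.default_rng(0))
        stage.proj.weight.data[:] = 0
        stage.proj.bias.data[:] = 0
        stage.fc2.weight.data[:] = 0
        stage.fc2.bias.data[:] = 0
        x = rng_tensor(rng, 1, 8, 8, 12)
        np.testing.assert_allclose(stage(x).data, x.data, atol=1e-12)

    def test_stage2_shift_is_half_window(self):
        blk = SwinBlock(12, 2, np.random.default_rng(0), window_size=4)
        assert blk.stage1.cfg.shift_size == 0
        assert blk.stage2.cfg.shift_size == 2

    def test_shifted_stage_equals_unshifted_on_rolled_input(self, rng, monkeypatch):
        """Roll-equivalence: with the seam mask disabled, SW-MSA on x equals
        W-MSA on the pre-rolled map with the roll undone afterwards."""
        from irisseg import semantic as sem
        monkeypatch.setattr(sem, "shift_attention_mask",
                            lambda *a: np.zeros((1, 16, 16), dtype=np.float32))
        r = np.random.default_rng(5)
        shifted = SwinStage(SwinBlockConfig(4, 12, 2, 2), r)
        plain = SwinStage(SwinBlockConfig(4, 12, 2, 0), np.random.default_rng(0))
        plain.load_state_dict(shifted.state_dict())
        x = rng_tensor(rng, 1, 8, 8, 12)
        out_shifted = shifted(x).data
        rolled = Tensor(np.roll(x.data, (-2, -2), axis=(1, 2)))
        out_plain = np.roll(plain(rolled).data, (2, 2), axis=(1, 2))
        np.testing.assert_allclose(out_shifted, out_plain, atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        blk = SwinBlock(12, 2, np.random.default_rng(0), window_size=4)
        with pytest.raises(DimensionError):
            blk(rng_tensor(rng, 1, 8, 8, 10))


# -------------------------------------------------------------- patch merging

class TestPatchMerging:
    @pytest.mark.parametrize("h,w,c,out_hw,out_c", [
        (56, 56, 96, 28, 192), (14, 14, 384, 7, 768)])
    def test_halves_resolution_doubles_channels(self, h, w, c, out_hw, out_c):
        pm = PatchMerging(c, np.random.default_rng(0))
        x = Tensor(np.zeros((1, h, w, c), dtype=np.float32))
        assert pm(x).shape == (1, out_hw, out_hw, out_c)

    def test_constant_input_gives_constant_output(self, rng):
        pm = PatchMerging(6, np.random.default_rng(0))
        x = Tensor(np.full((1, 4, 4, 6), 1.7))
        out = pm(x).data
        np.testing.assert_allclose(out - out[:, :1, :1, :], 0.0, atol=1e-12)

    def test_odd_size_rejected(self):
        pm = PatchMerging(6, np.random.default_rng(0))
        with pytest.raises(DimensionError):
            pm(Tensor(np.zeros((1, 5, 4, 6))))


# ------------------------------------------------------------------ the branch

class TestSemanticBranch:
    def test_scaled_shape_cascade(self, rng):
        br = SemanticBranch(np.random.default_rng(0), (24, 48, 96, 192),
                            (3, 6, 12), 7, 12)
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        trace = {}
        out = br(x, trace)
        assert out.shape == (1, 192, 2, 2)
        assert trace["semantic.patch_partition"] == (16, 16, 12)
        assert trace["semantic.swin_block2"] == (8, 8, 48)
        assert trace["semantic.patch_merging3"] == (2, 2, 192)

    def test_batch_samples_are_independent(self, rng):
        br = SemanticBranch(np.random.default_rng(0), (24, 48, 96, 192),
                            (3, 6, 12), 7, 12)
        one = rng.random((1, 3, 64, 64), dtype=np.float32)
        two = np.concatenate([one, one])
        with ad.no_grad():
            out = br(Tensor(two)).data
        np.testing.assert_array_equal(out[0], out[1])
        assert np.isfinite(out).all()
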