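"""Semantic branch: a hierarchical windowed self-attention encoder.

The branch tokenizes the 224 x 224 x 3 input into 4 x 4 patches (a strided
convolution with 48 kernels), lifts them to 96 channels with a linear
embedding, and alternates windowed-attention blocks with patch-merging
downsamplers.  Each block runs two attention stages: plain window attention
(W-MSA) followed by shifted-window attention (SW-MSA), each wrapped in the
pre-norm residual form

    z  <- attn(LN(z)) + z
    z  <- MLP(LN(z)) + z

Attention inside a window of M x M patch tokens is

    Attention(Q, K, V) = softmax(Q K^T / sqrt(d) + B) V

with a learned relative-position bias B shared across windows.  The shifted
stage cyclically rolls the map by floor(M/2) and masks attention between
token pairs that were not neighbours before the roll, which lets information
cross window boundaries without enlarging the windows.

Feature maps here use the channels-last (N, H, W, C) token layout; the
branch converts from and to NCHW at its boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .nn import DimensionError, Module, Parameter

__all__ = [
    "SwinBlockConfig", "WindowSet",
    "window_partition", "window_reverse", "window_attention",
    "relative_position_index", "shift_attention_mask",
    "PatchEmbed", "SwinStage", "SwinBlock", "PatchMerging", "SemanticBranch",
]

MASK_VALUE = -100.0  # additive pre-softmax penalty for forbidden pairs


@dataclass
class SwinBlockConfig:
    """Hyperparameters of one attention stage.

    ``embed_dim`` must equal ``num_heads * head_dim``; ``shift_size`` is 0
    for the plain stage and ``window_size // 2`` for the shifted stage.
    """

    window_size: int = 7
    embed_dim: int = 96
    num_heads: int = 3
    shift_size: int = 0
    mlp_ratio: float = 4.0

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads

    def __post_init__(self):
        if self.embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        if not 0 <= self.shift_size < self.window_size:
            raise ValueError("shift_size must satisfy 0 <= shift < window_size")


@dataclass
class WindowSet:
    """Windows produced by :func:`window_partition` plus undo metadata."""

    tokens: Tensor              # (batch * num_windows, wh * ww, C)
    num_windows: int
    window_shape: tuple         # (wh, ww) tokens per window side
    origin_shape: tuple         # (H, W) before padding
    padded_shape: tuple         # (Hp, Wp) after padding
    batch: int
    shift_applied: int
    attn_mask: np.ndarray | None = None   # (num_windows, T, T) additive

    @property
    def tokens_per_window(self) -> int:
        return self.window_shape[0] * self.window_shape[1]

    @property
    def channels(self) -> int:
        return self.tokens.shape[-1]


def _resolve_window(h: int, w: int, m: int) -> tuple:
    """Effective window shape: full-map fallback when the map is smaller
    than the configured window on both sides."""
    if m <= 0:
        raise ValueError(f"window size must be positive, got {m}")
    if h < m and w < m:
        return h, w
    return m, m


def shift_attention_mask(hp: int, wp: int, wh: int, ww: int,
                         shift: int) -> np.ndarray:
    """Additive mask forbidding attention across the cyclic-roll seam.

    Positions of the rolled (hp, wp) grid are labelled by the canonical
    three-slice scheme along each axis (interior, tail, wrapped-in tail);
    within every window, pairs with different labels receive
    ``MASK_VALUE``.  Only the windows touching the right/bottom edge mix
    labels: there the last ``shift`` rows/columns hold tokens carried over
    from the opposite image border, which are not genuine neighbours of the
    rest of the window.
    """
    img = np.zeros((hp, wp), dtype=np.int64)
    cnt = 0
    h_slices = (slice(0, -wh), slice(-wh, -shift), slice(-shift, None))
    w_slices = (slice(0, -ww), slice(-ww, -shift), slice(-shift, None))
    for hs in h_slices:
        for ws in w_slices:
            img[hs, ws] = cnt
            cnt += 1
    wins = img.reshape(hp // wh, wh, wp // ww, ww).transpose(0, 2, 1, 3)
    wins = wins.reshape(-1, wh * ww)
    diff = wins[:, :, None] != wins[:, None, :]
    return np.where(diff, MASK_VALUE, 0.0).astype(np.float32)


def window_partition(fm: Tensor, window_size: int, shift: int = 0) -> WindowSet:
    """Split an (N, H, W, C) map into non-overlapping windows of tokens.

    The map is right/bottom zero-padded to a multiple of the window, and,
    for ``shift > 0``, cyclically rolled by (-shift, -shift) first; the
    cross-seam attention mask is attached in that case.
    """
    n, h, w, c = fm.shape
    wh, ww = _resolve_window(h, w, window_size)
    if not 0 <= shift < max(wh, ww):
        raise ValueError(f"shift {shift} out of range for window {wh}x{ww}")
    pad_h = (-h) % wh
    pad_w = (-w) % ww
    x = fm
    if pad_h or pad_w:
        x = x.pad(((0, 0), (0, pad_h), (0, pad_w), (0, 0)))
    hp, wp = h + pad_h, w + pad_w
    mask = None
    if shift > 0:
        x = x.roll((-shift, -shift), (1, 2))
        mask = shift_attention_mask(hp, wp, wh, ww, shift)
    nh, nw = hp // wh, wp // ww
    x = x.reshape(n, nh, wh, nw, ww, c).transpose(0, 1, 3, 2, 4, 5)
    tokens = x.reshape(n * nh * nw, wh * ww, c)
    return WindowSet(tokens=tokens, num_windows=nh * nw, window_shape=(wh, ww),
                     origin_shape=(h, w), padded_shape=(hp, wp), batch=n,
                     shift_applied=shift, attn_mask=mask)


def window_reverse(ws: WindowSet, tokens: Tensor | None = None) -> Tensor:
    """Exact inverse of :func:`window_partition` back to (N, H, W, C)."""
    t = ws.tokens if tokens is None else tokens
    wh, ww = ws.window_shape
    hp, wp = ws.padded_shape
    h, w = ws.origin_shape
    n = ws.batch
    c = t.shape[-1]
    nh, nw = hp // wh, wp // ww
    x = t.reshape(n, nh, nw, wh, ww, c).transpose(0, 1, 3, 2, 4, 5)
    x = x.reshape(n, hp, wp, c)
    if ws.shift_applied:
        x = x.roll((ws.shift_applied, ws.shift_applied), (1, 2))
    if (hp, wp) != (h, w):
        x = x[:, :h, :w, :]
    return x


def window_attention(q: Tensor, k: Tensor, v: Tensor,
                     bias: Tensor | None = None,
                     mask: Tensor | np.ndarray | None = None) -> Tensor:
    """Scaled dot-product attention with an additive bias and optional mask.

    ``q``, ``k``, ``v`` share the shape (..., T, d); ``bias`` and ``mask``
    broadcast against the (..., T, T) score matrix.  Masked entries receive
    a large negative score before the softmax, so their weight is
    effectively zero.
    """
    if q.shape != k.shape or q.shape != v.shape:
        raise DimensionError(
            f"Q/K/V shapes differ: {q.shape}, {k.shape}, {v.shape}")
    d = q.shape[-1]
    scores = ad.matmul(q, k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2))
    scores = scores * (1.0 / np.sqrt(d))
    if bias is not None:
        scores = scores + bias
    if mask is not None:
        if not isinstance(mask, Tensor):
            mask = Tensor(np.asarray(mask, dtype=scores.dtype))
        scores = scores + mask
    attn = ad.softmax(scores, axis=-1)
    return ad.matmul(attn, v)


def relative_position_index(wh: int, ww: int, m: int) -> np.ndarray:
    """Flat (2M-1)^2-table index for every ordered token pair of a
    wh x ww window (wh, ww <= m)."""
    yy, xx = np.meshgrid(np.arange(wh), np.arange(ww), indexing="ij")
    coords = np.stack([yy.reshape(-1), xx.reshape(-1)], axis=1)  # (T, 2)
    rel = coords[:, None, :] - coords[None, :, :]                # (T, T, 2)
    return (rel[..., 0] + m - 1) * (2 * m - 1) + (rel[..., 1] + m - 1)


class PatchEmbed(Module):
    """4 x 4 stride-4 patch partition (48 kernels) + linear embedding."""

    def __init__(self, rng, in_channels: int = 3, partition_channels: int = 48,
                 embed_dim: int = 96):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, partition_channels, 4, rng, stride=4)
        self.embed = nn.Linear(partition_channels, embed_dim, rng)
        self.norm = nn.LayerNorm(embed_dim)

    def partition(self, image: Tensor) -> Tensor:
        """Patch partition only: (N, 3, H, W) -> (N, H/4, W/4, 48)."""
        n, c, h, w = image.shape
        if h % 4:
            raise DimensionError(f"height {h} not divisible by patch size 4")
        if w % 4:
            raise DimensionError(f"width {w} not divisible by patch size 4")
        x = self.proj(image)
        return x.transpose(0, 2, 3, 1)

    def forward(self, image: Tensor) -> Tensor:
        return self.norm(self.embed(self.partition(image)))


class SwinStage(Module):
    """One pre-norm attention stage (W-MSA or SW-MSA) plus its MLP."""

    def __init__(self, cfg: SwinBlockConfig, rng):
        super().__init__()
        self.cfg = cfg
        c = cfg.embed_dim
        self.norm1 = nn.LayerNorm(c)
        self.qkv = nn.Linear(c, 3 * c, rng)
        self.proj = nn.Linear(c, c, rng)
        m = cfg.window_size
        self.bias_table = Parameter(
            nn.trunc_normal_(rng, ((2 * m - 1) ** 2, cfg.num_heads)))
        self.norm2 = nn.LayerNorm(c)
        hidden = int(c * cfg.mlp_ratio)
        self.fc1 = nn.Linear(c, hidden, rng)
        self.fc2 = nn.Linear(hidden, c, rng)

    def _attend(self, tokens: Tensor, window_shape, attn_mask,
                masked: bool) -> Tensor:
        cfg = self.cfg
        bt, t, c = tokens.shape
        nh, d = cfg.num_heads, cfg.head_dim
        qkv = self.qkv(tokens).reshape(bt, t, 3, nh, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        idx = relative_position_index(*window_shape, cfg.window_size)
        bias = ad.index_select(self.bias_table, idx).transpose(2, 0, 1)  # (nh,T,T)
        mask = None
        if masked and attn_mask is not None:
            nw = attn_mask.shape[0]
            tiled = np.broadcast_to(
                attn_mask[None, :, None], (bt // nw, nw, 1, t, t))
            mask = tiled.reshape(bt, 1, t, t)
        out = window_attention(q, k, v, bias=bias, mask=mask)  # (bt, nh, T, d)
        out = out.transpose(0, 2, 1, 3).reshape(bt, t, c)
        return self.proj(out)

    def forward(self, fm: Tensor) -> Tensor:
        cfg = self.cfg
        if fm.shape[-1] != cfg.embed_dim:
            raise DimensionError(
                f"expected {cfg.embed_dim} channels, got {fm.shape[-1]}")
        shift = cfg.shift_size
        if fm.shape[1] < cfg.window_size and fm.shape[2] < cfg.window_size:
            shift = 0  # single full-map window: shifting is a no-op
        shortcut = fm
        x = self.norm1(fm)
        ws = window_partition(x, cfg.window_size, shift)
        out = self._attend(ws.tokens, ws.window_shape, ws.attn_mask,
                           masked=shift > 0)
        x = window_reverse(ws, out) + shortcut
        y = self.norm2(x)
        y = self.fc2(ad.gelu(self.fc1(y)))
        return y + x


class SwinBlock(Module):
    """A full block: plain-window stage followed by a shifted-window stage."""

    def __init__(self, embed_dim: int, num_heads: int, rng,
                 window_size: int = 7, mlp_ratio: float = 4.0):
        super().__init__()
        self.stage1 = SwinStage(SwinBlockConfig(
            window_size, embed_dim, num_heads, 0, mlp_ratio), rng)
        self.stage2 = SwinStage(SwinBlockConfig(
            window_size, embed_dim, num_heads, window_size // 2, mlp_ratio), rng)

    def forward(self, fm: Tensor) -> Tensor:
        return self.stage2(self.stage1(fm))


class PatchMerging(Module):
    """2 x 2 neighbourhood concatenation + pre-norm linear 4C -> 2C."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.channels = channels
        self.norm = nn.LayerNorm(4 * channels)
        self.reduction = nn.Linear(4 * channels, 2 * channels, rng, bias=False)

    def forward(self, fm: Tensor) -> Tensor:
        n, h, w, c = fm.shape
        if h % 2:
            raise DimensionError(f"height {h} must be even for patch merging")
        if w % 2:
            raise DimensionError(f"width {w} must be even for patch merging")
        x0 = fm[:, 0::2, 0::2, :]
        x1 = fm[:, 1::2, 0::2, :]
        x2 = fm[:, 0::2, 1::2, :]
        x3 = fm[:, 1::2, 1::2, :]
        x = ad.concat([x0, x1, x2, x3], axis=-1)
        return self.reduction(self.norm(x))


class SemanticBranch(Module):
    """Patch embed -> (block, merge) x 3: 224x224x3 -> 7x7x768 (NCHW io)."""

    def __init__(self, rng, channels=(96, 192, 384, 768), num_heads=(3, 6, 12),
                 window_size: int = 7, partition_channels: int = 48):
        super().__init__()
        self.patch_embed = PatchEmbed(rng, 3, partition_channels, channels[0])
        self.block1 = SwinBlock(channels[0], num_heads[0], rng, window_size)
        self.merge1 = PatchMerging(channels[0], rng)
        self.block2 = SwinBlock(channels[1], num_heads[1], rng, window_size)
        self.merge2 = PatchMerging(channels[1], rng)
        self.block3 = SwinBlock(channels[2], num_heads[2], rng, window_size)
        self.merge3 = PatchMerging(channels[2], rng)

    def forward(self, image: Tensor, trace: dict | None = None) -> Tensor:
        x = self.patch_embed(image)
        if trace is not None:
            part = self.patch_embed.partition(image)
            trace["semantic.patch_partition"] = _nchw_shape(part)
            trace["semantic.linear_embedding"] = _nchw_shape(x)
        x = self.block1(x)
        if trace is not None:
            trace["semantic.swin_block1"] = _nchw_shape(x)
        x = self.merge1(x)
        if trace is not None:
            trace["semantic.patch_merging1"] = _nchw_shape(x)
        x = self.block2(x)
        if trace is not None:
            trace["semantic.swin_block2"] = _nchw_shape(x)
        x = self.merge2(x)
        if trace is not None:
            trace["semantic.patch_merging2"] = _nchw_shape(x)
        x = self.block3(x)
        if trace is not None:
            trace["semantic.swin_block3"] = _nchw_shape(x)
        x = self.merge3(x)
        if trace is not None:
            trace["semantic.patch_merging3"] = _nchw_shape(x)
        return x.transpose(0, 3, 1, 2)


def _nchw_shape(nhwc: Tensor) -> tuple:
    n, h, w, c = nhwc.shape
    return (h, w, c)
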