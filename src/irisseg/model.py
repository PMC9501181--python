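"""The full bilateral segmentation network and its configuration.

The encoder runs two branches over the same preprocessed image: a windowed
self-attention semantic branch (global context, output 7x7x768) and a
depthwise-separable CNN detail branch (local texture, output 14x14x384 with
skip features).  The decoder upsamples the semantic output through four
decode blocks (1x1 reduce -> stride-2 transposed conv -> 1x1 project),
fusing the detail-branch skips by elementwise addition at the three
shape-matched resolutions, then a 3x3 convolution and a final transposed
convolution produce one logit per input pixel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .nn import DimensionError, Module
from .semantic import SemanticBranch
from .detail import DetailBranch

__all__ = ["ModelConfig", "DecodeBlock", "IrisSegNet", "build_model",
           "predict_mask", "save_checkpoint", "load_checkpoint",
           "DESIGN_LAYER_SHAPES"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults give the full-size network.

    ``scaled`` builds a width-divided, smaller-input variant with the same
    topology for desk-scale experiments.
    """

    input_size: int = 224
    semantic_channels: tuple = (96, 192, 384, 768)
    detail_channels: tuple = (16, 96, 192, 384)
    decoder_channels: tuple = (384, 192, 96, 48, 16, 1)
    partition_channels: int = 48
    num_heads: tuple = (3, 6, 12)
    window_size: int = 7
    dilation_rates: tuple = (1, 2, 3)
    camm_squeeze: int = 16
    fem_reduction: int = 4
    random_seed: int = 0

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be a multiple of 32")
        for name in ("semantic_channels", "detail_channels",
                     "decoder_channels", "num_heads", "dilation_rates"):
            setattr(self, name, tuple(getattr(self, name)))
        if any(c <= 0 for c in self.semantic_channels + self.detail_channels
               + self.decoder_channels):
            raise ValueError("channel counts must be positive")

    @classmethod
    def scaled(cls, width_divisor: int = 4, input_size: int = 64,
               random_seed: int = 0) -> "ModelConfig":
        d = width_divisor
        return cls(
            input_size=input_size,
            semantic_channels=tuple(c // d for c in (96, 192, 384, 768)),
            detail_channels=tuple(c // d for c in (16, 96, 192, 384)),
            decoder_channels=tuple(max(c // d, 1) for c in (384, 192, 96, 48, 16, 1)),
            partition_channels=max(48 // d, 4),
            camm_squeeze=16 if (384 // d) % 16 == 0 else 4,
            random_seed=random_seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def layer_shapes(self) -> dict:
        """Expected (H, W, C) output shape per named layer."""
        s = self.input_size
        sc, dc = self.semantic_channels, self.detail_channels
        dec = self.decoder_channels
        p = s // 4
        return {
            "semantic.patch_partition": (p, p, self.partition_channels),
            "semantic.linear_embedding": (p, p, sc[0]),
            "semantic.swin_block1": (p, p, sc[0]),
            "semantic.patch_merging1": (p // 2, p // 2, sc[1]),
            "semantic.swin_block2": (p // 2, p // 2, sc[1]),
            "semantic.patch_merging2": (p // 4, p // 4, sc[2]),
            "semantic.swin_block3": (p // 4, p // 4, sc[2]),
            "semantic.patch_merging3": (p // 8, p // 8, sc[3]),
            "detail.conv1": (s // 2, s // 2, dc[0]),
            "detail.conv2": (s // 4, s // 4, dc[1]),
            "detail.fem1": (s // 8, s // 8, dc[2]),
            "detail.fem2": (s // 8, s // 8, dc[2]),
            "detail.fem3": (s // 16, s // 16, dc[3]),
            "detail.fem4": (s // 16, s // 16, dc[3]),
            "detail.mfiem": (s // 16, s // 16, dc[3]),
            "detail.camm": (s // 16, s // 16, dc[3]),
            "decoder.decode_block1": (s // 16, s // 16, dec[0]),
            "decoder.decode_block2": (s // 8, s // 8, dec[1]),
            "decoder.decode_block3": (s // 4, s // 4, dec[2]),
            "decoder.decode_block4": (s // 2, s // 2, dec[3]),
            "decoder.conv3x3": (s // 2, s // 2, dec[4]),
            "decoder.head": (s, s, dec[5]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return cls(**d)


class DecodeBlock(Module):
    """1x1 reduce (C -> C/4) -> transposed conv x2 -> 1x1 to out_channels."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        super().__init__()
        if in_channels < 4:
            raise ValueError(
                f"decode block needs >= 4 input channels, got {in_channels}")
        mid = in_channels // 4
        self.reduce = nn.ConvBNAct(in_channels, mid, 1, rng)
        self.up = nn.ConvTranspose2d(mid, mid, rng, bias=False)
        self.up_bn = nn.BatchNorm2d(mid)
        self.project = nn.ConvBNAct(mid, out_channels, 1, rng)
        self.in_channels = in_channels

    def forward(self, fm: Tensor) -> Tensor:
        if fm.shape[1] != self.in_channels:
            raise DimensionError(
                f"decode block expected {self.in_channels} channels, "
                f"got {fm.shape[1]}")
        x = self.reduce(fm)
        x = ad.relu6(self.up_bn(self.up(x)))
        return self.project(x)


class IrisSegNet(Module):
    """Bilateral encoder + decoder producing per-pixel iris logits."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.random_seed)
        self.semantic = SemanticBranch(
            rng, cfg.semantic_channels, cfg.num_heads, cfg.window_size,
            cfg.partition_channels)
        self.detail = DetailBranch(
            rng, cfg.detail_channels, cfg.fem_reduction, cfg.dilation_rates,
            cfg.camm_squeeze)
        dc = cfg.decoder_channels
        self.decode1 = DecodeBlock(cfg.semantic_channels[3], dc[0], rng)
        self.decode2 = DecodeBlock(dc[0], dc[1], rng)
        self.decode3 = DecodeBlock(dc[1], dc[2], rng)
        self.decode4 = DecodeBlock(dc[2], dc[3], rng)
        self.adjust = nn.ConvBNAct(dc[3], dc[4], 3, rng, padding=1)
        self.head = nn.ConvTranspose2d(dc[4], dc[5], rng)

    def forward(self, image: Tensor, trace: dict | None = None) -> Tensor:
        s = self.input_size_check(image)
        sem = self.semantic(image, trace)            # (N, C3, s/32, s/32)
        _, skips = self.detail(image, trace)

        def rec(name, t):
            if trace is not None:
                trace[name] = (t.shape[2], t.shape[3], t.shape[1])

        x = self.decode1(sem) + skips[2]
        rec("decoder.decode_block1", x)
        x = self.decode2(x) + skips[1]
        rec("decoder.decode_block2", x)
        x = self.decode3(x) + skips[0]
        rec("decoder.decode_block3", x)
        x = self.decode4(x)
        rec("decoder.decode_block4", x)
        x = self.adjust(x)
        rec("decoder.conv3x3", x)
        logits = self.head(x)
        rec("decoder.head", logits)
        return logits

    def input_size_check(self, image: Tensor) -> int:
        s = self.config.input_size
        if image.ndim != 4 or image.shape[1] != 3 or \
                image.shape[2] != s or image.shape[3] != s:
            raise DimensionError(
                f"expected an (N, 3, {s}, {s}) image, got {image.shape}")
        return s

    def shape_trace(self, image: Tensor | np.ndarray) -> dict:
        """Instrumented forward pass: layer name -> (H, W, C) output shape."""
        if not isinstance(image, Tensor):
            image = Tensor(np.asarray(image, dtype=np.float32))
        trace: dict = {}
        was_training = self.training
        self.eval()
        with ad.no_grad():
            self.forward(image, trace)
        self.train(was_training)
        return trace


def build_model(config: ModelConfig | None = None) -> IrisSegNet:
    return IrisSegNet(config)


def predict_mask(logits: Tensor | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize per-pixel logits: mask = 1 iff sigmoid(logit) >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    prob = 1.0 / (1.0 + np.exp(-arr))
    return (prob >= threshold).astype(np.uint8)


def save_checkpoint(path, model: IrisSegNet) -> None:
    """Write weights + config to a single ``.npz`` file."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> IrisSegNet:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode()))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = IrisSegNet(cfg)
    model.load_state_dict(state)
    return model


#: Expected layer output shapes for the full-size default configuration.
DESIGN_LAYER_SHAPES = ModelConfig().layer_shapes()
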