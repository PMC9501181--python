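"""Detail branch: a depthwise-separable CNN encoder for fine iris texture.

Two stride-2 3x3 stem convolutions take the 224x224x3 input to 56x56x96;
four bottleneck feature-extraction modules (1x1 reduce -> depthwise 3x3 ->
depthwise 3x3 -> 1x1 expand, residual shortcut when the shape is unchanged)
continue to 14x14x384.  A multiscale dilated module and a channel-attention
module refine the final map.  Skip features are tapped at the three
resolutions the decoder fuses (56x56x96, 28x28x192, 14x14x384).

Every convolution is followed by batch normalization; ReLU6 is the
activation except after the first 1x1 convolution and the second depthwise
convolution of each bottleneck, which are deliberately linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .nn import DimensionError, Module
from .attention import CAMM, MFIEM

__all__ = ["FEMConfig", "DetailStem", "FeatureExtractionModule", "DetailBranch"]


@dataclass
class FEMConfig:
    """Bottleneck feature-extraction-module hyperparameters.

    The shortcut is active iff ``stride == 1`` and the channel count is
    preserved; ``reduction_factor`` sets the bottleneck width
    ``in_channels // reduction_factor``.
    """

    in_channels: int
    out_channels: int
    stride: int = 1
    reduction_factor: int = 4

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.in_channels < self.reduction_factor:
            raise ValueError("in_channels smaller than reduction_factor")

    @property
    def shortcut_active(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


_ConvBN = nn.ConvBNAct


class _DepthwiseSeparable(Module):
    """Per-channel 3x3 convolution followed by a 1x1 pointwise convolution."""

    def __init__(self, cin, cout, rng, stride=1, act=True):
        super().__init__()
        self.dw = _ConvBN(cin, cin, 3, rng, stride=stride, padding=1,
                          groups=cin, act=act)
        self.pw = _ConvBN(cin, cout, 1, rng, act=act)

    def forward(self, x):
        return self.pw(self.dw(x))


class DetailStem(Module):
    """Two stride-2 3x3 convolutions: 224x224x3 -> 112x112x16 -> 56x56x96."""

    def __init__(self, rng, channels=(16, 96)):
        super().__init__()
        self.conv1 = _ConvBN(3, channels[0], 3, rng, stride=2, padding=1)
        self.conv2 = _ConvBN(channels[0], channels[1], 3, rng, stride=2,
                             padding=1)

    def forward(self, image: Tensor) -> Tensor:
        if image.ndim != 4 or image.shape[1] != 3:
            raise DimensionError(
                f"stem expects an (N, 3, H, W) image, got {image.shape}")
        return self.conv2(self.conv1(image))


class FeatureExtractionModule(Module):
    """Bottleneck block of two 1x1 and two depthwise-separable convolutions.

    Pipeline: 1x1 reduce (linear) -> DW-separable 3x3 stride s (ReLU6) ->
    DW-separable 3x3 (linear) -> 1x1 expand (ReLU6); the input is added
    back when the shape is preserved.
    """

    def __init__(self, cfg: FEMConfig, rng):
        super().__init__()
        self.cfg = cfg
        mid = cfg.in_channels // cfg.reduction_factor
        self.reduce = _ConvBN(cfg.in_channels, mid, 1, rng, act=False)
        self.dw1 = _DepthwiseSeparable(mid, mid, rng, stride=cfg.stride,
                                       act=True)
        self.dw2 = _DepthwiseSeparable(mid, mid, rng, act=False)
        self.expand = _ConvBN(mid, cfg.out_channels, 1, rng, act=True)

    def forward(self, fm: Tensor) -> Tensor:
        if fm.shape[1] != self.cfg.in_channels:
            raise DimensionError(
                f"FEM expected {self.cfg.in_channels} channels, "
                f"got {fm.shape[1]}")
        y = self.expand(self.dw2(self.dw1(self.reduce(fm))))
        if self.cfg.shortcut_active:
            y = y + fm
        return y


class DetailBranch(Module):
    """Stem + four bottleneck modules + MFIEM + CAMM, with skip taps."""

    def __init__(self, rng, channels=(16, 96, 192, 384),
                 reduction_factor: int = 4, dilation_rates=(1, 2, 3),
                 camm_squeeze: int = 16):
        super().__init__()
        c0, c1, c2, c3 = channels
        self.stem = DetailStem(rng, (c0, c1))
        self.fem1 = FeatureExtractionModule(
            FEMConfig(c1, c2, 2, reduction_factor), rng)
        self.fem2 = FeatureExtractionModule(
            FEMConfig(c2, c2, 1, reduction_factor), rng)
        self.fem3 = FeatureExtractionModule(
            FEMConfig(c2, c3, 2, reduction_factor), rng)
        self.fem4 = FeatureExtractionModule(
            FEMConfig(c3, c3, 1, reduction_factor), rng)
        self.mfiem = MFIEM(c3, rng, dilation_rates)
        self.camm = CAMM(c3, rng, camm_squeeze)

    def forward(self, image: Tensor, trace: dict | None = None):
        def rec(name, t):
            if trace is not None:
                trace[name] = (t.shape[2], t.shape[3], t.shape[1])

        x = self.stem.conv1(image)
        rec("detail.conv1", x)
        x = self.stem.conv2(x)
        rec("detail.conv2", x)
        skip56 = x
        x = self.fem1(x)
        rec("detail.fem1", x)
        x = self.fem2(x)
        rec("detail.fem2", x)
        skip28 = x
        x = self.fem3(x)
        rec("detail.fem3", x)
        x = self.fem4(x)
        rec("detail.fem4", x)
        x = self.mfiem(x)
        rec("detail.mfiem", x)
        x = self.camm(x)
        rec("detail.camm", x)
        return x, [skip56, skip28, x]
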