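"""Multiscale dilated feature extraction and attention gates.

MFIEM = MFEM + SAMM.  MFEM runs three parallel 3x3 convolutions with
dilation rates {1, 2, 3} (same-padding, so a rate-r kernel spans 2r+1
pixels without changing the map size), stacks the results along the channel
axis and adjusts the dimension back with a 3x3 convolution.  SAMM gates the
result with a single-channel spatial sigmoid map.  CAMM produces a
per-channel sigmoid weight vector from two directional global-pooling
branches (max over width, average over height), each squeezed and restored
by a pair of 1x1 convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .nn import DimensionError, Module

__all__ = ["MFIEMConfig", "CAMMConfig", "MFEM", "SAMM", "MFIEM", "CAMM"]


@dataclass
class MFIEMConfig:
    channels: int
    dilation_rates: tuple = (1, 2, 3)

    def __post_init__(self):
        if any(r < 1 for r in self.dilation_rates):
            raise ValueError("dilation rates must be >= 1")


@dataclass
class CAMMConfig:
    channels: int
    squeeze_factor: int = 16

    def __post_init__(self):
        if self.channels % self.squeeze_factor:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by the "
                f"squeeze factor ({self.squeeze_factor})")


class MFEM(Module):
    """Parallel dilated 3x3 branches, concatenated and re-projected."""

    def __init__(self, channels: int, rng, dilation_rates=(1, 2, 3)):
        super().__init__()
        self.cfg = MFIEMConfig(channels, tuple(dilation_rates))
        self.branches = nn.ModuleList([
            nn.ConvBNAct(channels, channels, 3, rng, padding=r, dilation=r)
            for r in self.cfg.dilation_rates
        ])
        self.adjust = nn.ConvBNAct(
            channels * len(self.cfg.dilation_rates), channels, 3, rng,
            padding=1)

    def forward(self, fm: Tensor) -> Tensor:
        if fm.shape[1] != self.cfg.channels:
            raise DimensionError(
                f"MFEM expected {self.cfg.channels} channels, got {fm.shape[1]}")
        outs = [b(fm) for b in self.branches]
        return self.adjust(ad.concat(outs, axis=1))


class SAMM(Module):
    """Spatial attention: sigmoid(1x1 conv) broadcast over channels."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(channels, 1, 1, rng)

    def forward(self, fm: Tensor) -> Tensor:
        gate = ad.sigmoid(self.conv(fm))  # (N, 1, H, W) in (0, 1)
        return fm * gate


class MFIEM(Module):
    """Multiscale feature-information extraction: MFEM gated by SAMM."""

    def __init__(self, channels: int, rng, dilation_rates=(1, 2, 3)):
        super().__init__()
        self.mfem = MFEM(channels, rng, dilation_rates)
        self.samm = SAMM(channels, rng)

    def forward(self, fm: Tensor) -> Tensor:
        return self.samm(self.mfem(fm))


class CAMM(Module):
    """Channel attention from two directional global-pooling branches.

    Branch 1 max-pools over the width axis, branch 2 average-pools over the
    height axis; each remaining spatial axis is collapsed by mean to a
    1x1xC descriptor before the squeeze/restore 1x1 convolutions (the two
    branches keep independent weights).  The summed descriptors pass a
    sigmoid and rescale the channels.
    """

    def __init__(self, channels: int, rng, squeeze_factor: int = 16):
        super().__init__()
        self.cfg = CAMMConfig(channels, squeeze_factor)
        mid = channels // squeeze_factor
        self.w_squeeze = nn.Conv2d(channels, mid, 1, rng)
        self.w_restore = nn.Conv2d(mid, channels, 1, rng)
        self.h_squeeze = nn.Conv2d(channels, mid, 1, rng)
        self.h_restore = nn.Conv2d(mid, channels, 1, rng)

    def forward(self, fm: Tensor) -> Tensor:
        if fm.shape[1] != self.cfg.channels:
            raise DimensionError(
                f"CAMM expected {self.cfg.channels} channels, got {fm.shape[1]}")
        # max over width, then mean over height -> (N, C, 1, 1)
        d1 = fm.max(axis=3, keepdims=True).mean(axis=2, keepdims=True)
        # mean over height, then mean over width -> (N, C, 1, 1)
        d2 = fm.mean(axis=2, keepdims=True).mean(axis=3, keepdims=True)
        d1 = self.w_restore(ad.relu(self.w_squeeze(d1)))
        d2 = self.h_restore(ad.relu(self.h_squeeze(d2)))
        weights = ad.sigmoid(d1 + d2)  # (N, C, 1, 1) in (0, 1)
        return fm * weights
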