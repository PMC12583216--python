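"""Composite blocks: spatial+channel squeeze-and-excitation, residual blocks.

The concurrent spatial and channel squeeze-and-excitation (SCse) block
recalibrates a feature map two ways and sums the results:

* channel excitation (cSE): global average pool -> bottleneck MLP -> sigmoid
  gives one gate per channel;
* spatial excitation (sSE): a 1x1 convolution -> sigmoid gives one gate per
  pixel.

Both paths multiply the input feature map, so the backward pass applies the
product rule explicitly.
"""

from __future__ import annotations

import numpy as np

from .core import (
    F32,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    Module,
    ReLU,
    Sigmoid,
)


class SCse(Module):
    """Concurrent spatial and channel squeeze & excitation."""

    def __init__(self, channels: int, reduction: int = 2, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.gap = GlobalAvgPool()
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.relu = ReLU()
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.sig_c = Sigmoid()
        self.conv_s = Conv2d(channels, 1, kernel=1, rng=rng)
        self.sig_s = Sigmoid()

    def forward(self, x, train=False):
        s = self.sig_c(self.fc2(self.relu(self.fc1(self.gap(x, train), train), train), train), train)
        q = self.sig_s(self.conv_s(x, train), train)
        self._cache = (x, s, q)
        return (x * s[:, :, None, None] + x * q).astype(F32)

    def backward(self, gy):
        x, s, q = self._cache
        # channel path: y1 = x * s
        gx = gy * s[:, :, None, None]
        gs = (gy * x).sum(axis=(2, 3))
        gx += self.gap.backward(self.fc1.backward(self.relu.backward(self.fc2.backward(self.sig_c.backward(gs)))))
        # spatial path: y2 = x * q
        gx += gy * q
        gq = (gy * x).sum(axis=1, keepdims=True)
        gx += self.conv_s.backward(self.sig_s.backward(gq))
        return gx.astype(F32)


class ResidualBlock(Module):
    """Basic two-convolution residual block with optional SCse attention.

    conv3x3(stride)-BN-ReLU-conv3x3-BN plus a (projected, if needed) skip
    connection, followed by ReLU and, when enabled, an SCse block.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, attention: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        self.project = in_ch != out_ch or stride != 1
        if self.project:
            self.conv_skip = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.bn_skip = BatchNorm2d(out_ch)
        self.attn = SCse(out_ch, rng=rng) if attention else None

    def forward(self, x, train=False):
        h = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x, train), train), train), train), train)
        skip = self.bn_skip(self.conv_skip(x, train), train) if self.project else x
        out = self.relu2(h + skip, train)
        if self.attn is not None:
            out = self.attn(out, train)
        return out

    def backward(self, gy):
        if self.attn is not None:
            gy = self.attn.backward(gy)
        g = self.relu2.backward(gy)
        gx_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))))
        gx_skip = self.conv_skip.backward(self.bn_skip.backward(g)) if self.project else g
        return (gx_main + gx_skip).astype(F32)
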