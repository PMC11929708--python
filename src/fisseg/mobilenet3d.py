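"""MobileNetV3-Large inflated to 3D, with a lightweight segmentation head.

2D convolutions of the original architecture are replaced by 3D ones with
the same kernel sizes and channel dimensions.  The network is used as a
fissure *pre-segmentation*: it only needs to propose candidate voxels with
high recall, so a small FPN-style decoder on top of the inverted-residual
backbone suffices.  Inference-only: convolutions are plain numpy forward
passes.
"""

from __future__ import annotations

import numpy as np

from .nn.conv3d import conv3d, hardsigmoid, hardswish, upsample_trilinear
from .nn.modules import Module, Parameter
from .nn import modules as _mod


def _make_divisible(v, divisor=8):
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


class ConvBNAct(Module):
    def __init__(self, c_in, c_out, k=3, stride=1, groups=1, act="hs"):
        super().__init__()
        rng = _mod._init_rng
        fan_in = (c_in // groups) * k ** 3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0, std, (c_out, c_in // groups, k, k, k)))
        self.bn_weight = Parameter(np.ones(c_out))
        self.bn_bias = Parameter(np.zeros(c_out))
        self.running_mean = np.zeros(c_out, dtype=np.float32)
        self.running_var = np.ones(c_out, dtype=np.float32)
        self.stride, self.groups, self.k = stride, groups, k
        self.act = act

    def forward(self, x):
        y = conv3d(x, self.weight.data, None, self.stride,
                   self.k // 2, self.groups)
        inv = 1.0 / np.sqrt(self.running_var + 1e-5)
        y = ((y - self.running_mean[:, None, None, None])
             * (self.bn_weight.data * inv)[:, None, None, None]
             + self.bn_bias.data[:, None, None, None])
        if self.act == "hs":
            return hardswish(y)
        if self.act == "re":
            return np.maximum(y, 0.0)
        return y


class SqueezeExcite(Module):
    def __init__(self, channels, squeeze):
        super().__init__()
        rng = _mod._init_rng
        self.fc1_w = Parameter(rng.normal(0, np.sqrt(2.0 / channels),
                                          (squeeze, channels, 1, 1, 1)))
        self.fc1_b = Parameter(np.zeros(squeeze))
        self.fc2_w = Parameter(rng.normal(0, np.sqrt(2.0 / squeeze),
                                          (channels, squeeze, 1, 1, 1)))
        self.fc2_b = Parameter(np.zeros(channels))

    def forward(self, x):
        s = x.mean(axis=(1, 2, 3))
        s = np.maximum(self.fc1_w.data[:, :, 0, 0, 0] @ s + self.fc1_b.data, 0)
        s = hardsigmoid(self.fc2_w.data[:, :, 0, 0, 0] @ s + self.fc2_b.data)
        return x * s[:, None, None, None]


class InvertedResidual(Module):
    def __init__(self, c_in, exp, c_out, k, stride, se, act):
        super().__init__()
        self.use_res = stride == 1 and c_in == c_out
        layers = []
        if exp != c_in:
            layers.append(ConvBNAct(c_in, exp, 1, 1, 1, act))
        layers.append(ConvBNAct(exp, exp, k, stride, exp, act))
        if se:
            layers.append(SqueezeExcite(exp, _make_divisible(exp // 4)))
        layers.append(ConvBNAct(exp, c_out, 1, 1, 1, "none"))
        self.layers = layers

    def forward(self, x):
        y = x
        for layer in self.layers:
            y = layer(y)
        return x + y if self.use_res else y


# (kernel, expanded, out, SE, activation, stride) per torchvision's
# MobileNetV3-Large bottleneck configuration.
_MBV3_LARGE = [
    (3, 16, 16, False, "re", 1),
    (3, 64, 24, False, "re", 2),
    (3, 72, 24, False, "re", 1),
    (5, 72, 40, True, "re", 2),
    (5, 120, 40, True, "re", 1),
    (5, 120, 40, True, "re", 1),
    (3, 240, 80, False, "hs", 2),
    (3, 200, 80, False, "hs", 1),
    (3, 184, 80, False, "hs", 1),
    (3, 184, 80, False, "hs", 1),
    (3, 480, 112, True, "hs", 1),
    (3, 672, 112, True, "hs", 1),
    (5, 672, 160, True, "hs", 2),
    (5, 960, 160, True, "hs", 1),
    (5, 960, 160, True, "hs", 1),
]

# Backbone stages after which skip features are tapped (stride 2/4/8/16)
# plus the final stride-32 feature map.
_SKIP_AFTER = {0: 16, 2: 24, 5: 40, 11: 112}


class MobileNetV3Seg3D(Module):
    """3D MobileNetV3-Large encoder with an FPN-lite segmentation decoder."""

    def __init__(self, in_channels: int = 1, n_classes: int = 4,
                 head_width: int = 44):
        super().__init__()
        self.stem = ConvBNAct(in_channels, 16, 3, 2, 1, "hs")
        blocks = []
        c = 16
        for k, exp, c_out, se, act, s in _MBV3_LARGE:
            blocks.append(InvertedResidual(c, exp, c_out, k, s, se, act))
            c = c_out
        self.blocks = blocks
        self.top = ConvBNAct(c, 960, 1, 1, 1, "hs")
        h = head_width
        skip_channels = [16] + list(_SKIP_AFTER.values())  # stem + taps
        self.lateral = [ConvBNAct(ch, h, 1, 1, 1, "re")
                        for ch in skip_channels + [960]]
        self.fuse = [ConvBNAct(h, h, 3, 1, 1, "re") for _ in skip_channels]
        rng = _mod._init_rng
        self.classifier_w = Parameter(
            rng.normal(0, np.sqrt(2.0 / h), (n_classes, h, 1, 1, 1)))
        self.classifier_b = Parameter(np.zeros(n_classes))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (1, D, H, W) normalized intensity -> (n_classes, D, H, W) logits."""
        in_shape = x.shape[1:]
        y = self.stem(x)
        skips = [y]
        for i, block in enumerate(self.blocks):
            y = block(y)
            if i in _SKIP_AFTER:
                skips.append(y)
        y = self.top(y)
        feat = self.lateral[-1](y)
        for skip, lat, fuse in zip(reversed(skips),
                                   reversed(self.lateral[:-1]),
                                   reversed(self.fuse)):
            up = upsample_trilinear(feat, skip.shape[1:])
            feat = fuse(up + lat(skip))
        full = upsample_trilinear(feat, in_shape)
        logits = conv3d(full, self.classifier_w.data, self.classifier_b.data)
        return logits
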