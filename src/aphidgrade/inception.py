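"""Local-feature branch: an Inception-ResNet-V2-style convolutional encoder.

The full profile follows the canonical network: a stem whose 7-layer point
(six convolutions + one max-pool) emits the 192x71x71 checkpoint on a
3x299x299 input, then 10 type-A, 20 type-B and 10 type-C residual Inception
blocks at 35x35x320, 17x17x1088 and 8x8x2080 with reduction stages between,
and a final 1x1 convolution to the 1536-channel feature map.  Residual
branches are scaled (0.17 / 0.10 / 0.20) before the skip addition, as usual
for this family.  The tiny profile keeps the same topology (stem checkpoint,
A/B/C residual blocks, two reductions, 1x1 projection) at desk-scale widths
for a 64-px input.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F


class ConvBN(nn.Module):
    """conv -> batch-norm -> optional ReLU (bias folded into the BN)."""

    def __init__(self, cin: int, cout: int, kernel, stride=1, padding=0,
                 act: bool = True, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, stride, padding,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn(self.conv(x))
        return out.relu() if self.act else out


class InceptionResidualBlock(nn.Module):
    """Multi-branch residual unit: concat(branches) -> 1x1 -> scale -> add.

    branches: list of lists of (cin, cout, kernel, padding) conv specs.
    """

    def __init__(self, channels: int, branches, scale: float, rng=None):
        super().__init__()
        self.scale = scale
        self.branches = []
        concat_ch = 0
        for bi, specs in enumerate(branches):
            seq = nn.Sequential(*[ConvBN(ci, co, k, padding=p, rng=rng)
                                  for (ci, co, k, p) in specs])
            setattr(self, f"branch{bi}", seq)
            self.branches.append(seq)
            concat_ch += specs[-1][1]
        self.up = nn.Conv2d(concat_ch, channels, 1, rng=rng)  # linear proj

    def forward(self, x: Tensor) -> Tensor:
        outs = [br(x) for br in self.branches]
        up = self.up(nn.concat(outs, axis=1))
        return (x + self.scale * up).relu()


def _block_a(c: int, w, rng):
    return InceptionResidualBlock(c, [
        [(c, w[0], 1, 0)],
        [(c, w[0], 1, 0), (w[0], w[0], 3, 1)],
        [(c, w[0], 1, 0), (w[0], w[1], 3, 1), (w[1], w[2], 3, 1)],
    ], scale=0.17, rng=rng)


def _block_b(c: int, w, rng):
    return InceptionResidualBlock(c, [
        [(c, w[2], 1, 0)],
        [(c, w[0], 1, 0), (w[0], w[1], (1, 7), (0, 3)),
         (w[1], w[2], (7, 1), (3, 0))],
    ], scale=0.10, rng=rng)


def _block_c(c: int, w, rng):
    return InceptionResidualBlock(c, [
        [(c, w[0], 1, 0)],
        [(c, w[0], 1, 0), (w[0], w[1], (1, 3), (0, 1)),
         (w[1], w[2], (3, 1), (1, 0))],
    ], scale=0.20, rng=rng)


class _ReductionA(nn.Module):
    """35 -> 17 grid: strided conv, conv chain and max-pool, concatenated."""

    def __init__(self, cin: int, rng=None):
        super().__init__()
        self.conv = ConvBN(cin, 384, 3, stride=2, rng=rng)
        self.chain = nn.Sequential(ConvBN(cin, 256, 1, rng=rng),
                                   ConvBN(256, 256, 3, padding=1, rng=rng),
                                   ConvBN(256, 384, 3, stride=2, rng=rng))
        self.pool = nn.MaxPool2d(3, 2)
        self.out_channels = 384 + 384 + cin

    def forward(self, x: Tensor) -> Tensor:
        return nn.concat([self.conv(x), self.chain(x), self.pool(x)], axis=1)


class _ReductionB(nn.Module):
    """17 -> 8 grid: three strided conv chains plus max-pool, concatenated."""

    def __init__(self, cin: int, rng=None):
        super().__init__()
        self.c1 = nn.Sequential(ConvBN(cin, 256, 1, rng=rng),
                                ConvBN(256, 384, 3, stride=2, rng=rng))
        self.c2 = nn.Sequential(ConvBN(cin, 256, 1, rng=rng),
                                ConvBN(256, 288, 3, stride=2, rng=rng))
        self.c3 = nn.Sequential(ConvBN(cin, 256, 1, rng=rng),
                                ConvBN(256, 288, 3, padding=1, rng=rng),
                                ConvBN(288, 320, 3, stride=2, rng=rng))
        self.pool = nn.MaxPool2d(3, 2)
        self.out_channels = 384 + 288 + 320 + cin

    def forward(self, x: Tensor) -> Tensor:
        return nn.concat([self.c1(x), self.c2(x), self.c3(x), self.pool(x)],
                         axis=1)


class _TinyReduction(nn.Module):
    def __init__(self, cin: int, cout: int, rng=None):
        super().__init__()
        self.conv = ConvBN(cin, cout, 3, stride=2, padding=1, rng=rng)
        self.out_channels = cout

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class InceptionResNetEncoder(nn.Module):
    """The local branch; exposes the stem checkpoint and the final map."""

    def __init__(self, profile, seed: int = 0):
        super().__init__()
        self.profile = profile
        rng = np.random.default_rng(seed)
        na, nb, nc = profile.local_blocks
        if profile.name == "full":
            # stem to the printed 71x71x192 checkpoint: Conv+Pool x 7
            self.stem = nn.Sequential(
                ConvBN(3, 32, 3, stride=2, rng=rng),        # 299 -> 149
                ConvBN(32, 32, 3, rng=rng),                 # -> 147
                ConvBN(32, 64, 3, padding=1, rng=rng),      # -> 147
                nn.MaxPool2d(3, 2),                         # -> 73
                ConvBN(64, 80, 1, rng=rng),                 # -> 73
                ConvBN(80, 192, 3, rng=rng),                # -> 71 (checkpoint)
            )
            self.stem_tail = nn.Sequential(
                nn.MaxPool2d(3, 2),                         # -> 35
                ConvBN(192, 320, 3, padding=1, rng=rng),
            )
            ca, wa = 320, (32, 48, 64)
            wb = (128, 160, 192)
            wc = (192, 224, 256)
            red_a = _ReductionA(ca, rng=rng)
            cb = red_a.out_channels                         # 1088
            red_b = _ReductionB(cb, rng=rng)
            cc = red_b.out_channels                         # 2080
        elif profile.name == "tiny":
            self.stem = nn.Sequential(
                ConvBN(3, 16, 3, padding=1, rng=rng),             # 64, full res
                ConvBN(16, 24, 3, stride=2, padding=1, rng=rng),  # -> 32
                ConvBN(24, profile.stem_checkpoint_channels, 3,
                       padding=1, rng=rng),                       # checkpoint
            )
            self.stem_tail = nn.Sequential(
                nn.MaxPool2d(2, 2),                               # -> 16
                ConvBN(profile.stem_checkpoint_channels, 80, 3,
                       padding=1, rng=rng),
            )
            ca, wa = 80, (24, 32, 40)
            wb = (32, 40, 40)
            wc = (40, 40, 56)
            red_a = _TinyReduction(ca, 112, rng=rng)
            cb = red_a.out_channels
            red_b = _TinyReduction(cb, 144, rng=rng)
            cc = red_b.out_channels
        else:  # pragma: no cover - profiles are validated upstream
            raise ValueError(f"unknown profile {profile.name!r}")

        self.blocks_a = nn.Sequential(*[_block_a(ca, wa, rng)
                                        for _ in range(na)])
        self.reduction_a = red_a
        self.blocks_b = nn.Sequential(*[_block_b(cb, wb, rng)
                                        for _ in range(nb)])
        self.reduction_b = red_b
        self.blocks_c = nn.Sequential(*[_block_c(cc, wc, rng)
                                        for _ in range(nc)])
        self.final_conv = ConvBN(cc, profile.local_dim, 1, rng=rng)
        self.out_channels = profile.local_dim

    def residual_block_counts(self) -> tuple[int, int, int]:
        return (len(self.blocks_a.layers), len(self.blocks_b.layers),
                len(self.blocks_c.layers))

    def forward_features(self, x: Tensor) -> dict[str, Tensor]:
        if x.shape[1] != 3 or x.shape[2] != self.profile.local_input \
                or x.shape[3] != self.profile.local_input:
            raise ValueError(
                f"local branch expects 3x{self.profile.local_input}"
                f"x{self.profile.local_input}, got {tuple(x.shape[1:])}")
        ckpt = self.stem(x)
        h = self.stem_tail(ckpt)
        h = self.blocks_a(h)
        h = self.reduction_a(h)
        h = self.blocks_b(h)
        h = self.reduction_b(h)
        h = self.blocks_c(h)
        h = self.final_conv(h)
        return {"stem_checkpoint": ckpt, "features": h}

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_features(x)["features"]
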