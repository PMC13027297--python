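"""Global Channel-Spatial Attention (GCSA).

The module refines a feature map in three sequential steps:

1. **Channel attention** — the map is permuted from C*H*W to W*H*C and a
   two-layer MLP (channel bottleneck C -> C/r_c -> C, ReLU between) is
   applied along the channel axis at every spatial position; a sigmoid turns
   the result into a gate in (0,1) which multiplies the input elementwise:
   ``F_channel = sigmoid(MLP(permute(F))) * F``.
2. **Channel shuffle** — channels are reshaped to (g, C/g), transposed and
   flattened, mixing information across the g groups.
3. **Spatial attention** — a k*k convolution reduces channels to C/r_s,
   then batch-norm, ReLU, a second k*k convolution back to C channels,
   batch-norm and a sigmoid produce a spatial gate that multiplies the
   shuffled map.

With the residual flag on, the input is added back after the spatial stage
(feature recalibration rather than replacement).  A ``pooled`` variant
(global-average-pool -> MLP -> sigmoid, one gate per channel) is provided
for ablation against the per-position channel attention above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F


@dataclass
class GCSAConfig:
    """Hyper-parameters of one GCSA block.

    channel_reduction: bottleneck ratio r_c of the channel MLP (C -> C/r_c).
    spatial_reduction: bottleneck ratio r_s of the spatial convs (C -> C/r_s,
        floored, never below one channel).
    kernel_size: side of the two spatial convolutions (odd, 'same' padding).
    groups: channel-shuffle group count g; must divide the channel count.
    residual: add the input back after the spatial stage.
    pooled: use the pooled (squeeze-excite style) channel-attention variant.
    seed: weight-initialisation seed.
    """

    channel_reduction: int = 4
    spatial_reduction: int = 14
    kernel_size: int = 7
    groups: int = 4
    residual: bool = True
    pooled: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.channel_reduction < 1 or self.spatial_reduction < 1:
            raise ValueError("reduction ratios must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("spatial kernel size must be odd")
        if self.groups < 1:
            raise ValueError("groups must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "GCSAConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Permute channels by reshape-to-(g, C/g), transpose, flatten.

    For C=8, g=4 the output channel order reads input channels
    [0, 2, 4, 6, 1, 3, 5, 7].  Spatial content is untouched; shuffling with
    g followed by C/g is the identity.
    """
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape(1, *x.shape)
    B, C, H, W = x.shape
    if C % groups != 0:
        raise ValueError(f"groups={groups} does not divide C={C}")
    out = (x.reshape(B, groups, C // groups, H, W)
            .transpose(0, 2, 1, 3, 4)
            .reshape(B, C, H, W))
    return out.reshape(C, H, W) if squeeze else out


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Index array p with output[:, j] = input[:, p[j]] under channel_shuffle."""
    if channels % groups != 0:
        raise ValueError(f"groups={groups} does not divide C={channels}")
    return np.arange(channels).reshape(groups, channels // groups).T.reshape(-1)


class ChannelAttention(nn.Module):
    """Per-position channel gate: sigmoid(MLP(permute(F))) * F."""

    def __init__(self, channels: int, reduction: int = 4, pooled: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError(
                f"channel count {channels} not reducible by ratio {reduction}")
        rng = rng or np.random.default_rng()
        self.pooled = pooled
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        if self.pooled:
            vec = F.global_avg_pool(x)                        # (B, C)
            g = self.fc2(self.fc1(vec).relu()).sigmoid()
            return g.reshape(g.shape[0], g.shape[1], 1, 1)
        # C,H,W -> W,H,C: the MLP acts on the channel vector of each position
        perm = x.transpose(0, 3, 2, 1)
        g = self.fc2(self.fc1(perm).relu()).sigmoid()
        return g.transpose(0, 3, 2, 1)                        # back to C,H,W

    def forward(self, x: Tensor) -> Tensor:
        return self.gate(x) * x


class SpatialAttention(nn.Module):
    """Spatial gate: sigmoid(BN(Conv(ReLU(BN(Conv(F)))))) * F."""

    def __init__(self, channels: int, reduction: int = 14, kernel_size: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, channels // reduction)
        pad = kernel_size // 2
        rng = rng or np.random.default_rng()
        self.conv1 = nn.Conv2d(channels, hidden, kernel_size, padding=pad, rng=rng)
        self.bn1 = nn.BatchNorm2d(hidden)
        self.conv2 = nn.Conv2d(hidden, channels, kernel_size, padding=pad, rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def gate(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(h)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] < 1 or x.shape[3] < 1:
            raise ValueError("spatial attention needs H, W >= 1")
        return self.gate(x) * x


class GCSA(nn.Module):
    """channel attention -> channel shuffle -> spatial attention (+residual)."""

    def __init__(self, channels: int, cfg: GCSAConfig | None = None):
        super().__init__()
        cfg = cfg or GCSAConfig()
        if channels % cfg.groups != 0:
            raise ValueError(
                f"shuffle groups {cfg.groups} must divide channels {channels}")
        self.cfg = cfg
        self.channels = channels
        rng = np.random.default_rng(cfg.seed)
        self.channel = ChannelAttention(channels, cfg.channel_reduction,
                                        cfg.pooled, rng)
        self.spatial = SpatialAttention(channels, cfg.spatial_reduction,
                                        cfg.kernel_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        squeeze = x.ndim == 3
        if squeeze:
            x = x.reshape(1, *x.shape)
        out = self.channel(x)
        out = channel_shuffle(out, self.cfg.groups)
        out = self.spatial(out)
        if self.cfg.residual:
            out = x + out
        return out.reshape(*out.shape[1:]) if squeeze else out
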