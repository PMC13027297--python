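"""Global-feature branch: a Swin-style hierarchical windowed-attention
encoder.

Patch embedding partitions the image into non-overlapping patch_size^2
patches projected to embed_dim tokens (full profile: 224/4 = 56x56 tokens of
dim 96).  Stages alternate regular and shifted window multi-head
self-attention (window w, shift w//2, attention masked across the wrap-
around boundary, learnable relative position bias), each followed by an MLP
with GELU and pre-norm residuals; patch merging halves the grid and doubles
the channel dim between stages.  The final layer-norm'd token grid is
returned both as tokens and reshaped to a C x h x w feature map (full
profile: 768 x 7 x 7).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F
from .nn.init import trunc_normal
from .nn.tensor import stack_rows_lookup


def _relative_position_index(window: int) -> np.ndarray:
    """(w^2, w^2) index into the (2w-1)^2 relative-position-bias table."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                  indexing="ij")).reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]
    rel = rel + (window - 1)
    return rel[0] * (2 * window - 1) + rel[1]


def _shift_attn_mask(grid: int, window: int, shift: int) -> np.ndarray:
    """Additive mask (nW, w^2, w^2): -inf between wrapped-around regions."""
    img = np.zeros((grid, grid), dtype=np.int64)
    cnt = 0
    slices = (slice(0, -window), slice(-window, -shift), slice(-shift, None))
    for hs in slices:
        for ws in slices:
            img[hs, ws] = cnt
            cnt += 1
    wins = (img.reshape(grid // window, window, grid // window, window)
               .transpose(0, 2, 1, 3).reshape(-1, window * window))
    diff = wins[:, None, :] != wins[:, :, None]
    return np.where(diff, -100.0, 0.0).astype(np.float32)


class WindowAttention(nn.Module):
    def __init__(self, dim: int, window: int, heads: int, rng):
        super().__init__()
        if dim % heads != 0:
            raise ValueError("dim must be divisible by heads")
        self.window, self.heads = window, heads
        self.scale = (dim // heads) ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)
        self.qkv.weight.data = trunc_normal(rng, self.qkv.weight.shape)
        self.proj.weight.data = trunc_normal(rng, self.proj.weight.shape)
        self.rel_bias = Tensor(trunc_normal(rng, (heads, (2 * window - 1) ** 2)),
                               requires_grad=True)
        self.rel_index = _relative_position_index(window)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        Bn, N, C = x.shape
        h, d = self.heads, C // self.heads
        qkv = self.qkv(x).reshape(Bn, N, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (Bn, h, N, d)
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        bias = stack_rows_lookup(self.rel_bias, self.rel_index)  # (h, N, N)
        attn = attn + bias.reshape(1, h, N, N)
        if mask is not None:
            nW = mask.shape[0]
            attn = (attn.reshape(Bn // nW, nW, h, N, N)
                    + Tensor(mask[None, :, None]))
            attn = attn.reshape(Bn, h, N, N)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(Bn, N, C)
        return self.proj(out)


class SwinBlock(nn.Module):
    def __init__(self, dim: int, grid: int, window: int, heads: int,
                 shift: int, mlp_ratio: float, rng):
        super().__init__()
        if grid % window != 0:
            raise ValueError(f"window {window} must divide grid {grid}")
        self.dim, self.grid, self.window, self.shift = dim, grid, window, shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, window, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, dim, rng=rng)
        self.fc1.weight.data = trunc_normal(rng, self.fc1.weight.shape)
        self.fc2.weight.data = trunc_normal(rng, self.fc2.weight.shape)
        self.mask = (_shift_attn_mask(grid, window, shift) if shift else None)

    def _windows(self, x: Tensor) -> Tensor:
        B, _, C = x.shape
        g, w = self.grid, self.window
        return (x.reshape(B, g // w, w, g // w, w, C)
                 .transpose(0, 1, 3, 2, 4, 5)
                 .reshape(-1, w * w, C))

    def _unwindows(self, xw: Tensor, B: int) -> Tensor:
        g, w, C = self.grid, self.window, self.dim
        return (xw.reshape(B, g // w, g // w, w, w, C)
                  .transpose(0, 1, 3, 2, 4, 5)
                  .reshape(B, g * g, C))

    def forward(self, x: Tensor) -> Tensor:
        B, N, C = x.shape
        h = self.norm1(x)
        if self.shift:
            h = (h.reshape(B, self.grid, self.grid, C)
                  .roll((-self.shift, -self.shift), axis=(1, 2))
                  .reshape(B, N, C))
        h = self._unwindows(self.attn(self._windows(h), self.mask), B)
        if self.shift:
            h = (h.reshape(B, self.grid, self.grid, C)
                  .roll((self.shift, self.shift), axis=(1, 2))
                  .reshape(B, N, C))
        x = x + h
        m = self.fc2(self.fc1(self.norm2(x)).gelu())
        return x + m


class PatchMerging(nn.Module):
    """2x2 token merge: concat the four shifts, layer-norm, project to 2C."""

    def __init__(self, dim: int, grid: int, rng):
        super().__init__()
        self.dim, self.grid = dim, grid
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Linear(4 * dim, 2 * dim, bias=False, rng=rng)
        self.reduce.weight.data = trunc_normal(rng, self.reduce.weight.shape)

    def forward(self, x: Tensor) -> Tensor:
        B, N, C = x.shape
        g = self.grid
        x = x.reshape(B, g, g, C)
        parts = [x[:, 0::2, 0::2], x[:, 1::2, 0::2],
                 x[:, 0::2, 1::2], x[:, 1::2, 1::2]]
        merged = nn.concat(parts, axis=-1).reshape(B, (g // 2) ** 2, 4 * C)
        return self.reduce(self.norm(merged))


class SwinEncoder(nn.Module):
    """The global branch; exposes the patch map and the final feature map."""

    def __init__(self, profile, seed: int = 0,
                 mlp_ratio: float | None = None):
        super().__init__()
        self.profile = profile
        if mlp_ratio is None:
            mlp_ratio = getattr(profile, 'mlp_ratio', 4.0)
        side, patch = profile.global_input, profile.patch_size
        stages = len(profile.depths)
        if side % (patch * 2 ** (stages - 1)) != 0:
            raise ValueError(
                f"input side {side} not divisible by patch {patch} x "
                f"2^{stages - 1}")
        rng = np.random.default_rng(seed)
        self.patch_embed = nn.Conv2d(3, profile.embed_dim, patch,
                                     stride=patch, rng=rng)
        self.patch_norm = nn.LayerNorm(profile.embed_dim)
        grid = side // patch
        dim = profile.embed_dim
        self.stages = []
        for si, (depth, heads) in enumerate(zip(profile.depths,
                                                profile.num_heads)):
            blocks = []
            for bi in range(depth):
                shift = 0 if bi % 2 == 0 else profile.window_size // 2
                blocks.append(SwinBlock(dim, grid, profile.window_size,
                                        heads, shift, mlp_ratio, rng))
            stage = nn.Sequential(*blocks)
            setattr(self, f"stage{si}", stage)
            self.stages.append(stage)
            if si < stages - 1:
                merge = PatchMerging(dim, grid, rng)
                setattr(self, f"merge{si}", merge)
                grid //= 2
                dim *= 2
        self.norm = nn.LayerNorm(dim)
        self.final_grid = grid
        self.out_channels = dim
        if dim != profile.global_dim:  # pragma: no cover - profile invariant
            raise ValueError("profile global_dim inconsistent with stages")

    def forward_features(self, x: Tensor) -> dict[str, Tensor]:
        side = self.profile.global_input
        if x.shape[1] != 3 or x.shape[2] != side or x.shape[3] != side:
            raise ValueError(f"global branch expects 3x{side}x{side}, "
                             f"got {tuple(x.shape[1:])}")
        patch_map = self.patch_embed(x)               # (B, E, g, g)
        B, E, g, _ = patch_map.shape
        tokens = patch_map.reshape(B, E, g * g).transpose(0, 2, 1)
        tokens = self.patch_norm(tokens)
        for si, stage in enumerate(self.stages):
            tokens = stage(tokens)
            if si < len(self.stages) - 1:
                tokens = getattr(self, f"merge{si}")(tokens)
        tokens = self.norm(tokens)
        fg, C = self.final_grid, self.out_channels
        fmap = tokens.transpose(0, 2, 1).reshape(B, C, fg, fg)
        return {"patch_map": patch_map, "tokens": tokens, "features": fmap}

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_features(x)["features"]
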