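"""Branch encoder profiles and builders.

Two profiles are shipped:

* ``full`` — the published geometry: local branch on 3x299x299 with stem
  checkpoint 192x71x71, residual blocks 10/20/10 and a 1536-dim feature;
  global branch on 3x224x224 with 4x4 patch embedding to 96x56x56, the
  canonical Swin-Tiny stage layout (depths 2,2,6,2; heads 3,6,12,24;
  window 7) and a 768-dim feature.
* ``tiny`` — the same topology at desk scale (64-px inputs, blocks 2/2/2,
  128 + 64 dim features) for CPU training and tests.

Pre-trained weights are an optional local-file hook (`load_pretrained`);
the default is seeded random initialisation and nothing is ever downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .inception import InceptionResNetEncoder
from .nn.serialize import load_into
from .swin import SwinEncoder

__all__ = ["EncoderProfile", "FULL", "TINY", "get_profile",
           "build_local_encoder", "build_global_encoder", "load_pretrained"]


@dataclass(frozen=True)
class EncoderProfile:
    name: str
    local_input: int
    stem_checkpoint_channels: int
    local_blocks: tuple[int, int, int]
    local_dim: int
    global_input: int
    patch_size: int
    embed_dim: int
    depths: tuple[int, ...]
    num_heads: tuple[int, ...]
    window_size: int
    global_dim: int
    mlp_ratio: float = 4.0

    def __post_init__(self):
        expected = self.embed_dim * 2 ** (len(self.depths) - 1)
        if self.global_dim != expected:
            raise ValueError(f"global_dim {self.global_dim} inconsistent with "
                             f"embed_dim/depths (expect {expected})")
        if len(self.depths) != len(self.num_heads):
            raise ValueError("depths and num_heads must have equal length")


FULL = EncoderProfile(
    name="full", local_input=299, stem_checkpoint_channels=192,
    local_blocks=(10, 20, 10), local_dim=1536,
    global_input=224, patch_size=4, embed_dim=96,
    depths=(2, 2, 6, 2), num_heads=(3, 6, 12, 24), window_size=7,
    global_dim=768)

TINY = EncoderProfile(
    name="tiny", local_input=64, stem_checkpoint_channels=32,
    local_blocks=(2, 2, 2), local_dim=128,
    global_input=64, patch_size=4, embed_dim=32,
    depths=(2, 2), num_heads=(2, 4), window_size=4,
    global_dim=64, mlp_ratio=2.0)

_PROFILES = {"full": FULL, "tiny": TINY}


def get_profile(name: str) -> EncoderProfile:
    if name not in _PROFILES:
        raise ValueError(f"unknown profile {name!r}; choose from "
                         f"{sorted(_PROFILES)}")
    return _PROFILES[name]


def build_local_encoder(profile: EncoderProfile | str,
                        seed: int = 0) -> InceptionResNetEncoder:
    if isinstance(profile, str):
        profile = get_profile(profile)
    return InceptionResNetEncoder(profile, seed)


def build_global_encoder(profile: EncoderProfile | str,
                         seed: int = 0) -> SwinEncoder:
    if isinstance(profile, str):
        profile = get_profile(profile)
    return SwinEncoder(profile, seed)


def load_pretrained(encoder, weights_path: str | Path) -> dict[str, list[str]]:
    """Overwrite shape-matching parameters from a local checkpoint file.

    Returns a report dict with ``matched``, ``missing`` (own keys the file
    lacks) and ``unmatched`` (file keys the encoder lacks or whose shapes
    clash).  A missing file raises FileNotFoundError — never a download.
    """
    return load_into(encoder, weights_path, strict=False)
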