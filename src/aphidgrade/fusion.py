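"""Dual-branch severity classifier: encoders -> per-branch GCSA -> global
average pooling -> adaptive fusion -> MLP head -> 4-way softmax.

The model triple is (local encoder, global encoder, fusion/classifier).
Each branch's final spatial feature map is refined by its own GCSA block
*before* pooling (the pooled vectors have no spatial extent left for the
7x7 spatial-attention convolutions).  Adaptive fusion applies a learned
per-dimension sigmoid gate to each pooled branch vector, concatenates
(full profile: 1536 + 768 = 2304 dims) and passes one width-preserving
affine interaction layer with ReLU; both the gates and the interaction can
be switched off, reducing fusion to plain concatenation.  The head is
FC(fused -> w1) -> BN + ReLU -> Dropout -> FC(w1 -> w2) -> FC(w2 -> K).

Initialisation follows a differentiated scheme: GCSA convolutions are
Kaiming-normal (ReLU variance matching), fusion and head affine layers are
Xavier-uniform, all biases zero; the backbone encoders keep their own
seeded initialisation (or pre-trained weights when loaded from file).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

from . import nn
from .encoders import (EncoderProfile, build_global_encoder,
                       build_local_encoder, get_profile)
from .gcsa import GCSA, GCSAConfig
from .nn import Tensor, no_grad
from .nn import functional as F
from .nn.init import xavier_uniform

__all__ = ["FusionModelConfig", "AdaptiveFusion", "DualBranchClassifier",
           "assemble", "initialize_weights", "tiny_config", "full_config"]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class FusionModelConfig:
    """Assembly options for the dual-branch classifier.

    ``hybrid=False`` drops the global branch entirely (the single-branch
    CNN baseline of the ablation harness); ``use_gcsa=False`` removes both
    attention blocks.  ``gate='vector'`` gives one sigmoid gate per feature
    dimension, ``'scalar'`` a single gate per branch.
    """

    profile: str = "full"
    num_classes: int = 4
    head_widths: tuple[int, int] = (1024, 512)
    dropout: float = 0.4
    hybrid: bool = True
    use_gcsa: bool = True
    gcsa: GCSAConfig = field(default_factory=GCSAConfig)
    fusion_gates: bool = True
    fusion_interaction: bool = True
    gate: str = "vector"
    normalize_mean: tuple[float, float, float] = IMAGENET_MEAN
    normalize_std: tuple[float, float, float] = IMAGENET_STD
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.gate not in ("vector", "scalar"):
            raise ValueError("gate must be 'vector' or 'scalar'")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")

    @property
    def encoder_profile(self) -> EncoderProfile:
        return get_profile(self.profile)

    @property
    def fused_dim(self) -> int:
        p = self.encoder_profile
        return p.local_dim + (p.global_dim if self.hybrid else 0)

    @classmethod
    def from_dict(cls, d: dict) -> "FusionModelConfig":
        d = dict(d)
        if "gcsa" in d and isinstance(d["gcsa"], dict):
            d["gcsa"] = GCSAConfig.from_dict(d["gcsa"])
        for key in ("head_widths", "normalize_mean", "normalize_std"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**{k: v for k, v in d.items()
                      if k in cls.__dataclass_fields__})


def tiny_config(**overrides) -> FusionModelConfig:
    """Desk-scale model: tiny encoders, narrow head."""
    base = FusionModelConfig(profile="tiny", head_widths=(128, 64))
    return replace(base, **overrides)


def full_config(**overrides) -> FusionModelConfig:
    return replace(FusionModelConfig(), **overrides)


class AdaptiveFusion(nn.Module):
    """Sigmoid-gated concatenation with an affine interaction layer."""

    def __init__(self, local_dim: int, global_dim: int,
                 gates: bool = True, interaction: bool = True,
                 gate: str = "vector", rng=None):
        super().__init__()
        self.local_dim, self.global_dim = local_dim, global_dim
        self.out_dim = local_dim + global_dim
        self.use_gates, self.use_interaction = gates, interaction
        rng = rng or np.random.default_rng()
        if gates:
            g_out_l = local_dim if gate == "vector" else 1
            g_out_g = global_dim if gate == "vector" else 1
            self.gate_local = nn.Linear(local_dim, g_out_l, rng=rng)
            self.gate_global = nn.Linear(global_dim, g_out_g, rng=rng)
        if interaction:
            self.interact = nn.Linear(self.out_dim, self.out_dim, rng=rng)

    def forward(self, local_vec: Tensor, global_vec: Tensor) -> Tensor:
        if local_vec.shape[-1] != self.local_dim \
                or global_vec.shape[-1] != self.global_dim:
            raise ValueError(
                f"fusion expects dims ({self.local_dim}, {self.global_dim}), "
                f"got ({local_vec.shape[-1]}, {global_vec.shape[-1]})")
        if self.use_gates:
            local_vec = self.gate_local(local_vec).sigmoid() * local_vec
            global_vec = self.gate_global(global_vec).sigmoid() * global_vec
        fused = nn.concat([local_vec, global_vec], axis=-1)
        if self.use_interaction:
            fused = self.interact(fused).relu()
        return fused


class DualBranchClassifier(nn.Module):
    """End-to-end severity classifier over raw RGB images."""

    def __init__(self, cfg: FusionModelConfig):
        super().__init__()
        self.cfg = cfg
        profile = cfg.encoder_profile
        rng = np.random.default_rng(cfg.seed)
        self.local_branch = build_local_encoder(profile, seed=cfg.seed)
        if cfg.hybrid:
            self.global_branch = build_global_encoder(profile,
                                                      seed=cfg.seed + 1)
        if cfg.use_gcsa:
            self.gcsa_local = GCSA(profile.local_dim,
                                   replace(cfg.gcsa, seed=cfg.seed + 2))
            if cfg.hybrid:
                self.gcsa_global = GCSA(profile.global_dim,
                                        replace(cfg.gcsa, seed=cfg.seed + 3))
        if cfg.hybrid:
            self.fusion = AdaptiveFusion(profile.local_dim, profile.global_dim,
                                         cfg.fusion_gates,
                                         cfg.fusion_interaction,
                                         cfg.gate, rng=rng)
            fused = self.fusion.out_dim
        else:
            fused = profile.local_dim
        w1, w2 = cfg.head_widths
        self._dropout_rng = np.random.default_rng(cfg.seed + 4)
        self.head = nn.Sequential(
            nn.Linear(fused, w1, rng=rng),
            nn.BatchNorm1d(w1),
            nn.ReLU(),
            nn.Dropout(cfg.dropout, rng=self._dropout_rng),
            nn.Linear(w1, w2, rng=rng),
            nn.Linear(w2, cfg.num_classes, rng=rng),
        )
        self.fused_dim = fused
        self.capture = False
        self._cache: dict[str, Tensor] = {}

    # -- preprocessing --------------------------------------------------------
    def _resize_batch(self, images: np.ndarray, side: int) -> np.ndarray:
        if images.shape[1] == side and images.shape[2] == side:
            out = images
        else:
            out = np.empty((images.shape[0], side, side, 3), np.float32)
            for i, img in enumerate(images):
                pil = Image.fromarray(
                    np.clip(np.round(img * 255), 0, 255).astype(np.uint8))
                out[i] = np.asarray(pil.resize((side, side), Image.BILINEAR),
                                    np.float32) / 255.0
        mean = np.asarray(self.cfg.normalize_mean, np.float32)
        std = np.asarray(self.cfg.normalize_std, np.float32)
        return ((out - mean) / std).transpose(0, 3, 1, 2).astype(np.float32)

    def preprocess(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """HWC [0,1] image batch -> per-branch normalised CHW arrays."""
        images = np.asarray(images, np.float32)
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError("expected a batch of H*W*3 RGB images")
        p = self.cfg.encoder_profile
        xl = self._resize_batch(images, p.local_input)
        xg = self._resize_batch(images, p.global_input) if self.cfg.hybrid else None
        return xl, xg

    # -- forward --------------------------------------------------------------
    def forward_tensors(self, xl: Tensor, xg: Tensor | None) -> Tensor:
        """Branch inputs (already resized/normalised) -> logits (B, K)."""
        cache: dict[str, Tensor] = {}
        fl = self.local_branch.forward_features(xl)
        local_map = fl["features"]
        cache["local_map"] = local_map
        if self.cfg.use_gcsa:
            local_map = self.gcsa_local(local_map)
            cache["gcsa_local"] = local_map
        local_vec = F.global_avg_pool(local_map)
        if self.cfg.hybrid:
            if xg is None:
                raise ValueError("hybrid model needs the global-branch input")
            fg = self.global_branch.forward_features(xg)
            global_map = fg["features"]
            cache["global_map"] = global_map
            if self.cfg.use_gcsa:
                global_map = self.gcsa_global(global_map)
                cache["gcsa_global"] = global_map
            global_vec = F.global_avg_pool(global_map)
            fused = self.fusion(local_vec, global_vec)
        else:
            fused = local_vec
        logits = self.head(fused)
        if self.capture:
            for t in cache.values():
                t.retain_grad()
            self._cache = cache
        return logits

    def forward(self, images: np.ndarray) -> Tensor:
        """Raw image batch -> class-probability Tensor (rows sum to 1)."""
        xl, xg = self.preprocess(images)
        return self.forward_tensors(
            Tensor(xl), Tensor(xg) if xg is not None else None).softmax()

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                probs = self.forward(images).data
        finally:
            self.train(was_training)
        return probs

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)


def initialize_weights(model: DualBranchClassifier, seed: int = 0
                       ) -> DualBranchClassifier:
    """Re-apply the differentiated init scheme to GCSA/fusion/head.

    GCSA convolutions: Kaiming-normal.  Fusion and head affine layers:
    Xavier-uniform.  All biases zero, batch-norm at scale 1 / shift 0.
    Backbone encoders are left untouched.
    """
    rng = np.random.default_rng(seed)

    def init_gcsa(block: GCSA):
        for m in block.modules():
            if isinstance(m, nn.Conv2d):
                fan_in = int(np.prod(m.weight.shape[1:]))
                m.weight.data = nn.init.kaiming_normal(rng, m.weight.shape,
                                                       fan_in)
                if m.bias is not None:
                    m.bias.data[...] = 0.0
            elif isinstance(m, nn.Linear):
                m.weight.data = nn.init.kaiming_normal(
                    rng, m.weight.shape, fan_in=m.weight.shape[1])
                m.bias.data[...] = 0.0

    def init_affine(root: nn.Module):
        for m in root.modules():
            if isinstance(m, nn.Linear):
                m.weight.data = xavier_uniform(
                    rng, m.weight.shape,
                    fan_in=m.weight.shape[1], fan_out=m.weight.shape[0])
                if m.bias is not None:
                    m.bias.data[...] = 0.0

    if model.cfg.use_gcsa:
        init_gcsa(model.gcsa_local)
        if model.cfg.hybrid:
            init_gcsa(model.gcsa_global)
    if model.cfg.hybrid:
        init_affine(model.fusion)
    init_affine(model.head)
    for m in model.head.modules():
        if isinstance(m, (nn.BatchNorm1d, nn.BatchNorm2d)):
            m.weight.data[...] = 1.0
            m.bias.data[...] = 0.0
    return model


def assemble(cfg: FusionModelConfig, seed: int | None = None
             ) -> DualBranchClassifier:
    """Build and initialise the classifier; deterministic in (cfg, seed)."""
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    model = DualBranchClassifier(cfg)
    initialize_weights(model, seed=cfg.seed + 5)
    return model
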