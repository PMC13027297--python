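"""Dataset expansion: standard photometric augmentation plus a small
per-class generative adversarial network.

The GAN plays the usual minimax game between a generator G mapping Gaussian
noise z to images and a discriminator D scoring realness.  The
discriminator minimises ``L_D = -(E[log D(x)] + E[log(1 - D(G(z)))])``;
for the generator two printed forms are supported: the default critic-score
form ``L_G = -E[D(G(z))]`` and the classical minimax form
``L_G = E[log(1 - D(G(z)))]`` behind a config switch.  Log arguments are
epsilon-clamped at 1e-7.

The backbone is a desk-scale DCGAN flavour: the generator projects noise to
a 4x4 grid and doubles resolution with nearest-upsample + convolution
stages; the discriminator mirrors it with strided convolutions and leaky
ReLU.  One GAN is trained per severity grade (unconditional generation
within a class).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .nn import Tensor, no_grad
from .nn import functional as F
from .synthetic import GRADES, DatasetManifest, LabeledImage, save_png

__all__ = ["AugmentSpec", "GanConfig", "standard_augment",
           "discriminator_loss", "generator_loss", "Generator",
           "Discriminator", "train_gan", "augment_dataset"]

LOG_EPS = 1e-7


# ---------------------------------------------------------------------------
# standard photometric augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentSpec:
    """Random rotation, colour jitter, grayscale and channel normalisation.

    Jitter strengths s draw multiplicative factors from [1-s, 1+s];
    rotation draws degrees from [-rotation, rotation].  Normalisation is
    ``(x - mean) / std`` per channel on the [0, 1] scale.
    """

    rotation: float = 15.0
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    grayscale_prob: float = 0.1
    mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    std: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if not 0.0 <= self.grayscale_prob <= 1.0:
            raise ValueError("grayscale_prob must be in [0, 1]")


def standard_augment(image: np.ndarray, spec: AugmentSpec,
                     seed: int) -> np.ndarray:
    """Augment one H*W*3 [0,1] image; deterministic per seed."""
    rng = np.random.default_rng(seed)
    out = np.asarray(image, np.float32)
    if spec.rotation > 0:
        angle = rng.uniform(-spec.rotation, spec.rotation)
        pil = Image.fromarray(
            np.clip(np.round(out * 255), 0, 255).astype(np.uint8))
        out = np.asarray(pil.rotate(angle, Image.BILINEAR),
                         np.float32) / 255.0
    if spec.brightness > 0:
        out = out * rng.uniform(1 - spec.brightness, 1 + spec.brightness)
    if spec.contrast > 0:
        f = rng.uniform(1 - spec.contrast, 1 + spec.contrast)
        out = (out - out.mean()) * f + out.mean()
    if spec.saturation > 0:
        f = rng.uniform(1 - spec.saturation, 1 + spec.saturation)
        gray = out.mean(axis=2, keepdims=True)
        out = gray + (out - gray) * f
    if spec.grayscale_prob > 0 and rng.random() < spec.grayscale_prob:
        out = np.repeat(out.mean(axis=2, keepdims=True), 3, axis=2)
    out = np.clip(out, 0.0, 1.0)
    mean = np.asarray(spec.mean, np.float32)
    std = np.asarray(spec.std, np.float32)
    return ((out - mean) / std).astype(np.float32)


# ---------------------------------------------------------------------------
# adversarial losses (printed closed forms)
# ---------------------------------------------------------------------------

def _clamp(t: Tensor) -> Tensor:
    clipped = np.clip(t.data, LOG_EPS, 1.0 - LOG_EPS)
    out = Tensor(clipped)
    out.requires_grad = t.requires_grad
    if t.requires_grad:
        inside = ((t.data > LOG_EPS) & (t.data < 1.0 - LOG_EPS)).astype(np.float32)
        out._prev = (t,)
        out._backward = lambda g: t._accum(g * inside)
    return out


def discriminator_loss(d_real, d_fake):
    """-(mean log D(real) + mean log(1 - D(fake))); always >= 0."""
    if isinstance(d_real, Tensor) or isinstance(d_fake, Tensor):
        dr = d_real if isinstance(d_real, Tensor) else Tensor(np.asarray(d_real))
        df = d_fake if isinstance(d_fake, Tensor) else Tensor(np.asarray(d_fake))
        return -(_clamp(dr).log().mean() + (1.0 - _clamp(df)).log().mean())
    dr = np.clip(np.asarray(d_real, np.float64), LOG_EPS, 1.0 - LOG_EPS)
    df = np.clip(np.asarray(d_fake, np.float64), LOG_EPS, 1.0 - LOG_EPS)
    return float(-(np.mean(np.log(dr)) + np.mean(np.log1p(-df))))


def generator_loss(d_fake_scores, form: str = "score"):
    """'score': -mean(D(G(z))); 'minimax': mean log(1 - D(G(z)))."""
    if form not in ("score", "minimax"):
        raise ValueError("generator loss form must be 'score' or 'minimax'")
    if isinstance(d_fake_scores, Tensor):
        df = d_fake_scores
        if form == "score":
            return -df.mean()
        return (1.0 - _clamp(df)).log().mean()
    df = np.asarray(d_fake_scores, np.float64)
    if form == "score":
        return float(-np.mean(df))
    return float(np.mean(np.log1p(-np.clip(df, LOG_EPS, 1.0 - LOG_EPS))))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass
class GanConfig:
    noise_dim: int = 100
    image_side: int = 64
    epochs: int = 30
    batch_size: int = 16
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    generator_loss_form: str = "score"
    base_channels: int = 64
    per_class: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be >= 1")
        side = self.image_side
        if side < 32 or (side & (side - 1)) != 0:
            raise ValueError("image side must be a power of two >= 32")


class Generator(nn.Module):
    """Noise (B, z) -> image batch (B, 3, side, side) in [0, 1]."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        n_up = int(np.log2(cfg.image_side // 4))
        ch = cfg.base_channels * 2 ** (n_up - 1)
        self.fc = nn.Linear(cfg.noise_dim, ch * 16, rng=rng)
        self.start_ch = ch
        blocks = []
        for _ in range(n_up):
            nxt = max(ch // 2, 8)
            blocks += [nn.Conv2d(ch, nxt, 3, padding=1, bias=False, rng=rng),
                       nn.BatchNorm2d(nxt), nn.ReLU()]
            ch = nxt
        self.blocks = nn.Sequential(*blocks)
        self.n_up = n_up
        self.to_rgb = nn.Conv2d(ch, 3, 3, padding=1, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        h = self.fc(z).relu().reshape(z.shape[0], self.start_ch, 4, 4)
        for layer in self.blocks:
            if isinstance(layer, nn.Conv2d):
                h = F.upsample2x(h)
            h = layer(h)
        return self.to_rgb(h).sigmoid()

    def sample(self, n: int, seed: int) -> np.ndarray:
        """n images as (n, side, side, 3) floats in [0, 1]."""
        rng = np.random.default_rng(seed)
        z = Tensor(rng.normal(size=(n, self.cfg.noise_dim)).astype(np.float32))
        was = self.training
        self.eval()
        try:
            with no_grad():
                imgs = self.forward(z).data
        finally:
            self.train(was)
        return imgs.transpose(0, 2, 3, 1)


class Discriminator(nn.Module):
    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        super().__init__()
        side, ch = cfg.image_side, 16
        layers = [nn.Conv2d(3, ch, 3, stride=2, padding=1, rng=rng),
                  nn.LeakyReLU(0.2)]
        side //= 2
        while side > 4:
            layers += [nn.Conv2d(ch, ch * 2, 3, stride=2, padding=1,
                                 bias=False, rng=rng),
                       nn.BatchNorm2d(ch * 2), nn.LeakyReLU(0.2)]
            ch *= 2
            side //= 2
        self.conv = nn.Sequential(*layers)
        self.fc = nn.Linear(ch * side * side, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv(x)
        return self.fc(h.reshape(h.shape[0], -1)).sigmoid().reshape(-1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _to_chw(images: np.ndarray, side: int) -> np.ndarray:
    out = np.empty((len(images), side, side, 3), np.float32)
    for i, img in enumerate(images):
        if img.shape[0] == side and img.shape[1] == side:
            out[i] = img
        else:
            pil = Image.fromarray(
                np.clip(np.round(img * 255), 0, 255).astype(np.uint8))
            out[i] = np.asarray(pil.resize((side, side), Image.BILINEAR),
                                np.float32) / 255.0
    return out.transpose(0, 3, 1, 2)


def train_gan(images: np.ndarray | list, cfg: GanConfig
              ) -> tuple[Generator, dict[str, list[float]]]:
    """Alternating D/G updates on one class's images; fully seeded.

    Returns the trained generator and per-epoch mean losses
    ``{"d_loss": [...], "g_loss": [...]}``.
    """
    images = np.asarray(images, np.float32)
    if len(images) < cfg.batch_size:
        raise ValueError(f"need at least batch_size={cfg.batch_size} images, "
                         f"got {len(images)}")
    real = _to_chw(images, cfg.image_side)
    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg, rng)
    disc = Discriminator(cfg, rng)
    opt_g = nn.Adam(gen.parameters(), lr=cfg.lr_g, betas=cfg.betas)
    opt_d = nn.Adam(disc.parameters(), lr=cfg.lr_d, betas=cfg.betas)
    history: dict[str, list[float]] = {"d_loss": [], "g_loss": []}
    n = len(real)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            batch = real[order[start:start + cfg.batch_size]]
            # discriminator step (generator frozen: sample without graph)
            with no_grad():
                z = rng.normal(size=(cfg.batch_size, cfg.noise_dim))
                fake = gen(Tensor(z.astype(np.float32))).data
            d_real = disc(Tensor(batch))
            d_fake = disc(Tensor(fake))
            d_loss = discriminator_loss(d_real, d_fake)
            disc.zero_grad()
            d_loss.backward()
            opt_d.step()
            # generator step (through the discriminator)
            z = rng.normal(size=(cfg.batch_size, cfg.noise_dim))
            scores = disc(gen(Tensor(z.astype(np.float32))))
            g_loss = generator_loss(scores, cfg.generator_loss_form)
            gen.zero_grad()
            disc.zero_grad()
            g_loss.backward()
            opt_g.step()
            d_losses.append(float(d_loss.data))
            g_losses.append(float(g_loss.data))
        history["d_loss"].append(float(np.mean(d_losses)))
        history["g_loss"].append(float(np.mean(g_losses)))
    return gen, history


# ---------------------------------------------------------------------------
# manifest expansion
# ---------------------------------------------------------------------------

def balance_allocation(class_counts: dict[int, int], n_new: int
                       ) -> dict[int, int]:
    """Assign n_new records one at a time to the currently smallest class."""
    counts = dict(class_counts)
    alloc = {g: 0 for g in counts}
    for _ in range(n_new):
        g = min(counts, key=lambda k: (counts[k], k))
        counts[g] += 1
        alloc[g] += 1
    return alloc


def augment_dataset(manifest: DatasetManifest, target_total: int,
                    generators: dict[int, Generator], seed: int,
                    out_dir: str | Path | None = None,
                    emit_side: int | None = None) -> DatasetManifest:
    """Expand a manifest to ``target_total`` records with GAN images.

    New images are allocated to classes smallest-first so the expansion
    can only shrink (never grow) the spread between class counts.  Original
    records are never altered.  When ``out_dir`` is given the generated
    images are written there as PNGs (optionally resized to ``emit_side``).
    """
    current = len(manifest)
    if target_total < current:
        raise ValueError(f"target_total {target_total} below current size "
                         f"{current}")
    if target_total == current:
        return DatasetManifest(manifest.records.copy())
    alloc = balance_allocation(manifest.class_counts(), target_total - current)
    rows = []
    idx = 0
    for grade in GRADES:
        n_g = alloc.get(grade, 0)
        if n_g == 0:
            continue
        if grade not in generators:
            raise ValueError(f"no generator provided for grade {grade}")
        imgs = generators[grade].sample(n_g, seed=seed + grade)
        for j in range(n_g):
            name = f"gan_grade{grade}_{j:04d}.png"
            if out_dir is not None:
                img = imgs[j]
                if emit_side and img.shape[0] != emit_side:
                    pil = Image.fromarray(
                        np.clip(np.round(img * 255), 0, 255).astype(np.uint8))
                    img = np.asarray(
                        pil.resize((emit_side, emit_side), Image.BILINEAR),
                        np.float32) / 255.0
                save_png(LabeledImage(pixels=img, label=grade, source="gan"),
                         Path(out_dir) / name)
            rows.append({"path": name, "label": grade, "source": "gan",
                         "seed": seed + grade})
            idx += 1
    expanded = pd.concat([manifest.records,
                          pd.DataFrame(rows)], ignore_index=True)
    return DatasetManifest(expanded)
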