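"""Grad-CAM class-activation heatmaps.

For a chosen spatial layer with activations A_k, the map is
``ReLU(sum_k alpha_k A_k)`` with channel weights alpha_k equal to the
spatial mean of the class-score gradient dy_c / dA_k, normalised so the
maximum is 1 (unless the rectified map is identically zero) and bilinearly
upsampled to the input image size.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as sk_resize

from .fusion import DualBranchClassifier
from .nn import Tensor

__all__ = ["grad_cam", "cam_layers", "overlay_heatmap"]


def cam_layers(model: DualBranchClassifier) -> list[str]:
    layers = ["local_map"]
    if model.cfg.use_gcsa:
        layers.append("gcsa_local")
    if model.cfg.hybrid:
        layers.append("global_map")
        if model.cfg.use_gcsa:
            layers.append("gcsa_global")
    return layers


def grad_cam(model: DualBranchClassifier, image: np.ndarray,
             target_class: int | None = None,
             layer: str = "gcsa_local") -> np.ndarray:
    """Heatmap in [0, 1] with the spatial size of ``image`` (H, W)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("grad_cam expects one H*W*3 RGB image")
    valid = cam_layers(model)
    if layer not in valid:
        raise ValueError(f"unknown layer {layer!r}; available: {valid}")
    model.eval()
    model.capture = True
    try:
        xl, xg = model.preprocess(image[None])
        logits = model.forward_tensors(
            Tensor(xl), Tensor(xg) if xg is not None else None)
        if target_class is None:
            target_class = int(logits.data.argmax())
        onehot = np.zeros_like(logits.data)
        onehot[0, target_class] = 1.0
        logits.backward(onehot)
        act = model._cache[layer]
        grads = act.grad[0]                       # (C, h, w)
        alpha = grads.mean(axis=(1, 2))           # GAP of the gradients
        cam = np.maximum((alpha[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    finally:
        model.capture = False
        model.zero_grad()
    cam = sk_resize(cam, image.shape[:2], order=1, mode="edge",
                    anti_aliasing=False)
    if cam.max() > 0:  # normalise after interpolation so the peak is exactly 1
        cam = cam / cam.max()
    return cam.astype(np.float32)


def overlay_heatmap(image: np.ndarray, heatmap: np.ndarray,
                    alpha: float = 0.45) -> np.ndarray:
    """Blend a red-scale heatmap over the image for visual inspection."""
    colored = np.zeros_like(image)
    colored[..., 0] = heatmap
    colored[..., 2] = 0.25 * (1.0 - heatmap)
    return np.clip((1 - alpha) * image + alpha * colored, 0.0, 1.0)
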