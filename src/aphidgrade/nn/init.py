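"""Weight initialisers.

Kaiming (He) normal draws from N(0, 2/fan_in), matched to ReLU variance
propagation; Xavier (Glorot) uniform draws from U(±sqrt(6/(fan_in+fan_out))).
"""

from __future__ import annotations

import numpy as np

__all__ = ["kaiming_normal", "kaiming_uniform", "xavier_uniform",
           "trunc_normal"]


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02,
                 clip: float = 2.0) -> np.ndarray:
    vals = rng.normal(0.0, std, size=shape)
    return np.clip(vals, -clip * std, clip * std).astype(np.float32)
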