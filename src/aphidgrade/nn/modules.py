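"""Layer/module abstractions over the autodiff core (torch-like surface)."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from . import init
from .tensor import Tensor

__all__ = ["Module", "Sequential", "Identity", "Linear", "Conv2d",
           "BatchNorm2d", "BatchNorm1d", "LayerNorm", "ReLU", "LeakyReLU",
           "GELU", "Sigmoid", "Tanh", "Dropout", "MaxPool2d", "AvgPool2d",
           "Flatten"]


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def modules(self) -> Iterator["Module"]:
        for _, m in self.named_modules():
            yield m

    def get_submodule(self, path: str) -> "Module":
        mod: Module = self
        for part in path.split("."):
            if part not in mod._modules:
                raise KeyError(f"no submodule {path!r} (missing {part!r})")
            mod = mod._modules[part]
        return mod

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state ----------------------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[f"{prefix}{name}"] = p.data
        for name, b in self._buffers.items():
            out[f"{prefix}{name}"] = b
        for name, mod in self._modules.items():
            out.update(mod.state_dict(f"{prefix}{name}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True
                        ) -> tuple[list[str], list[str]]:
        """Copy matching entries in-place; returns (missing, unexpected)."""
        own = self.state_dict()
        missing = [k for k in own if k not in state]
        unexpected = [k for k in state if k not in own]
        if strict and (missing or unexpected):
            raise KeyError(f"state dict mismatch: missing={missing}, "
                           f"unexpected={unexpected}")
        self._assign(state, "")
        return missing, unexpected

    def _assign(self, state: dict[str, np.ndarray], prefix: str) -> None:
        for name, p in self._params.items():
            key = f"{prefix}{name}"
            if key in state:
                arr = np.asarray(state[key], dtype=np.float32)
                if arr.shape != p.data.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{arr.shape} vs {p.data.shape}")
                p.data[...] = arr
        for name in self._buffers:
            key = f"{prefix}{name}"
            if key in state:
                self._buffers[name][...] = state[key]
        for name, mod in self._modules.items():
            mod._assign(state, f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        self.weight = Tensor(init.kaiming_uniform(rng, (out_features, in_features),
                                                  fan_in=in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        flat = x.reshape(-1, self.in_features) if x.ndim != 2 else x
        out = flat @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        if x.ndim != 2:
            out = out.reshape(*lead, self.out_features)
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: int | tuple[int, int], stride: int = 1,
                 padding: int | tuple[int, int] = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = ((kernel_size, kernel_size) if isinstance(kernel_size, int)
                  else kernel_size)
        self.stride, self.padding = stride, padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kh * kw
        self.weight = Tensor(
            init.kaiming_normal(rng, (out_channels, in_channels, kh, kw),
                                fan_in=fan_in),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class _BatchNorm(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(num_features, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))

    def _norm(self, x: Tensor, axes: tuple[int, ...], shape) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self._buffers["running_mean"] *= (1 - self.momentum)
            self._buffers["running_mean"] += self.momentum * mu
            self._buffers["running_var"] *= (1 - self.momentum)
            self._buffers["running_var"] += self.momentum * var
            return F.batch_norm(x, self.weight, self.bias, axes, shape,
                                self.eps)
        mu = self._buffers["running_mean"].reshape(shape)
        sd = np.sqrt(self._buffers["running_var"] + self.eps).reshape(shape)
        xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.weight.reshape(*shape) + self.bias.reshape(*shape)


class BatchNorm2d(_BatchNorm):
    def forward(self, x: Tensor) -> Tensor:
        return self._norm(x, (0, 2, 3), (1, -1, 1, 1))


class BatchNorm1d(_BatchNorm):
    def forward(self, x: Tensor) -> Tensor:
        return self._norm(x, (0,), (1, -1))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Dropout(Module):
    """Inverted dropout; draws from a module-held generator so that training
    runs are reproducible given the model seed."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.p))


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x: Tensor) -> Tensor:
        return F.avg_pool2d(x, self.kernel, self.stride)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)
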