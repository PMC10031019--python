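"""Layer / module abstractions on top of the autodiff tensor engine."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "ConvTranspose2d",
    "DepthwiseConv2d",
    "Linear",
    "InstanceNorm2d",
    "BatchNorm2d",
    "Sequential",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Swish",
    "Identity",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: child tracking, parameter iteration, state dicts, train/eval."""

    def __init__(self):
        self._modules: Dict[str, "Module"] = {}
        self._params: Dict[str, Parameter] = {}
        self._buffers: Dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer." + name] = np.asarray(b).copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        expected = set(own) | {"buffer." + n for n, _ in self.named_buffers()}
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} unexpected={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(np.float32).copy()
        self._load_buffers(state, "")

    def _load_buffers(self, state: Dict[str, np.ndarray], prefix: str) -> None:
        for name in self._buffers:
            key = "buffer." + prefix + name
            arr = state[key].astype(np.float32).copy()
            self._buffers[name] = arr
            object.__setattr__(self, name, arr)
        for name, m in self._modules.items():
            m._load_buffers(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: Optional[int] = None,
                 bias: bool = True, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.weight = Parameter(_kaiming(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2, pad: int = 1,
                 bias: bool = True, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = pad
        self.weight = Parameter(_kaiming(rng, (cin, cout, k, k), cin * k * k // (stride * stride)))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, k: int = 3, stride: int = 1, pad: Optional[int] = None,
                 bias: bool = True, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.weight = Parameter(_kaiming(rng, (channels, k, k), k * k))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, din: int, dout: int, bias: bool = True, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (dout, din), din))
        self.bias = Parameter(np.zeros(dout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class InstanceNorm2d(Module):
    """Normalize over (H, W) per sample/channel; affine by default.

    Built from primitive ops so the backward pass needs no bespoke math.
    """

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
            self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc * (var + self.eps).pow(-0.5)
        if self.affine:
            return xhat * self.gamma + self.beta
        return xhat


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))
        self.register_buffer("running_mean", np.zeros((1, channels, 1, 1), dtype=np.float32))
        self.register_buffer("running_var", np.ones((1, channels, 1, 1), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            rm = (1 - self.momentum) * self._buffers["running_mean"] + self.momentum * mu.data
            rv = (1 - self.momentum) * self._buffers["running_var"] + self.momentum * var.data
            self._buffers["running_mean"] = rm.astype(np.float32)
            self._buffers["running_var"] = rv.astype(np.float32)
            object.__setattr__(self, "running_mean", self._buffers["running_mean"])
            object.__setattr__(self, "running_var", self._buffers["running_var"])
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            xhat = (x - Tensor(self._buffers["running_mean"])) * Tensor(
                (self._buffers["running_var"] + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.alpha)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Swish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x * x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
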