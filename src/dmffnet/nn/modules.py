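"""Layer abstractions over the autodiff core.

Follows the familiar module idiom: a :class:`Module` owns named parameters,
buffers and child modules, can switch between train and eval mode (which only
batch normalization cares about), and serializes to a flat ``state_dict`` of
ndarrays for checkpointing.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterator

import numpy as np

from .autograd import Tensor
from .functional import conv2d

__all__ = ["Module", "Parameter", "Conv2d", "BatchNorm2d", "Linear", "ReLU",
           "Sigmoid", "Identity", "Sequential"]


class Parameter(Tensor):
    """A tensor registered as trainable state of a module."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._parameters: OrderedDict[str, Parameter] = OrderedDict()
        self._buffers: OrderedDict[str, np.ndarray] = OrderedDict()
        self._modules: OrderedDict[str, Module] = OrderedDict()
        self.training = True

    # attribute-based registration, as users expect
    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, child in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mod_name, mod in self.named_modules():
            for p_name, p in mod._parameters.items():
                yield (f"{mod_name}.{p_name}" if mod_name else p_name), p

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._modules.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- serialization --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for mod_name, mod in self.named_modules():
            for p_name, p in mod._parameters.items():
                out[f"{mod_name}.{p_name}" if mod_name else p_name] = p.data.copy()
            for b_name, b in mod._buffers.items():
                out[f"{mod_name}.{b_name}" if mod_name else b_name] = np.array(b, copy=True)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own: dict[str, np.ndarray] = {}
        for mod_name, mod in self.named_modules():
            for p_name, p in mod._parameters.items():
                own[f"{mod_name}.{p_name}" if mod_name else p_name] = p.data
            for b_name in mod._buffers:
                own[f"{mod_name}.{b_name}" if mod_name else b_name] = mod._buffers[b_name]
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state dict mismatch; missing={sorted(missing)}, "
                           f"unexpected={sorted(unexpected)}")
        for key, arr in state.items():
            if own[key].shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}: {own[key].shape} vs {arr.shape}")
            own[key][...] = arr

    def zero_parameters(self) -> "Module":
        """Set all weights/biases to zero (BN scale stays 1) — used to realize
        the identity-at-initialization behaviour of attention gates."""
        for mod_name, mod in self.named_modules():
            for p_name, p in mod._parameters.items():
                if isinstance(mod, BatchNorm2d) and p_name == "gamma":
                    p.data[...] = 1.0
                else:
                    p.data[...] = 0.0
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2-D convolution with He-normal initialization from an explicit RNG."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *,
                 stride: int = 1, padding: int | None = None, dilation: int = 1,
                 groups: int = 1, bias: bool = True, rng: np.random.Generator):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(f"groups={groups} must divide in={in_channels} and out={out_channels}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        # default: "same" padding for the dilated kernel at stride 1
        self.padding = dilation * (kernel_size - 1) // 2 if padding is None else padding
        self.dilation = dilation
        self.groups = groups
        fan_in = in_channels // groups * kernel_size ** 2
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std,
                                           (out_channels, in_channels // groups,
                                            kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.last_output_hw: tuple[int, int] | None = None  # recorded for MAC accounting

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias, stride=self.stride,
                     padding=self.padding, dilation=self.dilation, groups=self.groups)
        self.last_output_hw = out.shape[2:]
        return out

    def macs(self) -> int:
        """Analytic multiply–accumulate count at the last recorded output size."""
        if self.last_output_hw is None:
            raise RuntimeError("run a forward pass before querying MACs")
        h, w = self.last_output_hw
        return (self.kernel_size ** 2 * self.in_channels * self.out_channels
                // self.groups) * h * w


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if c != self.num_features:
            raise ValueError(f"BatchNorm2d expected {self.num_features} channels, got {c}")
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / c
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        x_hat = (x - mu) / ((var + self.eps) ** 0.5)
        g = Tensor.make(self.gamma.data.reshape(1, c, 1, 1), (self.gamma,),
                        lambda gr: self.gamma._accum(gr.sum(axis=(0, 2, 3))))
        b = Tensor.make(self.beta.data.reshape(1, c, 1, 1), (self.beta,),
                        lambda gr: self.beta._accum(gr.sum(axis=(0, 2, 3))))
        return x_hat * g + b


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


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
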