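"""Stateless-forward modules over the autograd Tensor."""

from __future__ import annotations

import numpy as np

from cutsct.nn import autograd as ag
from cutsct.nn.autograd import Tensor


class Module:
    """Base class: parameter registry + train/eval flag."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, child in self._children.items():
            out.extend(child.named_parameters(prefix + name + "."))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, v in state.items():
            if own[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            own[k].data = np.asarray(v, dtype=np.float32)

    def __call__(self, x):
        return self.forward(x)


def _gauss(rng: np.random.Generator, shape, scale: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, pad_mode: str = "zero", rng: np.random.Generator = None):
        super().__init__()
        self.stride, self.pad, self.pad_mode = stride, pad, pad_mode
        self.weight = _gauss(rng, (out_ch, in_ch, kernel, kernel))
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if self.pad:
            x = ag.pad2d(x, self.pad, "reflect" if self.pad_mode == "reflect" else "zero")
        return ag.conv2d(x, self.weight, self.bias, self.stride)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 2,
                 pad: int = 1, output_pad: int = 1, rng: np.random.Generator = None):
        super().__init__()
        self.stride, self.pad, self.output_pad = stride, pad, output_pad
        self.weight = _gauss(rng, (in_ch, out_ch, kernel, kernel))
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias,
                                   self.stride, self.pad, self.output_pad)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator = None):
        super().__init__()
        self.weight = _gauss(rng, (in_dim, out_dim))
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class InstanceNorm2d(Module):
    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.instance_norm2d(x, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.tanh(x)


class ReflectionPad2d(Module):
    def __init__(self, pad: int):
        super().__init__()
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return ag.pad2d(x, self.pad, "reflect")


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._children[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
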