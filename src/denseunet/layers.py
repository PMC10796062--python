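"""Neural-network layers and the Adam optimizer on top of the autograd core.

Layers mirror the conventional NCHW building blocks: ``Conv2d`` (stride 1,
"same" padding by default), ``BatchNorm2d`` with running statistics,
``ReLU``, ``AvgPool2d`` (2x2/2), and ``ConvTranspose2x2`` for exact 2x
upsampling.  Weight initialization is He-normal from a caller-supplied
:class:`numpy.random.Generator`, so a fixed seed reproduces parameters
byte-for-byte.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def modules(self) -> Iterator["Module"]:
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for mod in self.modules():
            for attr in vars(mod).values():
                if isinstance(attr, Parameter):
                    params.append(attr)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        for mod in self.modules():
            mod.training = True
        return self

    def eval(self) -> "Module":
        for mod in self.modules():
            mod.training = False
        return self

    # -- flat state dict (numpy arrays only, for .npz checkpoints) ----------

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, mod in enumerate(self.modules()):
            for name, attr in vars(mod).items():
                if isinstance(attr, Parameter):
                    state[f"{i}.{name}"] = attr.data
                elif isinstance(attr, np.ndarray) and name.startswith("running_"):
                    state[f"{i}.{name}"] = attr
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, mod in enumerate(self.modules()):
            for name, attr in vars(mod).items():
                key = f"{i}.{name}"
                if isinstance(attr, Parameter):
                    if attr.data.shape != state[key].shape:
                        raise ValueError(
                            f"checkpoint mismatch at {key}: "
                            f"{state[key].shape} vs {attr.data.shape}"
                        )
                    attr.data = state[key].astype(np.float32)
                elif isinstance(attr, np.ndarray) and name.startswith("running_"):
                    setattr(mod, name, state[key].astype(np.float32))


class Conv2d(Module):
    """Stride-1 convolution; padding defaults to (kernel-1)//2 ("same")."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 pad: int | None = None, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"Conv2d expected {self.in_ch} input channels, got {x.shape[1]}"
            )
        return ag.conv2d(x, self.weight, self.bias, self.pad)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution: doubles both spatial dims."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        scale = np.sqrt(2.0 / (in_ch * 4))
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_ch, out_ch, 2, 2)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.n_ch = n_ch
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(n_ch))
        self.beta = Parameter(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class AvgPool2d(Module):
    """2x2 average pooling, stride 2."""

    def forward(self, x: Tensor) -> Tensor:
        return ag.avg_pool2d(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for mod in self.mods:
            x = mod(x)
        return x


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
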