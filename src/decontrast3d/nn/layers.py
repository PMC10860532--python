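"""Layer modules built on the autograd tape."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv3d, instance_norm, upsample2x_linear


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter collection and train/eval bookkeeping."""

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name in sorted(vars(self)):
            val = getattr(self, name)
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing {missing}, extra {extra}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """3D convolution, kernel k^3, 'same'-style padding k//2 by default."""

    def __init__(self, in_channels, out_channels, kernel_size=3, stride=1,
                 padding=None, rng=None, init_std=0.02):
        rng = np.random.default_rng() if rng is None else rng
        k = int(kernel_size)
        self.stride = int(stride)
        self.padding = (k // 2,) * 3 if padding is None else tuple(padding)
        self.weight = Parameter(
            rng.normal(0.0, init_std, size=(out_channels, in_channels, k, k, k))
        )
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class InstanceNorm3d(Module):
    def __init__(self, channels, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta, eps=self.eps)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def relu(x: Tensor) -> Tensor:
    return x.relu()


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    return x.leaky_relu(slope)


def tanh(x: Tensor) -> Tensor:
    return x.tanh()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def upsample2x(x: Tensor) -> Tensor:
    return upsample2x_linear(x)
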