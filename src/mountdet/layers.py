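"""Layer/module system on top of :mod:`mountdet.autodiff`.

Mirrors the familiar ``Module``/``Parameter`` pattern: modules own parameters
and submodules, expose ``parameters()`` / ``named_parameters()`` walks, and a
train/eval flag that switches batch-norm statistics.

Each leaf layer also knows its *analytic* trainable-parameter count
(``param_count``), computed from hyper-parameters alone — convolution weights
``k*k*c_in*c_out/groups``, declared biases, and ``2*C`` per normalisation
layer.  This is deliberately independent of the stored arrays so tests can
cross-check it against a brute-force walk of the actual weight buffers.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the global weight-initialisation RNG."""
    global _rng
    _rng = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: attribute-registered parameters and submodules."""

    def __init__(self):
        self.training = True

    # attribute walk keeps registration implicit, like the common frameworks
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield (f"{prefix}{name}", value)
        for cname, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def param_count(self) -> int:
        """Analytic trainable-parameter count (sums over children)."""
        return sum(child.param_count() for _, child in self._children())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- flat state dict (numpy arrays) --------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(arr, dtype=np.float32)
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unknown entry {name!r} in state dict")

    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and not isinstance(value, Parameter):
                yield (f"{prefix}{name}", value)
        for cname, child in self._children():
            yield from child._named_buffers(prefix=f"{prefix}{cname}.")


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 bias: bool = False):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"kernel must be odd, got {kernel}")
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels not divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.groups = groups
        fan_in = in_channels // groups * kernel * kernel
        w = _rng.normal(0.0, np.sqrt(2.0 / fan_in),
                        size=(out_channels, in_channels // groups, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)

    def param_count(self) -> int:
        n = self.kernel * self.kernel * self.in_channels * self.out_channels // self.groups
        if self.bias is not None:
            n += self.out_channels
        return n


class BatchNorm2d(Module):
    """Per-channel affine normalisation; running stats are non-trainable."""

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        if self.training:
            out, (mean, var) = ad.batchnorm2d(x, self.weight, self.bias, self.eps)
            m = float(np.prod([x.shape[0], x.shape[2], x.shape[3]]))
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * (m / max(m - 1.0, 1.0))
            self.running_var += self.momentum * (unbiased - self.running_var)
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.weight.data * inv
        shift = self.bias.data - self.running_mean * scale
        if self.weight.requires_grad and ad._grad_enabled:
            # keep the affine parameters on the tape even in eval mode
            w = ad.reshape(self.weight, (1, self.channels, 1, 1))
            b = ad.reshape(self.bias, (1, self.channels, 1, 1))
            xhat = (x - self.running_mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
            return xhat * w + b
        return ad.affine_channels(x, scale, shift)

    def param_count(self) -> int:
        return 2 * self.channels


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        w = _rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out

    def param_count(self) -> int:
        n = self.in_features * self.out_features
        if self.bias is not None:
            n += self.out_features
        return n


class SiLU(Module):
    def forward(self, x):
        return ad.silu(x)

    def param_count(self) -> int:
        return 0


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)

    def param_count(self) -> int:
        return 0


class Identity(Module):
    def forward(self, x):
        return x

    def param_count(self) -> int:
        return 0


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int = 1):
        super().__init__()
        self.kernel = kernel
        self.stride = stride

    def forward(self, x):
        return ad.maxpool2d(x, self.kernel, stride=self.stride)

    def param_count(self) -> int:
        return 0


class UpsampleNearest2x(Module):
    def forward(self, x):
        return ad.upsample_nearest2(x)

    def param_count(self) -> int:
        return 0


def brute_force_param_count(module: Module) -> int:
    """Independent oracle: walk every weight container, sum element counts."""
    return sum(p.data.size for p in module.parameters())
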