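"""Trainable building blocks: convolution, batch norm, residual and
attention-residual units.

The residual unit is a pre-activation bottleneck: three BN-ReLU-conv sets
(channel-reducing 1-kernel, spatial k-kernel at C/4 width, channel-restoring
1-kernel) plus an identity path, which is a 1-kernel convolution whenever
the input and output channel counts differ.  This keeps the full-size 3D
network within its few-million-parameter budget while preserving the
three-convolution structure.

The attention module splits into a trunk branch (one residual unit) and a
soft-mask branch (a depth-D max-pool encoder / nearest-upsample decoder of
residual units with long-range additive skips, closed by two 1-kernel
convolutions and a sigmoid); its output is ``(1 + S(x)) * F(x)``.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Minimal module base: parameter discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for c in self.children():
            yield from c.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = []
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((f"{prefix}{name}", v))
            elif isinstance(v, Module):
                out += v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out += item.named_parameters(f"{prefix}{name}.{i}.")
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for name, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                out.append((f"{prefix}{name}", v))
            elif isinstance(v, Module):
                out += v.named_buffers(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out += item.named_buffers(f"{prefix}{name}.{i}.")
        return out

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data for n, p in self.named_parameters()}
        state.update({f"buffer:{n}": b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = np.asarray(value, dtype=np.float32)


def count_parameters(module: Module) -> int:
    """Total number of trainable scalars (incl. BN scale/shift)."""
    return int(sum(p.size for p in module.parameters()))


class Conv(Module):
    """Stride-1 same-padding convolution, He-normal initialised."""

    def __init__(self, ndim: int, cin: int, cout: int, kernel: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        kshape = (kernel,) * ndim
        fan_in = cin * int(np.prod(kshape))
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, kshape + (cin, cout)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv(x, self.w, self.b)


class BatchNorm(Module):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class BNReLUConv(Module):
    """One pre-activation set: batch norm, ReLU, convolution."""

    def __init__(self, ndim: int, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.bn = BatchNorm(cin)
        self.conv = Conv(ndim, cin, cout, kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(F.relu(self.bn(x)))


class ResidualBlock(Module):
    """Pre-activation bottleneck residual unit: out = identity(x) + f(x)."""

    def __init__(self, ndim: int, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        mid = max(cout // 4, 1)
        self.set1 = BNReLUConv(ndim, cin, mid, 1, rng)
        self.set2 = BNReLUConv(ndim, mid, mid, kernel, rng)
        self.set3 = BNReLUConv(ndim, mid, cout, 1, rng)
        self.identity = Conv(ndim, cin, cout, 1, rng) if cin != cout else None

    def forward(self, x: Tensor) -> Tensor:
        branch = self.set3(self.set2(self.set1(x)))
        shortcut = self.identity(x) if self.identity is not None else x
        return shortcut + branch


def _pool_factors(spatial: tuple[int, ...]) -> tuple[int, ...]:
    """Halve every even axis; leave collapsed (size-1) axes alone."""
    factors = []
    for s in spatial:
        if s == 1:
            factors.append(1)
        elif s % 2 == 0:
            factors.append(2)
        else:
            raise ValueError(f"spatial size {s} is odd and >1; cannot pool by 2")
    return tuple(factors)


class AttentionModule(Module):
    """Attention-residual module: output = (1 + S(x)) * F(x).

    ``depth`` counts the nested pool/upsample levels of the soft-mask
    encoder-decoder; at depth 0 the mask branch has no pooling.  For testing
    the residual-attention identity, ``soft_mask_override`` may be set to a
    constant that replaces S(x).
    """

    def __init__(self, ndim: int, channels: int, depth: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if depth < 0:
            raise ValueError("attention depth must be >= 0")
        self.ndim = ndim
        self.depth = depth
        self.trunk = ResidualBlock(ndim, channels, channels, kernel, rng)
        self.mask_down = [ResidualBlock(ndim, channels, channels, kernel, rng) for _ in range(depth)]
        self.mask_skip = [ResidualBlock(ndim, channels, channels, kernel, rng) for _ in range(depth)]
        self.mask_up = [ResidualBlock(ndim, channels, channels, kernel, rng) for _ in range(depth)]
        self.mask_mid = ResidualBlock(ndim, channels, channels, kernel, rng)
        self.mask_out1 = Conv(ndim, channels, channels, 1, rng)
        self.mask_out2 = Conv(ndim, channels, channels, 1, rng)
        self.soft_mask_override: float | None = None

    def soft_mask(self, x: Tensor) -> Tensor:
        h = x
        skips = []
        factors = []
        for d in range(self.depth):
            f = _pool_factors(h.shape[1:-1])
            skips.append(self.mask_skip[d](h))
            factors.append(f)
            h = self.mask_down[d](F.max_pool(h, f))
        h = self.mask_mid(h)
        for d in reversed(range(self.depth)):
            h = F.upsample_nearest(self.mask_up[d](h), factors[d])
            h = h + skips[d]
        return F.sigmoid(self.mask_out2(self.mask_out1(h)))

    def forward(self, x: Tensor) -> Tensor:
        trunk = self.trunk(x)
        if self.soft_mask_override is not None:
            return (1.0 + float(self.soft_mask_override)) * trunk
        mask = self.soft_mask(x)
        return (1.0 + mask) * trunk
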