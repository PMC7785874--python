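"""Residual attention-aware U-Net builders (2D planar and 3D volumetric).

Both networks share one layer plan, parameterized by the base channel width
``c`` (32 by default):

* encoder: stem conv (1→c), then five pool+residual stages widening
  c → c → 2c → 4c → 8c → 16c, plus a second 16c residual block at the bottom;
* decoder: nearest-neighbour upsampling mirrored against the encoder pools,
  where each skip connection passes through an attention-residual module
  (depths 0,1,2,3 from the deepest skip to the shallowest) and is
  concatenated with the upsampled path before a residual block;
* head: a conv on the final concatenation and a 1-kernel conv to a single
  sigmoid probability channel.

Pooling halves every even spatial axis and leaves collapsed (size-1) axes
untouched, so anisotropic shapes such as 224×224×32 (whose axial extent
reaches 1 at the bottom) are handled; the decoder upsampling factors mirror
the recorded pooling factors exactly, which guarantees shape-conserving
skip connections for any admissible input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, ShapeError
from .ndnn import functional as F
from .ndnn.modules import (
    AttentionModule,
    BatchNorm,
    Conv,
    Module,
    ResidualBlock,
    _pool_factors,
)
from .ndnn.modules import count_parameters as _count
from .ndnn.tensor import Tensor

ATTENTION_DEPTHS = (0, 1, 2, 3)  # Att1..Att4, deepest skip first


@dataclass(frozen=True)
class ResidualBlockSpec:
    in_channels: int
    out_channels: int
    kernel_size: int = 3

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel size must be odd")


@dataclass(frozen=True)
class AttentionModuleSpec:
    channels: int
    depth: int
    kernel_size: int = 3

    def __post_init__(self):
        if self.channels < 1:
            raise ConfigurationError("channels must be >= 1")
        if self.depth < 0:
            raise ConfigurationError("depth must be >= 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of an RA-UNet variant."""

    dimensionality: int = 3
    base_channels: int = 32
    kernel_size: int = 3
    input_shape: tuple[int, ...] | None = None  # advisory default shape
    seed: int = 0

    def __post_init__(self):
        if self.dimensionality not in (2, 3):
            raise ConfigurationError("dimensionality must be 2 or 3")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel size must be odd")

    def default_input_shape(self) -> tuple[int, ...]:
        if self.input_shape is not None:
            return tuple(self.input_shape)
        return (224, 224, 32) if self.dimensionality == 3 else (256, 256)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["input_shape"] is not None:
            d["input_shape"] = list(d["input_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        if d.get("input_shape") is not None:
            d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)

    def spec_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def residual_block(x: Tensor, spec: ResidualBlockSpec, seed: int = 0) -> Tensor:
    """Apply a freshly initialized residual unit (functional convenience)."""
    if x.shape[-1] != spec.in_channels:
        raise ConfigurationError(
            f"input has {x.shape[-1]} channels, spec expects {spec.in_channels}"
        )
    rng = np.random.default_rng(seed)
    block = ResidualBlock(x.ndim - 2, spec.in_channels, spec.out_channels,
                          spec.kernel_size, rng)
    return block(x)


def attention_module(x: Tensor, spec: AttentionModuleSpec, seed: int = 0) -> Tensor:
    """Apply a freshly initialized attention-residual module."""
    if x.shape[-1] != spec.channels:
        raise ConfigurationError(
            f"input has {x.shape[-1]} channels, spec expects {spec.channels}"
        )
    spatial = x.shape[1:-1]
    for _ in range(spec.depth):
        spatial = tuple(s // f for s, f in zip(spatial, _pool_factors(spatial)))
    rng = np.random.default_rng(seed)
    mod = AttentionModule(x.ndim - 2, spec.channels, spec.depth, spec.kernel_size, rng)
    return mod(x)


def _simulate_pool_chain(spatial: tuple[int, ...], n_pools: int) -> list[tuple[int, ...]]:
    """Pool factors per stage, or raise if some axis becomes odd and > 1."""
    chain = []
    cur = tuple(spatial)
    for i in range(n_pools):
        try:
            f = _pool_factors(cur)
        except ValueError as exc:
            raise ConfigurationError(
                f"input spatial shape {spatial} is not poolable at stage {i + 1}: {exc}"
            ) from None
        chain.append(f)
        cur = tuple(s // x for s, x in zip(cur, f))
    return chain


class RAUNet(Module):
    """The residual attention-aware U-Net (dimensionality per its spec)."""

    N_POOLS = 5

    def __init__(self, spec: NetworkSpec):
        super().__init__()
        self.spec = spec
        nd, c, k = spec.dimensionality, spec.base_channels, spec.kernel_size
        rng = np.random.default_rng(spec.seed)
        widths = [c, c, 2 * c, 4 * c, 8 * c, 16 * c]  # after conv1, res1..res5
        self.conv1 = Conv(nd, 1, c, k, rng)
        self.bn1 = BatchNorm(c)
        self.res1 = ResidualBlock(nd, c, c, k, rng)
        self.res2 = ResidualBlock(nd, c, 2 * c, k, rng)
        self.res3 = ResidualBlock(nd, 2 * c, 4 * c, k, rng)
        self.res4 = ResidualBlock(nd, 4 * c, 8 * c, k, rng)
        self.res5 = ResidualBlock(nd, 8 * c, 16 * c, k, rng)
        self.res6 = ResidualBlock(nd, 16 * c, 16 * c, k, rng)
        # decoder: attention modules on the skips, deepest first
        self.att1 = AttentionModule(nd, 8 * c, ATTENTION_DEPTHS[0], k, rng)
        self.att2 = AttentionModule(nd, 4 * c, ATTENTION_DEPTHS[1], k, rng)
        self.att3 = AttentionModule(nd, 2 * c, ATTENTION_DEPTHS[2], k, rng)
        self.att4 = AttentionModule(nd, c, ATTENTION_DEPTHS[3], k, rng)
        self.res7 = ResidualBlock(nd, 24 * c, 8 * c, k, rng)
        self.res8 = ResidualBlock(nd, 12 * c, 4 * c, k, rng)
        self.res9 = ResidualBlock(nd, 6 * c, 2 * c, k, rng)
        self.res10 = ResidualBlock(nd, 3 * c, c, k, rng)
        self.conv2 = Conv(nd, 2 * c, c, k, rng)
        self.bn2 = BatchNorm(c)
        self.conv3 = Conv(nd, c, 1, 1, rng)
        del widths

    # -- shape admission ---------------------------------------------------
    def validate_input_shape(self, spatial: tuple[int, ...]) -> None:
        nd = self.spec.dimensionality
        if len(spatial) != nd:
            raise ShapeError(f"expected {nd} spatial axes, got {spatial}")
        _simulate_pool_chain(spatial, self.N_POOLS)

    def forward(self, x: Tensor, taps: dict | None = None) -> Tensor:
        if x.ndim != self.spec.dimensionality + 2 or x.shape[-1] != 1:
            raise ShapeError(
                f"expected (N, *spatial, 1) with {self.spec.dimensionality} spatial "
                f"axes, got {x.shape}"
            )
        self.validate_input_shape(x.shape[1:-1])

        def tap(name, t):
            if taps is not None:
                taps[name] = t.shape

        tap("Input", x)
        c1 = F.relu(self.bn1(self.conv1(x)))
        tap("Conv1", c1)
        h = c1
        factors: list[tuple[int, ...]] = []
        enc_out = []
        for i, res in enumerate([self.res1, self.res2, self.res3, self.res4, self.res5], 1):
            f = _pool_factors(h.shape[1:-1])
            factors.append(f)
            h = F.max_pool(h, f)
            tap(f"Pool{i}", h)
            h = res(h)
            tap(f"Res{i}", h)
            enc_out.append(h)
        h = self.res6(h)
        tap("Res6", h)

        r1, r2, r3, r4, _ = enc_out
        h = F.upsample_nearest(h, factors[4])
        tap("Up1", h)
        a = self.att1(r4)
        tap("Att1", a)
        h = self.res7(F.concat([h, a]))
        tap("Res7", h)
        h = F.upsample_nearest(h, factors[3])
        tap("Up2", h)
        a = self.att2(r3)
        tap("Att2", a)
        h = self.res8(F.concat([h, a]))
        tap("Res8", h)
        h = F.upsample_nearest(h, factors[2])
        tap("Up3", h)
        a = self.att3(r2)
        tap("Att3", a)
        h = self.res9(F.concat([h, a]))
        tap("Res9", h)
        h = F.upsample_nearest(h, factors[1])
        tap("Up4", h)
        a = self.att4(r1)
        tap("Att4", a)
        h = self.res10(F.concat([h, a]))
        tap("Res10", h)
        h = F.upsample_nearest(h, factors[0])
        tap("Up5", h)
        h = F.relu(self.bn2(self.conv2(F.concat([h, c1]))))
        tap("Conv2", h)
        out = F.sigmoid(self.conv3(h))
        tap("Conv3", out)
        return out

    def probe_shapes(self, spatial: tuple[int, ...] | None = None) -> dict[str, tuple[int, ...]]:
        """Run one forward pass and record every named layer's output shape."""
        from .ndnn.tensor import no_grad

        spatial = tuple(spatial) if spatial is not None else self.spec.default_input_shape()
        x = Tensor(np.zeros((1,) + spatial + (1,), dtype=np.float32))
        taps: dict[str, tuple[int, ...]] = {}
        mode = self.training
        self.eval()
        with no_grad():
            self.forward(x, taps=taps)
        if mode:
            self.train()
        return taps


def build_raunet2(spec: NetworkSpec | None = None) -> RAUNet:
    """Build the 3D volumetric network (liver/tumor VOI segmentation)."""
    spec = spec or NetworkSpec(dimensionality=3)
    if spec.dimensionality != 3:
        raise ConfigurationError("the volumetric builder requires dimensionality == 3")
    return RAUNet(spec)


def build_raunet1(spec: NetworkSpec | None = None) -> RAUNet:
    """Build the 2D planar network (coarse slice-wise liver localization)."""
    spec = spec or NetworkSpec(dimensionality=2, input_shape=(256, 256))
    if spec.dimensionality != 2:
        raise ConfigurationError("the planar builder requires dimensionality == 2")
    return RAUNet(spec)


def count_parameters(network: Module) -> int:
    """Number of trainable scalars, including batch-norm scale/shift."""
    return _count(network)


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON sidecar holding the NetworkSpec and its hash
# ---------------------------------------------------------------------------

def save_checkpoint(model: RAUNet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez(path, **model.state_dict())
    sidecar = {"network_spec": model.spec.to_dict(), "spec_hash": model.spec.spec_hash()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> RAUNet:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text())
    spec = NetworkSpec.from_dict(sidecar["network_spec"])
    if spec.spec_hash() != sidecar["spec_hash"]:
        raise ConfigurationError(f"checkpoint spec hash mismatch in {sidecar_path}")
    model = RAUNet(spec)
    with np.load(path) as state:
        model.load_state_dict({k: state[k] for k in state.files})
    return model
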