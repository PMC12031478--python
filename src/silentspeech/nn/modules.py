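"""Network building blocks and the three architectures.

* :class:`FEN` — the Feature Extraction Network: stacked blocks of
  Conv1d -> tanh -> BatchNorm1d -> adaptive average pooling, each block
  pooling to a spec-fixed temporal length so output shapes are independent
  of input length (that invariance is what lets streams with different
  sampling rates share a fusion network).
* :class:`CN` — the Classification Network: two fully connected layers
  reducing the flattened FEN output to a 256-dimensional feature vector,
  with an optional softmax classification layer on top.
* :class:`PMLDF` — Parallel Multi-Layer Data Fusion: one FEN per sensor
  stream plus a central fusion stack; fusion block l consumes the channel
  concatenation of (fusion block l-1 output, every stream's block-l
  output), all pooled to the fusion block's temporal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autograd import Tensor, adaptive_avg_pool1d, concat, conv1d


class Module:
    """Tiny torch-like module base: parameter discovery + train/eval mode."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and running arrays, for checkpoint copy."""
        arrs = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrs.extend([m.running_mean, m.running_var])
        return arrs

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        for a, s in zip(self.state_arrays(), state, strict=True):
            a[...] = s


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True,
                 padding: int | None = None):
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size
        self.weight = Tensor(_uniform_init(
            rng, (out_channels, in_channels, kernel_size), fan_in),
            requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, (out_channels,), fan_in),
                           requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = Tensor(_uniform_init(
            rng, (in_features, out_features), in_features), requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, (out_features,), in_features),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalisation over (batch, length) per channel for (B, C, L)."""

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, num_features, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, num_features, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, num_features, 1))
        self.running_var = np.ones((1, num_features, 1))
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * \
                Tensor((self.running_var + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


@dataclass(frozen=True)
class FENSpec:
    """Architecture of one Feature Extraction Network.

    ``pooled_lengths`` are the per-block adaptive-pool targets; they must be
    non-increasing and fully determine all output shapes, independent of
    input length.  Defaults: 7 blocks, channels doubling from 16 capped at
    64, kernel 7, lengths halving from 256 down to a floor of 16.
    """
    n_layers: int = 7
    channels: tuple[int, ...] = ()
    kernel_size: int = 7
    pooled_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        object.__setattr__(self, "channels", tuple(self.channels) or tuple(
            min(16 * 2 ** i, 64) for i in range(self.n_layers)))
        object.__setattr__(self, "pooled_lengths",
                           tuple(self.pooled_lengths) or tuple(
            max(256 // 2 ** i, 16) for i in range(self.n_layers)))
        if len(self.channels) != self.n_layers or \
                len(self.pooled_lengths) != self.n_layers:
            raise ValueError("channels/pooled_lengths must match n_layers")
        if any(b > a for a, b in zip(self.pooled_lengths,
                                     self.pooled_lengths[1:])):
            raise ValueError("pooled lengths must be non-increasing")

    @property
    def out_features(self) -> int:
        return self.channels[-1] * self.pooled_lengths[-1]


def reduced_fen_spec(n_layers: int = 4) -> FENSpec:
    """Desk-scale FEN: fewer blocks, aggressive early pooling."""
    lengths = {4: (128, 32, 16, 8), 3: (64, 16, 8), 2: (32, 8)}.get(
        n_layers, tuple(max(128 // 2 ** i, 8) for i in range(n_layers)))
    return FENSpec(n_layers=n_layers,
                   channels=tuple(min(16 * 2 ** i, 64) for i in range(n_layers)),
                   kernel_size=7, pooled_lengths=lengths)


class FENBlock(Module):
    def __init__(self, cin: int, cout: int, kernel: int, pooled: int,
                 rng: np.random.Generator, bias: bool = True):
        self.conv = Conv1d(cin, cout, kernel, rng, bias=bias)
        self.bn = BatchNorm1d(cout)
        self.pooled = pooled

    def __call__(self, x: Tensor) -> Tensor:
        return adaptive_avg_pool1d(self.bn(self.conv(x).tanh()), self.pooled)


class FEN(Module):
    """Feature Extraction Network; ``forward`` returns all block outputs."""

    def __init__(self, spec: FENSpec, rng: np.random.Generator,
                 in_channels: int = 1, bias: bool = True):
        self.spec = spec
        self.blocks = [
            FENBlock(in_channels if i == 0 else spec.channels[i - 1],
                     spec.channels[i], spec.kernel_size,
                     spec.pooled_lengths[i], rng, bias=bias)
            for i in range(spec.n_layers)]

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.shape[-1] < self.spec.pooled_lengths[0]:
            raise ValueError(
                f"input length {x.shape[-1]} shorter than first pooled length "
                f"{self.spec.pooled_lengths[0]}")
        outs: list[Tensor] = []
        for blk in self.blocks:
            x = blk(x)
            outs.append(x)
        return outs

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)[-1]


class CN(Module):
    """Classification Network: two FC layers to a 256-dim feature vector,
    plus an optional class-score layer."""

    def __init__(self, in_features: int, rng: np.random.Generator,
                 embed_dim: int = 256, hidden: int | None = None,
                 n_classes: int | None = None):
        hidden = hidden if hidden is not None else max(embed_dim, in_features // 2)
        self.fc1 = Linear(in_features, hidden, rng)
        self.fc2 = Linear(hidden, embed_dim, rng)
        self.head = Linear(embed_dim, n_classes, rng) if n_classes else None
        self.embed_dim = embed_dim

    def embed(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        flat = x.reshape(B, -1)
        return self.fc2(self.fc1(flat).tanh())

    def __call__(self, x: Tensor) -> Tensor:
        z = self.embed(x)
        return self.head(z) if self.head is not None else z


@dataclass(frozen=True)
class PMLDFSpec:
    """One FEN spec per sensor stream plus the fusion stack's spec.

    The fusion stack has ``fusion_spec.n_layers`` blocks, at most as deep as
    the shallowest stream FEN; fusion block l pools every input to
    ``fusion_spec.pooled_lengths[l]``.
    """
    stream_specs: tuple[FENSpec, ...]
    fusion_spec: FENSpec

    def __post_init__(self) -> None:
        if len(self.stream_specs) < 2:
            raise ValueError("PMLDF needs at least 2 sensor streams")
        min_depth = min(s.n_layers for s in self.stream_specs)
        if self.fusion_spec.n_layers > min_depth:
            raise ValueError(
                f"fusion depth {self.fusion_spec.n_layers} exceeds the "
                f"shallowest stream FEN ({min_depth})")


def default_pmldf_spec(n_streams: int = 2, n_layers: int = 4) -> PMLDFSpec:
    spec = reduced_fen_spec(n_layers)
    return PMLDFSpec(stream_specs=(spec,) * n_streams, fusion_spec=spec)


class PMLDF(Module):
    """Parallel multi-layer data fusion network (embedding trunk).

    ``forward`` returns the fused 256-dim embedding (via the CN); use
    ``n_classes`` to add a softmax head for plain classification.
    """

    def __init__(self, spec: PMLDFSpec, rng: np.random.Generator,
                 embed_dim: int = 256, n_classes: int | None = None):
        self.spec = spec
        self.streams = [FEN(s, rng) for s in spec.stream_specs]
        fs = spec.fusion_spec
        self.fusion_blocks: list[FENBlock] = []
        for l in range(fs.n_layers):
            cin = sum(s.channels[l] for s in spec.stream_specs)
            if l > 0:
                cin += fs.channels[l - 1]
            self.fusion_blocks.append(
                FENBlock(cin, fs.channels[l], fs.kernel_size,
                         fs.pooled_lengths[l], rng))
        self.cn = CN(fs.out_features, rng, embed_dim=embed_dim,
                     n_classes=n_classes)

    def fuse(self, xs: Sequence[Tensor]) -> Tensor:
        """Fused final feature map for one batch of paired streams."""
        if len(xs) != len(self.streams):
            raise ValueError(
                f"expected {len(self.streams)} streams, got {len(xs)}")
        batches = {x.shape[0] for x in xs}
        if len(batches) != 1:
            raise ValueError(f"unpaired batch sizes across streams: {batches}")
        per_stream = [fen.forward(x) for fen, x in zip(self.streams, xs)]
        fused: Tensor | None = None
        fs = self.spec.fusion_spec
        for l, blk in enumerate(self.fusion_blocks):
            length = fs.pooled_lengths[l]
            inputs = []
            if fused is not None:
                inputs.append(adaptive_avg_pool1d(fused, length)
                              if fused.shape[-1] != length else fused)
            for outs in per_stream:
                o = outs[l]
                inputs.append(adaptive_avg_pool1d(o, length)
                              if o.shape[-1] != length else o)
            fused = blk(concat(inputs, axis=1))
        assert fused is not None
        return fused

    def embed(self, xs: Sequence[Tensor]) -> Tensor:
        return self.cn.embed(self.fuse(xs))

    def __call__(self, xs: Sequence[Tensor]) -> Tensor:
        return self.cn(self.fuse(xs))


class CNNModel(Module):
    """Single-stream FEN + CN (the plain convolutional classifier)."""

    def __init__(self, spec: FENSpec, rng: np.random.Generator,
                 embed_dim: int = 256, n_classes: int | None = None,
                 in_channels: int = 1):
        self.fen = FEN(spec, rng, in_channels=in_channels)
        self.cn = CN(spec.out_features, rng, embed_dim=embed_dim,
                     n_classes=n_classes)

    def embed(self, x: Tensor) -> Tensor:
        return self.cn.embed(self.fen(x))

    def __call__(self, x: Tensor) -> Tensor:
        return self.cn(self.fen(x))
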