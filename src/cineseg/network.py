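"""Declarative 3D U-Net builder and whole-volume prediction.

The architecture is the classic encoder–decoder with skip connections:
a contracting path of ``n_levels`` resolution levels, each with two 3x3x3
convolutions (conv -> ReLU -> batch norm) and 2x2x2 max pooling between
levels, and a symmetric expanding path using nearest-neighbor 2x
upsampling and skip concatenation, closed by a 1x1x1 convolution to
``n_classes`` channels and a voxel-wise softmax.  With the default widths
(16 -> 32 -> 64 -> 128) the model has about 1.46 million trainable
parameters, small enough for real-time volumetric inference.

Training uses a batch of a single 3D volume, so batch normalization is
computed from per-volume statistics in both training and inference
(instance-norm behavior); inference is therefore deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    AMSGrad,
    Conv3d,
    InstanceBatchNorm,
    MaxPool3d,
    NearestUpsample3d,
    ReLU,
    softmax,
)


@dataclass(frozen=True)
class NetworkConfig:
    """Declarative U-Net description.

    ``channel_growth`` multiplies the channel width at each deeper level;
    the decoder mirrors the encoder widths.
    """

    n_levels: int = 4
    base_channels: int = 16
    channel_growth: int = 2
    n_classes: int = 9
    in_channels: int = 1
    conv_kernel: int = 3
    pool_kernel: int = 2

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def level_channels(self) -> list[int]:
        return [self.base_channels * self.channel_growth ** i for i in range(self.n_levels)]

    @property
    def divisor(self) -> int:
        """Spatial extents must be divisible by this (pooling depth)."""
        return self.pool_kernel ** (self.n_levels - 1)


class _ConvBlock:
    """Two (conv -> ReLU -> BN) stages at one resolution level."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.layers = [
            Conv3d(c_in, c_out, kernel, rng), ReLU(), InstanceBatchNorm(c_out),
            Conv3d(c_out, c_out, kernel, rng), ReLU(), InstanceBatchNorm(c_out),
        ]

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet3D:
    """The network with explicit forward/backward passes."""

    def __init__(self, config: NetworkConfig, seed: int):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        ch = config.level_channels
        k = config.conv_kernel

        self.enc = []
        c_prev = config.in_channels
        for c in ch:
            self.enc.append(_ConvBlock(c_prev, c, k, rng))
            c_prev = c
        self.pools = [MaxPool3d() for _ in range(config.n_levels - 1)]
        self.ups = [NearestUpsample3d() for _ in range(config.n_levels - 1)]
        self.dec = []
        for i in range(config.n_levels - 2, -1, -1):
            self.dec.append(_ConvBlock(ch[i + 1] + ch[i], ch[i], k, rng))
        self.head = Conv3d(ch[0], config.n_classes, 1, rng)

    def parameters(self):
        params = []
        for b in self.enc + self.dec:
            params.extend(b.parameters())
        params.extend(self.head.parameters())
        return params

    def forward(self, x: np.ndarray) -> np.ndarray:
        """``(D,H,W)`` or ``(1,D,H,W)`` input -> ``(n_classes,D,H,W)`` logits."""
        if x.ndim == 3:
            x = x[None]
        x = x.astype(np.float32)
        self._check_shape(x.shape[1:])
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_channels = []
        for i, block in enumerate(self.dec):
            up = self.ups[i].forward(x)
            skip = skips[-(i + 1)]
            self._skip_channels.append((up.shape[0], skip.shape[0]))
            x = block.forward(np.concatenate([up, skip], axis=0))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = []
        for i in range(len(self.dec) - 1, -1, -1):
            d = self.dec[i].backward(dy)
            c_up, _ = self._skip_channels[i]
            dskips.append(d[c_up:])
            dy = self.ups[i].backward(d[:c_up])
        dskips.reverse()
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy)
                dy = dy + dskips[len(self.pools) - 1 - i]
            dy = self.enc[i].backward(dy)

    def _check_shape(self, spatial):
        d = self.config.divisor
        bad = [s for s in spatial if s % d != 0]
        if bad:
            need = tuple(((s + d - 1) // d) * d for s in spatial)
            raise ValueError(
                f"spatial shape {tuple(spatial)} not divisible by {d}; "
                f"pad to {need} (predict_labels does this automatically)"
            )


@dataclass
class ModelHandle:
    """Opaque reference to a trained (or trainable) model."""

    net: UNet3D
    config: NetworkConfig
    seed: int
    loss_trace: list = field(default_factory=list)


def build_unet(config: NetworkConfig, seed: int) -> ModelHandle:
    """Build a freshly initialized U-Net; weights reproducible from ``seed``."""
    return ModelHandle(net=UNet3D(config, seed), config=config, seed=seed)


def count_parameters(model: ModelHandle) -> int:
    """Number of trainable scalars in the model."""
    return sum(p.size for p in model.net.parameters())


def make_optimizer(model: ModelHandle, lr: float = 3e-4) -> AMSGrad:
    return AMSGrad(model.net.parameters(), lr=lr)


def predict_probabilities(model: ModelHandle, volume: np.ndarray) -> np.ndarray:
    """Softmax class probabilities for an intensity-normalized volume.

    Volumes whose extents are not divisible by the pooling depth are
    symmetrically zero-padded and the prediction cropped back.
    """
    volume = np.asarray(volume, dtype=np.float32)
    d = model.config.divisor
    shape = volume.shape
    pads = []
    for s in shape:
        total = (-s) % d
        pads.append((total // 2, total - total // 2))
    if any(a or b for a, b in pads):
        volume = np.pad(volume, pads)
    logits = model.net.forward(volume)
    probs = softmax(logits)
    sl = tuple(slice(a, a + s) for (a, _), s in zip(pads, shape))
    return probs[(slice(None),) + sl]


def predict_labels(model: ModelHandle, volume: np.ndarray) -> np.ndarray:
    """Hard per-voxel argmax segmentation of a normalized volume."""
    return predict_probabilities(model, volume).argmax(axis=0).astype(np.int16)


def save_model(model: ModelHandle, path) -> None:
    """Write weights + architecture config + seed as a single .npz."""
    from dataclasses import asdict

    arrays = {f"param_{i}": p.value for i, p in enumerate(model.net.parameters())}
    np.savez_compressed(
        path,
        config=np.array(json.dumps(asdict(model.config))),
        seed=np.array(model.seed),
        loss_trace=np.asarray(model.loss_trace, dtype=np.float64),
        **arrays,
    )


def load_model(path) -> ModelHandle:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        config = NetworkConfig(**json.loads(str(data["config"])))
        model = build_unet(config, int(data["seed"]))
        model.loss_trace = data["loss_trace"].tolist()
        for i, p in enumerate(model.net.parameters()):
            stored = data[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValueError(f"checkpoint parameter {i} shape mismatch")
            p.value[...] = stored
    return model
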