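"""Seven-block 1-D convolutional audio backbone (SoundNet architecture).

The backbone maps a raw mono waveform sampled at 22,050 Hz through seven
convolutional blocks (conv -> batch norm -> ReLU, with temporal max pooling
after blocks 1, 2 and 5).  Cumulative temporal downsampling through block 7
is 32,768, so conv7 emits features at 22050/32768 ~ 0.67 Hz — essentially
one frame per fMRI volume at TR = 1.49 s, which is what makes this network
a convenient feature extractor for voxelwise encoding models.

Fine-tuning depth is block-controlled: depth ``"conv4"`` trains blocks 4-7
(plus whatever head sits on top) while blocks 1-3 stay frozen, including
their batch-normalisation statistics, so a frozen prefix is a pure function
of the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import BatchNorm1d, Conv1d, MaxPool1d, Parameter, ReLU

__all__ = [
    "BlockSpec",
    "BackboneConfig",
    "Backbone",
    "FeatureSeries",
    "build_backbone",
    "forward_features",
    "set_trainable_depth",
    "frame_arithmetic",
    "cumulative_stride",
    "DEPTHS",
    "WeightLoadError",
]

SAMPLE_RATE = 22050

# fine-tune depths, shallowest-trainable block first
DEPTHS = ("none", "conv7", "conv6", "conv5", "conv4", "conv3", "conv2", "conv1")


class WeightLoadError(RuntimeError):
    pass


@dataclass(frozen=True)
class BlockSpec:
    name: str
    out_channels: int
    conv_kernel: int
    conv_stride: int
    conv_padding: int
    pool_size: int | None = None


_SOUNDNET_BLOCKS = (
    BlockSpec("conv1", 16, 64, 2, 32, 8),
    BlockSpec("conv2", 32, 32, 2, 16, 8),
    BlockSpec("conv3", 64, 16, 2, 8, None),
    BlockSpec("conv4", 128, 8, 2, 4, None),
    BlockSpec("conv5", 256, 4, 2, 2, 4),
    BlockSpec("conv6", 512, 4, 2, 2, None),
    BlockSpec("conv7", 1024, 4, 2, 2, None),
)


@dataclass
class BackboneConfig:
    blocks: tuple[BlockSpec, ...] = _SOUNDNET_BLOCKS
    sample_rate_hz: int = SAMPLE_RATE
    fine_tune_depth: str = "none"

    def __post_init__(self):
        if len(self.blocks) != 7:
            raise ValueError("backbone requires exactly 7 blocks")
        if self.fine_tune_depth not in DEPTHS:
            raise ValueError(f"unknown fine_tune_depth {self.fine_tune_depth!r}; "
                             f"expected one of {DEPTHS}")

    def block_index(self, name: str) -> int:
        for i, b in enumerate(self.blocks):
            if b.name == name:
                return i
        raise ValueError(f"unknown block {name!r}")


@dataclass
class FeatureSeries:
    """Backbone activations at a tap layer: frames x channels."""
    values: np.ndarray
    tap: str
    frame_rate_hz: float

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


class _Block:
    def __init__(self, spec: BlockSpec, in_channels: int,
                 rng: np.random.Generator):
        self.spec = spec
        self.conv = Conv1d(in_channels, spec.out_channels, spec.conv_kernel,
                           spec.conv_stride, spec.conv_padding, rng=rng)
        self.bn = BatchNorm1d(spec.out_channels)
        self.relu = ReLU()
        self.pool = MaxPool1d(spec.pool_size) if spec.pool_size else None
        self.trainable = False

    @property
    def layers(self):
        out = [self.conv, self.bn, self.relu]
        if self.pool is not None:
            out.append(self.pool)
        return out

    def params(self) -> dict[str, Parameter]:
        out = {f"conv.{k}": v for k, v in self.conv.params().items()}
        out.update({f"bn.{k}": v for k, v in self.bn.params().items()})
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params().values())

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Backbone:
    """The seven-block feature extractor with depth-controlled trainability."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks: list[_Block] = []
        in_ch = 1
        for spec in config.blocks:
            self.blocks.append(_Block(spec, in_ch, rng))
            in_ch = spec.out_channels
        set_trainable_depth(self, config.fine_tune_depth)

    # -- introspection -------------------------------------------------
    def block(self, name: str) -> _Block:
        return self.blocks[self.config.block_index(name)]

    def params(self, trainable_only: bool = False) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for blk in self.blocks:
            if trainable_only and not blk.trainable:
                continue
            for k, v in blk.params().items():
                out[f"{blk.spec.name}.{k}"] = v
        return out

    def n_params(self, trainable_only: bool = False) -> int:
        return sum(p.size for p in self.params(trainable_only).values())

    def channels_at(self, tap: str) -> int:
        return self.config.blocks[self.config.block_index(tap)].out_channels

    def frame_rate_at(self, tap: str) -> float:
        return self.config.sample_rate_hz / cumulative_stride(self.config, tap)

    # -- execution -----------------------------------------------------
    def forward(self, x: np.ndarray, tap: str = "conv7",
                from_block: int = 0, train_from: int | None = None) -> np.ndarray:
        """Run blocks ``from_block..tap``; blocks >= ``train_from`` run in
        training mode (batch statistics, caches kept for backward)."""
        stop = self.config.block_index(tap)
        for i in range(from_block, stop + 1):
            train = train_from is not None and i >= train_from
            x = self.blocks[i].forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray, tap: str, down_to: int) -> np.ndarray:
        stop = self.config.block_index(tap)
        for i in range(stop, down_to - 1, -1):
            gy = self.blocks[i].backward(gy)
        return gy

    # -- persistence ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data for name, p in self.params().items()}
        for blk in self.blocks:
            out[f"{blk.spec.name}.bn.running_mean"] = blk.bn.running_mean
            out[f"{blk.spec.name}.bn.running_var"] = blk.bn.running_var
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        for name, value in state.items():
            value = np.asarray(value, dtype=np.float32)
            block = name.split(".", 1)[0]
            if name.endswith("running_mean"):
                target = self.block(block).bn.running_mean
            elif name.endswith("running_var"):
                target = self.block(block).bn.running_var
            elif name in params:
                target = params[name].data
            else:
                raise WeightLoadError(f"unknown tensor {name!r}")
            if target.shape != value.shape:
                raise WeightLoadError(
                    f"shape mismatch for block {block!r} tensor {name!r}: "
                    f"expected {target.shape}, got {value.shape}")
            target[...] = value

    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = self.state_dict()
        np.savez(path, **state)
        sidecar = {name: {"block": name.split(".", 1)[0],
                          "shape": list(v.shape), "dtype": str(v.dtype)}
                   for name, v in state.items()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def build_backbone(config: BackboneConfig | None = None,
                   weights: str | Path | dict | None = None,
                   seed: int = 0) -> Backbone:
    """Construct the backbone; load a named-tensor weight archive if given,
    otherwise keep the seeded fan-in-scaled random initialisation."""
    net = Backbone(config or BackboneConfig(), seed=seed)
    if weights is not None:
        if isinstance(weights, (str, Path)):
            with np.load(weights) as archive:
                state = {k: archive[k] for k in archive.files}
        else:
            state = dict(weights)
        net.load_state_dict(state)
    return net


def set_trainable_depth(backbone: Backbone, depth: str) -> Backbone:
    """depth ``"convN"`` makes blocks N..7 trainable; ``"none"`` freezes all."""
    if depth not in DEPTHS:
        raise ValueError(f"unknown depth {depth!r}; expected one of {DEPTHS}")
    start = 7 if depth == "none" else backbone.config.block_index(depth)
    for i, blk in enumerate(backbone.blocks):
        blk.trainable = i >= start
    backbone.config.fine_tune_depth = depth
    return backbone


def forward_features(backbone: Backbone, waveform: np.ndarray,
                     tap: str = "conv7") -> FeatureSeries:
    """Frozen-mode feature extraction: frames x channels at the tap block."""
    waveform = np.asarray(waveform, dtype=np.float32).ravel()
    if waveform.size == 0:
        raise ValueError("empty waveform")
    x = waveform[None, None, :]
    y = backbone.forward(x, tap=tap)  # (1, C, frames)
    return FeatureSeries(values=np.ascontiguousarray(y[0].T), tap=tap,
                         frame_rate_hz=backbone.frame_rate_at(tap))


def frame_arithmetic(input_len: int, tap: str = "conv7",
                     config: BackboneConfig | None = None) -> int:
    """Closed-form frame count at ``tap`` for an ``input_len``-sample input.

    Composes conv (floor((L + 2p - k)/s) + 1, clipped at 0) and pool
    (floor(L/pool)) length maps; pure arithmetic, no model evaluation.
    """
    config = config or BackboneConfig()
    length = int(input_len)
    for spec in config.blocks[: config.block_index(tap) + 1]:
        if length <= 0:
            return 0
        length = (length + 2 * spec.conv_padding - spec.conv_kernel) \
            // spec.conv_stride + 1
        if length < 0:
            length = 0
        if spec.pool_size:
            length //= spec.pool_size
    return max(length, 0)


def cumulative_stride(config: BackboneConfig | None, tap: str) -> int:
    """Product of conv strides and pool sizes up to and including ``tap``."""
    config = config or BackboneConfig()
    total = 1
    for spec in config.blocks[: config.block_index(tap) + 1]:
        total *= spec.conv_stride
        if spec.pool_size:
            total *= spec.pool_size
    return total
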