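"""fMRI encoding head and the composed audio-to-BOLD encoding model.

The head implements y_i = sum_k h_{i,k} * x_k: one temporal convolution
kernel per (feature channel k, brain target i) pair, summed over channels,
plus a per-target bias.  With kernel_size = 1 this is a frame-wise linear
regression of features onto BOLD; with a longer kernel it acts as an FIR
filter that absorbs the lagged haemodynamic response.  Padding of
kernel_size - 1 zeros is applied on the left (causal) so the output has
exactly as many frames as the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .backbone import Backbone, BackboneConfig, build_backbone, forward_features
from .nn import Parameter

__all__ = ["EncodingHead", "EncodingModel", "build_head", "predict",
           "harmonize_frames", "lagged_design"]


def harmonize_frames(features: np.ndarray, n_frames: int) -> np.ndarray:
    """Crop trailing frames or right-pad with zeros so features span exactly
    ``n_frames`` rows (backbone and TR rates match only approximately:
    0.673 vs 0.671 Hz)."""
    f = features.shape[0]
    if f == n_frames:
        return features
    if f > n_frames:
        return features[:n_frames]
    pad = np.zeros((n_frames - f, features.shape[1]), dtype=features.dtype)
    return np.concatenate([features, pad], axis=0)


def lagged_design(features: np.ndarray, kernel_size: int) -> np.ndarray:
    """(W, N) features -> (W, N*K) causal lag stack; column k*K + d holds
    channel k delayed by K-1-d frames, matching the head's kernel layout."""
    w, n = features.shape
    k = kernel_size
    padded = np.concatenate(
        [np.zeros((k - 1, n), dtype=features.dtype), features], axis=0)
    # out[t, :, d] = padded[t + d] = x[t + d - (K-1)]
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(padded, k, axis=0)  # (W, N, K)
    return win.reshape(w, n * k)


class EncodingHead:
    """Temporal-convolution read-out from features to brain targets."""

    def __init__(self, n_features: int, n_targets: int, kernel_size: int,
                 rng: np.random.Generator | None = None):
        if min(n_features, n_targets, kernel_size) < 1:
            raise ValueError("n_features, n_targets and kernel_size must be >= 1")
        self.n_features = n_features
        self.n_targets = n_targets
        self.kernel_size = kernel_size
        rng = rng if rng is not None else np.random.default_rng(0)
        # output layer starts near zero: an untrained head predicts ~the
        # signal mean, so a random-weight null model scores r^2 ~ 0 and a
        # ridge-like fit shrinks from the origin
        fan_in = n_features * kernel_size
        bound = 1.0 / fan_in
        self.kernels = Parameter(
            rng.uniform(-bound, bound,
                        (n_targets, n_features, kernel_size)).astype(np.float32))
        self.bias = Parameter(np.zeros(n_targets), decay=False)
        self._x_design: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.kernels.size + self.bias.size

    def params(self) -> dict[str, Parameter]:
        return {"head.kernels": self.kernels, "head.bias": self.bias}

    def forward(self, features: np.ndarray | None = None,
                train: bool = False, *,
                design: np.ndarray | None = None) -> np.ndarray:
        """(W, N) feature frames -> (W, n_targets) predicted BOLD.

        A precomputed lag design (from :func:`lagged_design`) may be passed
        instead of raw features to avoid rebuilding it every step.
        """
        if design is None:
            if features.shape[1] != self.n_features:
                raise ValueError(
                    f"expected {self.n_features} feature channels, "
                    f"got {features.shape[1]}")
            design = lagged_design(features.astype(np.float32),
                                   self.kernel_size)
        y = design @ self.kernels.data.reshape(self.n_targets, -1).T
        y += self.bias.data
        if train:
            self._x_design = design
        return y

    def backward(self, gy: np.ndarray,
                 need_input_grad: bool = True) -> np.ndarray | None:
        """gy (W, n_targets) -> gradient w.r.t. input features (W, N)."""
        if self._x_design is None:
            raise RuntimeError("backward before forward(train=True)")
        design = self._x_design
        self.bias.grad += gy.sum(axis=0)
        self.kernels.grad += (gy.T @ design).reshape(self.kernels.data.shape)
        self._x_design = None
        if not need_input_grad:
            return None
        gdesign = gy @ self.kernels.data.reshape(self.n_targets, -1)
        w = gy.shape[0]
        k, n = self.kernel_size, self.n_features
        gwin = gdesign.reshape(w, n, k)
        gpadded = np.zeros((w + k - 1, n), dtype=np.float32)
        for d in range(k):
            gpadded[d: d + w] += gwin[:, :, d]
        return gpadded[k - 1:]


def build_head(n_features: int, n_targets: int, kernel_size: int,
               seed: int = 0) -> EncodingHead:
    """Seeded-random kernels, zero bias; parameter count is
    n_features * n_targets * kernel_size + n_targets."""
    return EncodingHead(n_features, n_targets, kernel_size,
                        rng=np.random.default_rng(seed))


@dataclass
class EncodingModel:
    """Backbone + tap + encoding head + target labels."""
    backbone: Backbone
    head: EncodingHead
    tap: str = "conv7"
    target_space: list[str] | None = None

    def __post_init__(self):
        if self.head.n_features != self.backbone.channels_at(self.tap):
            raise ValueError(
                f"head expects {self.head.n_features} features but tap "
                f"{self.tap!r} emits {self.backbone.channels_at(self.tap)}")
        if self.target_space is None:
            self.target_space = [f"t{i:04d}" for i in range(self.head.n_targets)]
        elif len(self.target_space) != self.head.n_targets:
            raise ValueError("target_space length must equal n_targets")

    @property
    def n_targets(self) -> int:
        return self.head.n_targets

    def predict(self, waveform: np.ndarray, n_frames: int) -> np.ndarray:
        """Predict a BOLD window of ``n_frames`` TRs from the waveform."""
        feats = forward_features(self.backbone, waveform, tap=self.tap)
        return self.head.forward(harmonize_frames(feats.values, n_frames))

    # -- persistence ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.backbone.save(directory / "backbone.npz")
        np.savez(directory / "head.npz",
                 kernels=self.head.kernels.data, bias=self.head.bias.data)
        (directory / "model.json").write_text(json.dumps({
            "tap": self.tap,
            "kernel_size": self.head.kernel_size,
            "n_features": self.head.n_features,
            "n_targets": self.head.n_targets,
            "fine_tune_depth": self.backbone.config.fine_tune_depth,
            "target_space": self.target_space,
        }, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "EncodingModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg = BackboneConfig(fine_tune_depth=meta["fine_tune_depth"])
        net = build_backbone(cfg, weights=directory / "backbone.npz")
        head = build_head(meta["n_features"], meta["n_targets"],
                          meta["kernel_size"])
        with np.load(directory / "head.npz") as archive:
            head.kernels.data[...] = archive["kernels"]
            head.bias.data[...] = archive["bias"]
        return cls(net, head, tap=meta["tap"], target_space=meta["target_space"])


def predict(model: EncodingModel, waveform: np.ndarray,
            n_frames: int) -> np.ndarray:
    """Module-level convenience wrapper around ``EncodingModel.predict``."""
    return model.predict(waveform, n_frames)
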