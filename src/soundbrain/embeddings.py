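"""Scene and timestamp embedding export (HEAR-style API contract).

A scene embedding summarises a whole clip as one 1,024-vector: the conv7
feature frames averaged over time.  Timestamp embeddings are the conv5
block's output frames (256 channels, hop 8,192 samples ~ 0.37 s) together
with their centre times, for event-detection-style downstream tasks.
Both are deterministic functions of the clip for a frozen model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .backbone import (Backbone, cumulative_stride, forward_features,
                       frame_arithmetic)
from .encoding import EncodingModel

__all__ = ["SceneEmbedding", "TimestampEmbeddings", "scene_embedding",
           "timestamp_embeddings", "export_embeddings",
           "get_scene_embeddings", "get_timestamp_embeddings"]


@dataclass
class SceneEmbedding:
    vector: np.ndarray          # (1024,) conv7 channels, time-averaged

    def __post_init__(self):
        if not np.isfinite(self.vector).all():
            raise ValueError("non-finite embedding")


@dataclass
class TimestampEmbeddings:
    values: np.ndarray          # (frames, 256)
    times_s: np.ndarray         # frame centre times, strictly increasing

    def __post_init__(self):
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


def _net(model) -> Backbone:
    return model.backbone if isinstance(model, EncodingModel) else model


def scene_embedding(model, clip: np.ndarray) -> SceneEmbedding:
    """Mean of the conv7 feature frames; requires at least one frame."""
    net = _net(model)
    clip = np.asarray(clip, dtype=np.float32).ravel()
    if frame_arithmetic(clip.size, "conv7", net.config) < 1:
        raise ValueError(
            f"clip of {clip.size} samples is shorter than one conv7 "
            "receptive field")
    feats = forward_features(net, clip, tap="conv7")
    return SceneEmbedding(vector=feats.values.mean(axis=0))


def timestamp_embeddings(model, clip: np.ndarray,
                         pre_pool: bool = False) -> TimestampEmbeddings:
    """conv5-block output frames with centre times t_j = (j + 0.5) * hop / sr.

    By default the tap is the block output (after its max-pool, hop 8,192
    samples); ``pre_pool`` switches to the pre-pool activations (hop 2,048).
    """
    net = _net(model)
    clip = np.asarray(clip, dtype=np.float32).ravel()
    if frame_arithmetic(clip.size, "conv5", net.config) < 1:
        raise ValueError(
            f"clip of {clip.size} samples is shorter than one conv5 "
            "receptive field")
    if pre_pool:
        x = clip[None, None, :]
        for blk in net.blocks[: net.config.block_index("conv5") + 1]:
            x = blk.conv.forward(x)
            x = blk.bn.forward(x)
            x = blk.relu.forward(x)
            if blk.spec.name != "conv5" and blk.pool is not None:
                x = blk.pool.forward(x)
        values = np.ascontiguousarray(x[0].T)
        hop = cumulative_stride(net.config, "conv5") // 4
    else:
        values = forward_features(net, clip, tap="conv5").values
        hop = cumulative_stride(net.config, "conv5")
    sr = net.config.sample_rate_hz
    times = (np.arange(values.shape[0]) + 0.5) * hop / sr
    return TimestampEmbeddings(values=values, times_s=times)


# -- HEAR-style batch API ---------------------------------------------------

def get_scene_embeddings(model, clips) -> np.ndarray:
    """(n_clips, 1024) scene embeddings, order-preserving."""
    return np.stack([scene_embedding(model, c).vector for c in clips])


def get_timestamp_embeddings(model, clips):
    """Lists of (frames, 256) arrays and matching centre-time arrays."""
    out = [timestamp_embeddings(model, c) for c in clips]
    return [e.values for e in out], [e.times_s for e in out]


def export_embeddings(model, clips, outpath: str | Path,
                      mode: str = "scene") -> Path:
    """Batch-export embeddings to an NPZ archive plus a JSON times sidecar."""
    outpath = Path(outpath)
    if mode == "scene":
        emb = get_scene_embeddings(model, clips)
        np.savez(outpath, embeddings=emb)
        times = None
    elif mode == "timestamp":
        values, times_list = get_timestamp_embeddings(model, clips)
        np.savez(outpath, **{f"clip{i:04d}": v for i, v in enumerate(values)})
        times = {f"clip{i:04d}": t.tolist() for i, t in enumerate(times_list)}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sidecar = outpath.with_suffix(".times.json")
    sidecar.write_text(json.dumps({"mode": mode, "times_s": times}))
    return outpath
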