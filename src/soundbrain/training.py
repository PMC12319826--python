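"""End-to-end training of baseline and brain-aligned encoding models.

The baseline model trains only the encoding head on frozen backbone
features; a brain-aligned model at depth ``convN`` additionally trains
backbone blocks N..7.  Optimisation is AdamW (decoupled weight decay, so
the head behaves like a Ridge-regularised regression) on an MSE loss, with
a reduce-on-plateau learning-rate schedule and early stopping on the
validation loss; the weights from the best validation epoch are returned.

Everything below the trainable depth is a pure function of the input, so
its activations are computed once per window and cached for all epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .backbone import DEPTHS
from .data import BoldMatrix, SplitSpec, window_run
from .encoding import EncodingModel, harmonize_frames
from .evaluation import r2_scores
from .nn import Parameter

__all__ = ["TrainConfig", "TrainHistory", "AdamW", "train_model",
           "grid_search", "group_hyperparams", "train_group_model",
           "evaluate_runs"]


@dataclass(frozen=True)
class TrainConfig:
    window_tr: int = 70           # W, in TRs (the paper's grid spans 20-130 s)
    learning_rate: float = 1e-2
    kernel_size: int = 5
    weight_decay: float = 1e-4
    delta: float = 1e-4           # minimal val-loss improvement for early stop
    patience: int = 10            # non-improving epochs before stopping
    batch_size: int = 1
    max_epochs: int = 100
    seed: int = 0
    fine_tune_depth: str = "none"
    adam_eps: float = 1e-8        # larger values stabilise near-interpolation fits

    def __post_init__(self):
        if min(self.window_tr, self.kernel_size, self.batch_size,
               self.max_epochs, self.patience) < 1:
            raise ValueError("counts and patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0 or self.delta < 0:
            raise ValueError("weight_decay and delta must be non-negative")
        if self.fine_tune_depth not in DEPTHS:
            raise ValueError(f"unknown fine_tune_depth {self.fine_tune_depth!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""
    best_epoch: int = 0


class AdamW:
    """Adam with decoupled weight decay; decay applies only to parameters
    flagged for it (kernels, not biases or normalisation affines)."""

    def __init__(self, params: dict[str, Parameter], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if p.decay and self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data


class _Plateau:
    """Reduce-on-plateau: halve the learning rate when the monitored loss
    fails to improve by ``delta`` for ``patience`` epochs."""

    def __init__(self, optimizer: AdamW, delta: float, patience: int,
                 factor: float = 0.5, min_lr: float = 1e-7):
        self.opt = optimizer
        self.delta = delta
        self.patience = max(patience, 1)
        self.factor = factor
        self.min_lr = min_lr
        self.best = math.inf
        self.count = 0

    def step(self, loss: float) -> None:
        if loss < self.best - self.delta:
            self.best = loss
            self.count = 0
        else:
            self.count += 1
            if self.count >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.count = 0


def _trainable_params(model: EncodingModel) -> dict[str, Parameter]:
    out = dict(model.head.params())
    out.update(model.backbone.params(trainable_only=True))
    return out


def _first_trainable_block(model: EncodingModel) -> int | None:
    for i, blk in enumerate(model.backbone.blocks):
        if blk.trainable:
            return i
    return None


def _prepare_cache(model: EncodingModel, windows, w: int):
    """Precompute the frozen part of the forward pass for each window.

    With a fully frozen backbone the cache is the per-window causal lag
    design (head input); otherwise it is the (1, C, L) activation entering
    the first trainable block.
    """
    from .encoding import lagged_design

    start = _first_trainable_block(model)
    caches, bolds = [], []
    for waveform, bold in windows:
        bold = bold.values if isinstance(bold, BoldMatrix) else np.asarray(bold)
        if bold.shape[0] != w:
            raise ValueError(f"BOLD window has {bold.shape[0]} TRs, expected {w}")
        x = np.asarray(waveform, dtype=np.float32)[None, None, :]
        if start is None:
            feats = model.backbone.forward(x, tap=model.tap)[0].T
            feats = harmonize_frames(np.ascontiguousarray(feats), w)
            caches.append(lagged_design(feats, model.head.kernel_size))
        elif start == 0:
            caches.append(x)
        else:
            caches.append(model.backbone.forward(
                x, tap=model.backbone.config.blocks[start - 1].name))
        bolds.append(bold.astype(np.float32))
    if not caches:
        raise ValueError("empty training set")
    return start, caches, bolds


def _merge_full_batch(caches, bolds):
    """Stack per-window head designs into one matrix (same least-squares
    problem, one BLAS call per step)."""
    return ([np.concatenate(caches, axis=0)],
            [np.concatenate(bolds, axis=0)])


def _forward_loss(model: EncodingModel, start, cache, bold, w,
                  train: bool, batch_count: int = 1) -> tuple[float, int]:
    """Forward one window; if ``train``, backprop and accumulate grads for
    the batch-mean MSE (``batch_count`` windows per optimiser step).
    Returns (sum of squared errors, number of entries)."""
    if start is None:
        pred = model.head.forward(train=train, design=cache)
        err = pred - bold
        if train:
            gy = (2.0 / (err.size * batch_count)) * err
            model.head.backward(gy.astype(np.float32), need_input_grad=False)
        return float((err ** 2).sum()), err.size
    train_from = start if train else None
    acts = model.backbone.forward(cache, tap=model.tap,
                                  from_block=start, train_from=train_from)
    raw = acts.shape[2]
    feats = harmonize_frames(np.ascontiguousarray(acts[0].T), w)
    pred = model.head.forward(feats, train=train)
    err = pred - bold
    if train:
        gy = (2.0 / (err.size * batch_count)) * err
        gx = model.head.backward(gy.astype(np.float32))
        gfeat = np.zeros((raw, gx.shape[1]), dtype=np.float32)
        gfeat[: min(raw, w)] = gx[: min(raw, w)]
        model.backbone.backward(gfeat.T[None], tap=model.tap, down_to=start)
    return float((err ** 2).sum()), err.size


def train_model(model: EncodingModel, train_windows, val_windows,
                cfg: TrainConfig) -> tuple[EncodingModel, TrainHistory]:
    """Train in place and return (model at best validation epoch, history)."""
    if len(train_windows) == 0:
        raise ValueError("empty training set")
    w = cfg.window_tr
    start, tr_caches, tr_bolds = _prepare_cache(model, train_windows, w)
    _, va_caches, va_bolds = _prepare_cache(model, val_windows, w) \
        if len(val_windows) else (start, [], [])
    if start is None and cfg.batch_size >= len(tr_caches):
        # frozen backbone + full batch: one stacked design per step
        tr_caches, tr_bolds = _merge_full_batch(tr_caches, tr_bolds)
        if va_caches:
            va_caches, va_bolds = _merge_full_batch(va_caches, va_bolds)

    params = _trainable_params(model)
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
                eps=cfg.adam_eps)
    sched = _Plateau(opt, cfg.delta, math.ceil(cfg.patience / 2))
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    wait = 0

    def snapshot():
        return ({k: p.data.copy() for k, p in params.items()},
                [(blk.bn.running_mean.copy(), blk.bn.running_var.copy())
                 for blk in model.backbone.blocks])

    def val_eval():
        if not va_caches:
            return None
        vs = sum(_forward_loss(model, start, c, b, w, train=False)[0]
                 for c, b in zip(va_caches, va_bolds))
        return vs / sum(b.size for b in va_bolds)

    # the incoming model is the epoch-0 candidate: a warm start is never
    # replaced by something that validates worse
    init_val = val_eval()
    best_val = math.inf if init_val is None else init_val
    best_state = None if init_val is None else snapshot()
    hist.best_epoch = -1

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(tr_caches))
        sse = 0.0
        cnt = 0
        for lo in range(0, len(order), cfg.batch_size):
            batch = order[lo: lo + cfg.batch_size]
            opt.zero_grad()
            for i in batch:
                s, n = _forward_loss(model, start, tr_caches[i], tr_bolds[i],
                                     w, train=True, batch_count=len(batch))
                sse += s
                cnt += n
            opt.step()
        train_loss = sse / max(cnt, 1)
        if not math.isfinite(train_loss):
            raise RuntimeError("training diverged: non-finite loss")
        val_loss = val_eval()
        if val_loss is None:
            val_loss = train_loss
        hist.train_loss.append(train_loss)
        hist.val_loss.append(val_loss)
        hist.learning_rate.append(opt.lr)
        if val_loss < best_val:
            best_state = snapshot()
            hist.best_epoch = epoch
        # early stopping: improvement must exceed delta
        if val_loss < best_val - cfg.delta:
            wait = 0
        else:
            wait += 1
        best_val = min(best_val, val_loss)
        sched.step(val_loss)
        if wait >= cfg.patience:
            hist.stop_epoch = epoch + 1
            hist.stop_reason = "early_stop"
            break
    else:
        hist.stop_epoch = cfg.max_epochs
        hist.stop_reason = "max_epochs"

    if best_state is not None:
        data, bn = best_state
        for k, p in params.items():
            p.data[...] = data[k]
        for blk, (rm, rv) in zip(model.backbone.blocks, bn):
            blk.bn.running_mean[...] = rm
            blk.bn.running_var[...] = rv
    return model, hist


def evaluate_runs(model: EncodingModel, runs, w: int) -> np.ndarray:
    """Per-run, per-target r^2 on concatenated non-overlapping windows.

    ``runs`` is a sequence of (waveform, BoldMatrix) pairs; returns a
    (n_runs, n_targets) array.
    """
    rows = []
    for waveform, bold in runs:
        windows = window_run(bold, waveform, w)
        preds = np.concatenate([model.predict(aw, w) for aw, _ in windows])
        actual = np.concatenate([bw for _, bw in windows])
        rows.append(r2_scores(preds, actual))
    return np.vstack(rows)


def grid_search(model_factory, train_runs, val_runs, grid,
                ) -> tuple[TrainConfig, pd.DataFrame]:
    """Train one model per grid point (on the frozen-backbone baseline) and
    select the configuration with the best validation r^2 summary (median
    over targets, then mean over runs)."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    rows = []
    best_cfg, best_score = None, -math.inf
    for cfg in grid:
        model = model_factory(cfg)
        tw = [win for wav, bold in train_runs
              for win in window_run(bold, wav, cfg.window_tr)]
        vw = [win for wav, bold in val_runs
              for win in window_run(bold, wav, cfg.window_tr)]
        model, hist = train_model(model, tw, vw, cfg)
        r2 = evaluate_runs(model, val_runs, cfg.window_tr)
        score = float(np.mean(np.median(r2, axis=1)))
        rows.append({**{f.name: getattr(cfg, f.name) for f in fields(cfg)},
                     "val_r2_summary": score,
                     "stop_epoch": hist.stop_epoch})
        if score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg, pd.DataFrame(rows)


def _lower_median(values):
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def group_hyperparams(configs) -> TrainConfig:
    """Field-wise (lower) median of exactly five individual configurations."""
    configs = list(configs)
    if len(configs) != 5:
        raise ValueError(f"expected exactly 5 configs, got {len(configs)}")
    out = {}
    for f in fields(TrainConfig):
        vals = [getattr(c, f.name) for c in configs]
        if f.name == "fine_tune_depth":
            out[f.name] = DEPTHS[_lower_median(DEPTHS.index(v) for v in vals)]
        else:
            out[f.name] = type(vals[0])(_lower_median(vals))
    return TrainConfig(**out)


def train_group_model(target_subject: str, runs_by_subject: dict,
                      configs, model_factory,
                      split: SplitSpec = SplitSpec()
                      ) -> tuple[EncodingModel, TrainHistory, TrainConfig]:
    """Train a group model for ``target_subject`` on the pooled runs of all
    *other* subjects; hyper-parameters are the field-wise median of the five
    individual configurations (or a single config passed directly)."""
    if target_subject not in runs_by_subject:
        raise ValueError(f"target subject {target_subject!r} not in manifest")
    if len(runs_by_subject) < 2:
        raise ValueError("need at least 2 subjects")
    cfg = configs if isinstance(configs, TrainConfig) else group_hyperparams(configs)
    pool = [run for subj, runs in sorted(runs_by_subject.items())
            if subj != target_subject for run in runs]
    order = np.random.default_rng(split.seed).permutation(len(pool))
    n_train = int(np.floor(split.train_fraction * len(pool)))
    train_runs = [pool[i] for i in order[:n_train]]
    val_runs = [pool[i] for i in order[n_train:]]
    model = model_factory(cfg)
    tw = [win for wav, bold in train_runs
          for win in window_run(bold, wav, cfg.window_tr)]
    vw = [win for wav, bold in val_runs
          for win in window_run(bold, wav, cfg.window_tr)]
    model, hist = train_model(model, tw, vw, cfg)
    return model, hist, cfg
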