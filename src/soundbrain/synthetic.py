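"""Synthetic paired audio/BOLD data with planted ground truth.

The generator emulates the structure of a naturalistic TV-watching fMRI
dataset: episodes split into two runs (a/b), a mono 22,050 Hz soundtrack
per run, and a TR x targets BOLD matrix per run at TR = 1.49 s.  BOLD is
generated by the same function class the encoding head fits — a linear FIR
read-out of the (frozen) backbone's conv7 features — plus i.i.d. Gaussian
noise, so parameter recovery is well-posed and every downstream module can
be exercised without any real data.

Planted kernels are drawn from the principal subspace of the realised
lagged features (``plant_rank`` directions): a dense random kernel over
1,024 channels x K lags would have most of its mass outside the row space
spanned by a desk-scale dataset and could never be recovered, whereas a
kernel inside that subspace is identified by noiseless data.

All randomness flows from one spec seed through named substreams
(audio / noise / tags / kernels / split).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .backbone import Backbone, BackboneConfig, build_backbone
from .data import (BoldMatrix, Manifest, RunRecord, SAMPLE_RATE, TR_SECONDS,
                   save_audio, window_samples, write_bold_tsv)
from .encoding import harmonize_frames, lagged_design

__all__ = ["SyntheticSpec", "SyntheticDataset", "gen_audio", "gen_bold",
           "gen_manifest", "gen_tag_table", "plant_kernels", "make_dataset",
           "DEFAULT_CATEGORIES"]

_STREAMS = {"audio": 0, "noise": 1, "tags": 2, "split": 3, "kernels": 4,
            "teacher": 5}

DEFAULT_CATEGORIES = ("talking", "music", "laugh", "applause",
                      "kitchen", "vehicle", "door", "crowd")
# typical fraction of audio carrying each label (labels may overlap)
_CATEGORY_MEANS = (0.80, 0.12, 0.15, 0.04, 0.05, 0.03, 0.04, 0.06)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-shaped synthetic dataset description.

    Defaults mirror the real study's geometry where it states one (TR,
    sample rate, runs-per-episode, 75/25 split downstream); sizes such as
    episode and TR counts default to desk scale and are raised explicitly
    by callers that need the full 73-episode layout.
    """
    n_subjects: int = 1
    seasons: int = 1
    episodes_per_season: int = 5
    n_tr: int = 100
    tr_seconds: float = TR_SECONDS
    n_targets: int = 10
    kernel_size: int = 3
    lag: int = 0                      # extra TR delay planted in the mapping
    noise_sigma: float = 1.5          # BOLD noise sd, signal sd is ~1
    shared_mapping: bool = True       # one mapping for all subjects
    plant_rank: int = 64              # principal directions kernels live in
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.seasons, self.episodes_per_season,
               self.n_tr, self.n_targets, self.kernel_size) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def run_samples(self) -> int:
        return window_samples(self.n_tr, self.tr_seconds)

    def rng(self, stream: str, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.seed, _STREAMS[stream], *map(int, key)])


def _run_key(record: RunRecord) -> tuple[int, int, int, int]:
    subj = int(record.subject.split("-")[-1])
    return (subj, record.season, record.episode,
            0 if record.segment == "a" else 1)


def gen_manifest(spec: SyntheticSpec, subjects=None,
                 episodes_per_season=None) -> Manifest:
    """Two runs (a/b) per episode for every subject and season."""
    if subjects is None:
        subjects = [f"sub-{i + 1:02d}" for i in range(spec.n_subjects)]
    runs = []
    for subject in subjects:
        for season in range(1, spec.seasons + 1):
            n_eps = spec.episodes_per_season if episodes_per_season is None \
                else episodes_per_season[season - 1]
            for episode in range(1, n_eps + 1):
                for segment in ("a", "b"):
                    stem = f"{subject}_s{season:02d}e{episode:02d}{segment}"
                    runs.append(RunRecord(
                        subject=subject, season=season, episode=episode,
                        segment=segment, audio_path=f"{stem}.wav",
                        bold_path=f"{stem}.tsv", n_tr=spec.n_tr,
                        tr_seconds=spec.tr_seconds))
    return Manifest(runs)


def gen_audio(spec: SyntheticSpec, record: RunRecord) -> np.ndarray:
    """Seeded mixture of tone events and band-limited noise bursts.

    Event rate ~0.4 Hz over a low noise floor; amplitude bounded in [-1, 1].
    Audio depends on (season, episode, segment) only, so all subjects hear
    the same soundtrack — as in the real study.
    """
    rng = spec.rng("audio", *_run_key(record)[1:])
    n = spec.run_samples
    x = 0.01 * rng.standard_normal(n)
    duration = n / SAMPLE_RATE
    n_events = max(int(0.4 * duration), 1)
    t_all = np.arange(n) / SAMPLE_RATE
    for _ in range(n_events):
        start = rng.uniform(0, duration)
        dur = rng.uniform(0.3, 2.0)
        i0 = int(start * SAMPLE_RATE)
        i1 = min(int((start + dur) * SAMPLE_RATE), n)
        if i1 <= i0:
            continue
        seg_t = t_all[i0:i1] - t_all[i0]
        env = np.hanning(i1 - i0)
        amp = rng.uniform(0.2, 0.8)
        if rng.random() < 0.5:
            freq = rng.uniform(100.0, 4000.0)
            event = amp * np.sin(2 * np.pi * freq * seg_t)
        else:
            lo = rng.uniform(100.0, 2000.0)
            hi = lo * rng.uniform(1.5, 4.0)
            sos = scipy.signal.butter(4, [lo, min(hi, 10000.0)], "bandpass",
                                      fs=SAMPLE_RATE, output="sos")
            event = amp * scipy.signal.sosfilt(sos,
                                               rng.standard_normal(i1 - i0))
        x[i0:i1] += env * event
    peak = np.abs(x).max()
    if peak > 0.95:
        x *= 0.95 / peak
    return x.astype(np.float32)


def _features_for(spec: SyntheticSpec, backbone: Backbone,
                  waveform: np.ndarray) -> np.ndarray:
    from .backbone import forward_features
    feats = forward_features(backbone, waveform, tap="conv7").values
    return harmonize_frames(feats, spec.n_tr)


def plant_kernels(spec: SyntheticSpec, features_list,
                  subject_seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw target (kernels, intercepts) inside the top-``plant_rank``
    principal subspace of the realised lagged features, scaled so each
    target's noiseless signal has ~unit standard deviation and zero mean
    across the dataset."""
    designs = [lagged_design(f.astype(np.float64), spec.kernel_size)
               for f in features_list]
    stacked = np.concatenate(designs, axis=0)
    stacked = stacked - stacked.mean(axis=0)
    rank = min(spec.plant_rank, min(stacked.shape) - 1)
    _, _, vt = np.linalg.svd(stacked, full_matrices=False)
    rng = spec.rng("kernels", subject_seed)
    coefs = rng.standard_normal((spec.n_targets, rank))
    flat = coefs @ vt[:rank]                      # (n_targets, N*K)
    signal = np.concatenate(designs, axis=0) @ flat.T
    sd = signal.std(axis=0)
    sd[sd == 0] = 1.0
    flat /= sd[:, None]
    # intercept centres the signal over the dataset, as preprocessed
    # (detrended, confound-regressed) BOLD is
    bias = -(signal / sd).mean(axis=0)
    n_features = features_list[0].shape[1]
    return (flat.reshape(spec.n_targets, n_features,
                         spec.kernel_size).astype(np.float32),
            bias.astype(np.float32))


def gen_bold(spec: SyntheticSpec, backbone: Backbone, waveform: np.ndarray,
             kernels: np.ndarray, record: RunRecord | None = None,
             bias: np.ndarray | None = None,
             standardize: bool = False) -> BoldMatrix:
    """BOLD = planted FIR head applied to conv7 features + Gaussian noise.

    ``bias`` is the planted head's per-target intercept (the generator pairs
    it with the kernels so the signal is centred, as preprocessed BOLD is).
    A nonzero ``spec.lag`` delays the signal by that many TRs before noise,
    exercising the trained kernel's ability to absorb an extra lag.
    """
    feats = _features_for(spec, backbone, waveform)
    design = lagged_design(feats.astype(np.float64), spec.kernel_size)
    signal = design @ kernels.reshape(spec.n_targets, -1).T.astype(np.float64)
    if bias is not None:
        signal = signal + bias
    if spec.lag:
        shifted = np.zeros_like(signal)
        shifted[spec.lag:] = signal[: signal.shape[0] - spec.lag]
        signal = shifted
    key = _run_key(record) if record is not None else (0, 0, 0, 0)
    noise_rng = spec.rng("noise", *key)
    values = signal + spec.noise_sigma * noise_rng.standard_normal(signal.shape)
    if standardize:
        values = (values - values.mean(axis=0)) / values.std(axis=0)
    labels = [f"t{i:04d}" for i in range(spec.n_targets)]
    return BoldMatrix(values, labels, space="custom")


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset: manifest + per-run assets + ground truth."""
    spec: SyntheticSpec
    manifest: Manifest
    backbone: Backbone                       # the backbone models start from
    waveforms: dict                          # run key -> waveform
    bolds: dict                              # run key -> BoldMatrix
    kernels: dict                            # subject -> planted kernels
    biases: dict                             # subject -> planted intercepts
    teacher: Backbone | None = None          # generative backbone, if perturbed

    def runs_for(self, subject: str):
        """(waveform, BoldMatrix) pairs for one subject."""
        return [(self.waveforms[r.key], self.bolds[r.key])
                for r in self.manifest if r.subject == subject]

    def runs_by_subject(self) -> dict:
        return {s: self.runs_for(s) for s in self.manifest.subjects()}

    def write(self, outdir: str | Path) -> Path:
        """Write WAV + BOLD TSV + manifest CSV under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for record in self.manifest:
            save_audio(outdir / record.audio_path, self.waveforms[record.key])
            write_bold_tsv(self.bolds[record.key], outdir / record.bold_path)
        self.manifest.to_csv(outdir / "manifest.csv")
        return outdir


def _perturb_backbone(spec: SyntheticSpec, backbone: Backbone,
                      depth: str, scale: float) -> Backbone:
    """Copy the backbone and jitter conv weights of blocks >= depth by
    ``scale`` times their RMS — a 'teacher' whose features the student can
    only match by fine-tuning those blocks."""
    teacher = build_backbone(BackboneConfig(), weights=backbone.state_dict())
    rng = spec.rng("teacher")
    start = teacher.config.block_index(depth)
    for blk in teacher.blocks[start:]:
        w = blk.conv.weight.data
        rms = float(np.sqrt((w ** 2).mean()))
        w += (scale * rms) * rng.standard_normal(w.shape).astype(np.float32)
    return teacher


def make_dataset(spec: SyntheticSpec, backbone: Backbone | None = None,
                 teacher_perturb_depth: str | None = None,
                 perturb_scale: float = 0.5) -> SyntheticDataset:
    """Generate the full dataset described by ``spec``.

    With ``shared_mapping`` one planted kernel set serves every subject;
    otherwise each subject gets its own draw (subject-specific mappings).
    With ``teacher_perturb_depth`` the BOLD is generated from a perturbed
    copy of the backbone, so a frozen-backbone model is mis-specified and
    fine-tuning at that depth has headroom to gain.
    """
    if backbone is None:
        backbone = build_backbone(BackboneConfig(), seed=spec.seed)
    teacher = None
    gen_net = backbone
    if teacher_perturb_depth is not None:
        teacher = _perturb_backbone(spec, backbone, teacher_perturb_depth,
                                    perturb_scale)
        gen_net = teacher
    manifest = gen_manifest(spec)

    waveforms = {}
    features = {}
    for record in manifest:
        stim = _run_key(record)[1:]         # same audio for every subject
        if stim not in features:
            wav = gen_audio(spec, record)
            feats = _features_for(spec, gen_net, wav)
            features[stim] = (wav, feats)
        waveforms[record.key] = features[stim][0]

    subjects = manifest.subjects()
    kernels, biases = {}, {}
    feat_list = [f for _, f in features.values()]
    for i, subject in enumerate(subjects):
        if spec.shared_mapping and kernels:
            first = subjects[0]
            kernels[subject], biases[subject] = kernels[first], biases[first]
        else:
            kernels[subject], biases[subject] = plant_kernels(
                spec, feat_list, subject_seed=0 if spec.shared_mapping else i)

    bolds = {}
    for record in manifest:
        stim = _run_key(record)[1:]
        feats = features[stim][1]
        design = lagged_design(feats.astype(np.float64), spec.kernel_size)
        h = kernels[record.subject].reshape(spec.n_targets, -1)
        signal = design @ h.T.astype(np.float64) + biases[record.subject]
        if spec.lag:
            shifted = np.zeros_like(signal)
            shifted[spec.lag:] = signal[: signal.shape[0] - spec.lag]
            signal = shifted
        noise_rng = spec.rng("noise", *_run_key(record))
        values = signal + spec.noise_sigma * noise_rng.standard_normal(
            signal.shape)
        labels = [f"t{i:04d}" for i in range(spec.n_targets)]
        bolds[record.key] = BoldMatrix(values, labels, space="custom")

    return SyntheticDataset(spec=spec, manifest=manifest, backbone=backbone,
                            waveforms=waveforms, bolds=bolds, kernels=kernels,
                            biases=biases, teacher=teacher)


def gen_tag_table(spec: SyntheticSpec, manifest: Manifest,
                  categories=DEFAULT_CATEGORIES,
                  category_means=_CATEGORY_MEANS,
                  season_shifts: dict | None = None,
                  concentration: float = 50.0,
                  excerpt_seconds: float = 10.0) -> pd.DataFrame:
    """Per-excerpt label proportions for every run in the manifest.

    Each run's audio is notionally cut into 10 s excerpts (trailing partial
    excerpt excluded); each category's proportion is a Beta draw around its
    mean, optionally shifted per season via ``season_shifts`` mapping
    ``(season, category) -> shift``.  Proportions of different categories
    may overlap (labels are not exclusive), as with real audio taggers.
    """
    season_shifts = season_shifts or {}
    rows = []
    for record in manifest:
        run_seconds = record.n_tr * record.tr_seconds
        n_exc = int(run_seconds // excerpt_seconds)
        rng = spec.rng("tags", *_run_key(record))
        run_id = f"{record.subject}_s{record.season:02d}" \
                 f"e{record.episode:02d}{record.segment}"
        for j in range(n_exc):
            row = {"run_id": run_id, "subject": record.subject,
                   "season": record.season, "excerpt": j,
                   "start_s": j * excerpt_seconds}
            for cat, mean in zip(categories, category_means):
                m = float(np.clip(
                    mean + season_shifts.get((record.season, cat), 0.0),
                    1e-3, 1 - 1e-3))
                row[cat] = rng.beta(m * concentration,
                                    (1 - m) * concentration)
            rows.append(row)
    return pd.DataFrame(rows)
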