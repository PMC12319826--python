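"""Run manifests, train/validation splits, audio and BOLD I/O, windowing.

A *run* is one half-episode: a subject listened to (and watched) half an
episode while BOLD volumes were acquired every TR = 1.49 s.  The pipeline
pairs each run's mono 22,050 Hz waveform with its TR x targets BOLD matrix
and cuts both into aligned, non-overlapping windows of W TRs for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io.wavfile
import scipy.signal

__all__ = [
    "TR_SECONDS", "SAMPLE_RATE",
    "RunRecord", "Manifest", "BoldMatrix", "SplitSpec",
    "split_runs", "load_audio", "save_audio", "window_run", "window_samples",
    "extract_bold", "read_bold_tsv", "write_bold_tsv",
]

TR_SECONDS = 1.49
SAMPLE_RATE = 22050

MANIFEST_COLUMNS = ["subject", "season", "episode", "segment",
                    "audio_path", "bold_path", "n_tr"]


@dataclass(frozen=True)
class RunRecord:
    """One fMRI run (half-episode)."""
    subject: str
    season: int
    episode: int
    segment: str            # "a" | "b"
    audio_path: str
    bold_path: str
    n_tr: int
    tr_seconds: float = TR_SECONDS

    def __post_init__(self):
        if self.n_tr < 1:
            raise ValueError("n_tr must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.subject, self.season, self.episode, self.segment)


@dataclass
class Manifest:
    runs: list[RunRecord] = field(default_factory=list)

    def __post_init__(self):
        keys = [r.key for r in self.runs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject, season, episode, segment)")

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)

    def subset(self, subject=None, season=None) -> "Manifest":
        runs = [r for r in self.runs
                if (subject is None or r.subject == subject)
                and (season is None or r.season == season)]
        return Manifest(runs)

    def subjects(self) -> list[str]:
        return sorted({r.subject for r in self.runs})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{c: getattr(r, c) for c in MANIFEST_COLUMNS}
                             for r in self.runs])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Manifest":
        df = pd.read_csv(path)
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        runs = [RunRecord(subject=str(row.subject), season=int(row.season),
                          episode=int(row.episode), segment=str(row.segment),
                          audio_path=str(row.audio_path),
                          bold_path=str(row.bold_path), n_tr=int(row.n_tr))
                for row in df.itertuples()]
        return cls(runs)


@dataclass
class BoldMatrix:
    """n_TR x n_targets BOLD time series with target labels."""
    values: np.ndarray
    target_labels: list[str]
    space: str = "custom"   # "parcels-210" | "voxels-556" | "custom"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("BOLD values must be 2-D (TR x targets)")
        if self.values.shape[1] != len(self.target_labels):
            raise ValueError("target label count must match columns")
        if not np.isfinite(self.values).all():
            raise ValueError("BOLD matrix contains missing/non-finite values")

    @property
    def n_tr(self) -> int:
        return self.values.shape[0]

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]


def write_bold_tsv(bold: BoldMatrix, path: str | Path) -> None:
    pd.DataFrame(bold.values, columns=bold.target_labels).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_bold_tsv(path: str | Path, space: str = "custom") -> BoldMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return BoldMatrix(df.to_numpy(dtype=np.float64),
                      [str(c) for c in df.columns], space=space)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.75
    seed: int = 0
    level: str = "run"

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_runs(manifest: Manifest, spec: SplitSpec = SplitSpec()
               ) -> tuple[Manifest, Manifest]:
    """Seeded run-level shuffle; train gets floor(fraction * total) runs.

    146 runs at 0.75 reproduce the canonical 109 / 37 partition.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    order = np.random.default_rng(spec.seed).permutation(len(manifest))
    n_train = int(np.floor(spec.train_fraction * len(manifest)))
    train_idx = set(order[:n_train].tolist())
    train = [r for i, r in enumerate(manifest.runs) if i in train_idx]
    val = [r for i, r in enumerate(manifest.runs) if i not in train_idx]
    return Manifest(train), Manifest(val)


def load_audio(path: str | Path, target_rate: int = SAMPLE_RATE) -> np.ndarray:
    """Read a WAV file as a mono float waveform at ``target_rate`` Hz.

    Multi-channel audio is averaged across channels; integer PCM is scaled
    to [-1, 1]; resampling is polyphase (exact rational rate conversion).
    """
    path = Path(path)
    try:
        rate, data = scipy.io.wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface format problems as I/O
        raise IOError(f"could not read audio file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if rate != target_rate:
        g = np.gcd(int(rate), int(target_rate))
        data = scipy.signal.resample_poly(data, target_rate // g, rate // g)
    return data.astype(np.float32)


def save_audio(path: str | Path, waveform: np.ndarray,
               rate: int = SAMPLE_RATE) -> None:
    scipy.io.wavfile.write(path, rate, np.asarray(waveform, dtype=np.float32))


def window_samples(n_tr: int, tr_seconds: float = TR_SECONDS,
                   sample_rate: int = SAMPLE_RATE) -> int:
    """Audio samples spanning ``n_tr`` TRs: round(n_tr * 1.49 * 22050)."""
    return int(round(n_tr * tr_seconds * sample_rate))


def window_run(bold: BoldMatrix, waveform: np.ndarray, w: int,
               tr_seconds: float = TR_SECONDS,
               sample_rate: int = SAMPLE_RATE
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut a run into consecutive non-overlapping (audio, BOLD) windows of
    ``w`` TRs; the incomplete tail is dropped.  Audio and BOLD windows span
    the same time interval (no lag shift — the head's FIR kernel absorbs the
    haemodynamic delay)."""
    n_tr = bold.n_tr
    if w > n_tr:
        raise ValueError(f"window of {w} TRs exceeds run length {n_tr}")
    waveform = np.asarray(waveform, dtype=np.float32).ravel()
    # tolerate small audio/BOLD duration mismatch: truncate to the shorter
    n_tr = min(n_tr, int(waveform.size / (tr_seconds * sample_rate)))
    n_win = n_tr // w
    wlen = window_samples(w, tr_seconds, sample_rate)
    out = []
    for j in range(n_win):
        t0 = j * w
        s0 = window_samples(t0, tr_seconds, sample_rate)
        out.append((waveform[s0: s0 + wlen], bold.values[t0: t0 + w]))
    return out


def extract_bold(nifti_img, atlas_img, smoothing_fwhm: float | None = None,
                 mode: str = "auto") -> BoldMatrix:
    """Extract a TR x targets matrix from a 4-D NIfTI volume.

    ``atlas_img`` is either an integer-label parcellation (parcel mode:
    per-label voxel mean per TR, via nilearn's NiftiLabelsMasker) or a
    binary mask (voxel mode: one column per voxel, via NiftiMasker).
    Optional Gaussian smoothing (e.g. 5 mm FWHM) is applied before
    extraction.
    """
    import nibabel as nib
    from nilearn.maskers import NiftiLabelsMasker, NiftiMasker

    if isinstance(nifti_img, (str, Path)):
        nifti_img = nib.load(str(nifti_img))
    if isinstance(atlas_img, (str, Path)):
        atlas_img = nib.load(str(atlas_img))
    if nifti_img.shape[:3] != atlas_img.shape[:3]:
        raise ValueError(
            f"volume grid {nifti_img.shape[:3]} does not match atlas grid "
            f"{atlas_img.shape[:3]}")
    atlas_data = np.asanyarray(atlas_img.dataobj)
    labels = np.unique(atlas_data[atlas_data != 0]).astype(int)
    binary = mode == "mask" or (mode == "auto" and set(labels.tolist()) <= {1})
    if binary:
        masker = NiftiMasker(mask_img=atlas_img, smoothing_fwhm=smoothing_fwhm,
                             standardize=False)
        values = masker.fit_transform(nifti_img)
        names = [f"voxel{i:04d}" for i in range(values.shape[1])]
        space = "voxels-556" if values.shape[1] == 556 else "custom"
    else:
        masker = NiftiLabelsMasker(labels_img=atlas_img,
                                   smoothing_fwhm=smoothing_fwhm,
                                   standardize=False)
        values = masker.fit_transform(nifti_img)
        names = [f"parcel{int(label):03d}" for label in labels]
        space = "parcels-210" if values.shape[1] == 210 else "custom"
    return BoldMatrix(values.astype(np.float64), names, space=space)
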