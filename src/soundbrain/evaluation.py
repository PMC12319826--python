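"""Model evaluation: r^2 scoring, null models, paired statistics, transfer.

Encoding quality is the per-target coefficient of determination r^2 between
predicted and observed BOLD, computed per run (and allowed to be negative).
Model comparisons are paired across runs: a two-sided Wilcoxon signed-rank
test per target, corrected across targets with the Benjamini-Yekutieli
false-discovery-rate procedure (valid under arbitrary dependence between
targets), significant at q < 0.05.  The significance reference is a null
model with the same architecture but random, untrained weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .backbone import BackboneConfig, build_backbone
from .encoding import EncodingModel, build_head

__all__ = [
    "EvalTable", "StatResult", "TransferResult",
    "r2_scores", "make_null_model", "signed_rank_test", "compare_models",
    "percent_diff_map", "transfer_matrix",
]

# sample size at which the signed-rank test switches from the exact null
# distribution to the normal approximation
EXACT_N_MAX = 25


@dataclass
class EvalTable:
    """Per-run, per-target r^2 for one model/subject — the unit of all
    statistics."""
    r2: np.ndarray                      # (n_runs, n_targets)
    model_id: str = ""
    subject_id: str = ""
    dataset_tag: str = ""
    run_ids: list[str] | None = None
    target_labels: list[str] | None = None

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=np.float64)
        if self.r2.ndim != 2:
            raise ValueError("r2 must be 2-D (runs x targets)")
        if np.nanmax(self.r2, initial=-np.inf) > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        if self.run_ids is None:
            self.run_ids = [f"run{i:03d}" for i in range(self.r2.shape[0])]
        if self.target_labels is None:
            self.target_labels = [f"t{i:04d}" for i in range(self.r2.shape[1])]

    @property
    def n_runs(self) -> int:
        return self.r2.shape[0]

    @property
    def n_targets(self) -> int:
        return self.r2.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.run_ids,
                     columns=self.target_labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, **meta) -> "EvalTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), run_ids=[str(i) for i in df.index],
                   target_labels=[str(c) for c in df.columns], **meta)


@dataclass
class StatResult:
    """Per-target paired-test outcome."""
    p: np.ndarray                 # raw two-sided Wilcoxon p
    q: np.ndarray                 # Benjamini-Yekutieli adjusted
    significant: np.ndarray       # q < alpha
    median_diff: np.ndarray       # median paired r^2 difference
    alpha: float = 0.05
    target_labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p": self.p, "q": self.q,
                             "significant": self.significant,
                             "median_diff": self.median_diff},
                            index=self.target_labels or None)


def r2_scores(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Per-column r^2 = 1 - SS_res / SS_tot (SS_tot about the column mean).

    Columns of ``actual`` with zero variance have no defined r^2 and are
    returned as NaN with a warning.
    """
    pred = np.asarray(pred, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if pred.shape != actual.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    if pred.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    ss_res = ((actual - pred) ** 2).sum(axis=0)
    ss_tot = ((actual - actual.mean(axis=0)) ** 2).sum(axis=0)
    out = np.full(pred.shape[1], np.nan)
    ok = ss_tot > 0
    out[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} constant target column(s): r^2 undefined",
                      RuntimeWarning, stacklevel=2)
    return out


def make_null_model(n_targets: int, kernel_size: int = 5, tap: str = "conv7",
                    seed: int = 0, target_space=None) -> EncodingModel:
    """Same architecture, seeded random untrained weights."""
    net = build_backbone(BackboneConfig(), seed=seed)
    head = build_head(net.channels_at(tap), n_targets, kernel_size,
                      seed=seed + 1)
    return EncodingModel(net, head, tap=tap, target_space=target_space)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided p by dynamic programming over the null distribution
    of the positive rank sum.  Midranks for tied |d| are doubled so all
    weights are integers; equivalent to enumerating all 2^n sign patterns.
    """
    ranks = rankdata(np.abs(diffs))
    weights = np.rint(2 * ranks).astype(np.int64)
    w_pos = int(weights[diffs > 0].sum())
    total = int(weights.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for w in weights:
        shifted = np.zeros_like(counts)
        shifted[w:] = counts[:total + 1 - w]
        counts += shifted
    dev = abs(2 * w_pos - total)
    support = np.abs(2 * np.arange(total + 1) - total)
    p = counts[support >= dev].sum() / 2.0 ** len(diffs)
    return min(float(p), 1.0)


def _approx_signed_rank_p(diffs: np.ndarray) -> float:
    """Normal approximation with tie correction (no continuity correction)."""
    n = len(diffs)
    ranks = rankdata(np.abs(diffs))
    w_pos = ranks[diffs > 0].sum()
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_pos - mean) / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def signed_rank_test(diffs: np.ndarray, method: str = "auto") -> float:
    """Two-sided Wilcoxon signed-rank p for paired differences.

    Zero differences are dropped (standard signed-rank practice).  The exact
    null distribution is used for n <= 25 (``method="auto"``), the
    tie-corrected normal approximation beyond that.
    """
    diffs = np.asarray(diffs, dtype=np.float64)
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 1.0
    if method == "exact" or (method == "auto" and diffs.size <= EXACT_N_MAX):
        return _exact_signed_rank_p(diffs)
    return _approx_signed_rank_p(diffs)


def compare_models(a: EvalTable, b: EvalTable, alpha: float = 0.05,
                   method: str = "auto") -> StatResult:
    """Paired per-target comparison of two models over the same runs:
    Wilcoxon signed-rank on per-run r^2 differences, Benjamini-Yekutieli
    step-up across targets, significant at q < alpha."""
    if a.r2.shape != b.r2.shape:
        raise ValueError(f"table shapes differ: {a.r2.shape} vs {b.r2.shape}")
    if a.run_ids != b.run_ids:
        raise ValueError("tables cover different runs")
    diffs = a.r2 - b.r2
    p = np.array([signed_rank_test(diffs[:, j], method=method)
                  for j in range(diffs.shape[1])])
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_by")
    return StatResult(p=p, q=q, significant=q < alpha,
                      median_diff=np.median(diffs, axis=0), alpha=alpha,
                      target_labels=list(a.target_labels))


def percent_diff_map(aligned: EvalTable, baseline: EvalTable,
                     stats: StatResult, r2_threshold: float = 0.05
                     ) -> np.ndarray:
    """Percent change in mean r^2 per target, masked (NaN) where the aligned
    model's |mean r^2| < threshold or the difference is not significant."""
    if aligned.r2.shape != baseline.r2.shape:
        raise ValueError("tables not comparable")
    mean_a = aligned.r2.mean(axis=0)
    mean_b = baseline.r2.mean(axis=0)
    out = np.full(mean_a.shape, np.nan)
    shown = (np.abs(mean_a) >= r2_threshold) & stats.significant
    zero_base = shown & (mean_b == 0)
    if zero_base.any():
        warnings.warn(f"{zero_base.sum()} target(s) with zero baseline mean "
                      "r^2: percent change undefined", RuntimeWarning,
                      stacklevel=2)
        shown &= ~zero_base
    out[shown] = 100.0 * (mean_a[shown] - mean_b[shown]) / mean_b[shown]
    return out


@dataclass
class TransferResult:
    """Cross-subject transfer summary.

    ``max_r2[i, j]``: mean over subject-j runs of the per-run maximum (over
    targets) r^2 of subject-i's model.  ``diff_vs_matched`` and ``p`` compare
    each (model i, data j) cell against the matched model (model j on its own
    data) across runs.
    """
    max_r2: pd.DataFrame
    diff_vs_matched: pd.DataFrame
    p: pd.DataFrame
    per_run_max: dict


def transfer_matrix(models: dict, runs_by_subject: dict, w: int,
                    method: str = "auto") -> TransferResult:
    """Apply every subject's model to every subject's test runs."""
    from .training import evaluate_runs  # local import: avoid cycle

    subjects = sorted(models)
    if sorted(runs_by_subject) != subjects:
        raise ValueError("models and test runs must cover the same subjects")
    n_targets = {s: models[s].n_targets for s in subjects}
    if len(set(n_targets.values())) != 1:
        raise ValueError(f"models disagree on target space: {n_targets}")

    per_run = {}
    for mi in subjects:
        for dj in subjects:
            r2 = evaluate_runs(models[mi], runs_by_subject[dj], w)
            per_run[(mi, dj)] = np.nanmax(r2, axis=1)

    mat = pd.DataFrame(index=subjects, columns=subjects, dtype=float)
    diff = pd.DataFrame(index=subjects, columns=subjects, dtype=float)
    pval = pd.DataFrame(index=subjects, columns=subjects, dtype=float)
    for mi in subjects:
        for dj in subjects:
            mat.loc[mi, dj] = per_run[(mi, dj)].mean()
            d = per_run[(mi, dj)] - per_run[(dj, dj)]
            diff.loc[mi, dj] = d.mean()
            pval.loc[mi, dj] = signed_rank_test(d, method=method)
    return TransferResult(max_r2=mat, diff_vs_matched=diff, p=pval,
                          per_run_max=per_run)
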