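"""Audio-annotation aggregation and the two OLS analyses built on it.

An external tagger labels every 10-s excerpt of a run's audio with the
proportion of audio carried by each category (proportions of different
categories may overlap).  This module aggregates excerpt proportions to
run level, filters rare categories, tests whether category prevalence
differs between seasons, and regresses per-run encoding gains on per-run
deviations in category prevalence.  All model fits go through statsmodels
OLS; the per-category season test uses season indicator contrasts, with
pairwise coefficient tests at the stated alpha (no multiplicity correction
across categories — flagged in the docs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["aggregate_run_proportions", "select_categories",
           "season_comparison", "delta_r2_regression"]

_META = ("run_id", "subject", "season", "excerpt", "start_s")


def _categories(tags: pd.DataFrame) -> list[str]:
    return [c for c in tags.columns if c not in _META]


def aggregate_run_proportions(tags: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean proportion per category over a run's 10-s excerpts.

    The tag table already excludes any trailing partial excerpt; every run
    must contribute at least one excerpt.
    """
    cats = _categories(tags)
    if tags.empty or tags.groupby("run_id").size().min() < 1:
        raise ValueError("every run needs at least one excerpt")
    bad = [c for c in cats
           if (tags[c] < 0).any() or (tags[c] > 1).any()]
    if bad:
        raise ValueError(f"proportions outside [0, 1] for {bad}")
    keys = [k for k in ("subject", "season") if k in tags.columns]
    out = tags.groupby(["run_id"] + keys, as_index=False)[cats].mean()
    return out


def select_categories(run_props: pd.DataFrame,
                      threshold: float = 0.01) -> list[str]:
    """Categories whose overall mean proportion is at least ``threshold``
    (default: at least 1% of the audio recognised under the label)."""
    cats = _categories(run_props)
    keep = [c for c in cats if run_props[c].mean() >= threshold]
    if not keep:
        warnings.warn("no category reaches the prevalence threshold",
                      RuntimeWarning, stacklevel=2)
    return keep


def season_comparison(run_props: pd.DataFrame, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Per-category OLS of run proportion on season indicators, with a
    pairwise coefficient test for every season pair.

    Returns one row per (category, season_a, season_b) with the estimated
    mean difference, p-value and significance at ``alpha``.
    """
    seasons = sorted(run_props["season"].unique())
    if len(seasons) < 2:
        raise ValueError("need at least 2 seasons")
    counts = run_props.groupby("season").size()
    if counts.min() < 2:
        raise ValueError("need at least 2 runs per season")
    dummies = pd.get_dummies(run_props["season"], prefix="season",
                             dtype=float)
    design = sm.add_constant(dummies.iloc[:, 1:])  # first season = reference
    rows = []
    for cat in _categories(run_props):
        fit = sm.OLS(run_props[cat].to_numpy(), design).fit()
        for i, s_a in enumerate(seasons):
            for s_b in seasons[i + 1:]:
                contrast = np.zeros(design.shape[1])
                if s_a != seasons[0]:
                    contrast[design.columns.get_loc(f"season_{s_a}")] = 1.0
                if s_b != seasons[0]:
                    contrast[design.columns.get_loc(f"season_{s_b}")] -= 1.0
                test = fit.t_test(contrast)
                p = float(np.squeeze(test.pvalue))
                rows.append({"category": cat, "season_a": s_a,
                             "season_b": s_b,
                             "mean_diff": float(np.squeeze(test.effect)),
                             "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


@dataclass
class DeltaR2Regression:
    params: pd.Series
    pvalues: pd.Series
    significant: pd.Series
    condition_number: float
    fit: object


def delta_r2_regression(delta: pd.Series, run_props: pd.DataFrame,
                        categories=None, alpha: float = 0.05
                        ) -> DeltaR2Regression:
    """OLS of per-run encoding gain on per-run annotation deviations.

    ``delta`` is the per-run difference in max-over-targets r^2 between two
    models, indexed by run_id; regressors are each category's deviation
    from its mean proportion over these runs, plus an intercept.
    """
    props = run_props.set_index("run_id") if "run_id" in run_props.columns \
        else run_props
    cats = categories or [c for c in props.columns if c not in _META]
    common = [r for r in delta.index if r in props.index]
    if len(common) != len(delta):
        raise ValueError("delta and proportions cover different runs")
    x = props.loc[common, cats].astype(float)
    x = x - x.mean(axis=0)                      # centre per category
    design = sm.add_constant(x)
    fit = sm.OLS(delta.loc[common].to_numpy(), design).fit()
    cond = float(np.linalg.cond(design.to_numpy()))
    if cond > 1e8:
        warnings.warn(f"ill-conditioned design (cond={cond:.2g}): "
                      "collinear regressors", RuntimeWarning, stacklevel=2)
    params = pd.Series(fit.params, index=design.columns)
    pvals = pd.Series(fit.pvalues, index=design.columns)
    return DeltaR2Regression(params=params, pvalues=pvals,
                             significant=pvals < alpha,
                             condition_number=cond, fit=fit)
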