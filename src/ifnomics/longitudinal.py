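"""On/off-drug longitudinal case analysis.

One subject, repeated blood draws while taking a JAK inhibitor and during
treatment interruptions. Three questions: how do individual features (e.g.
the non-chr21 ISGs) move between on- and off-drug draws; where do the
subject's IFN scores sit relative to the cross-sectional cohort's control
and T21 interquartile bands; and does the on-drug score distribution fall
below the off-drug one.

The subject is always scored against the cross-sectional cohort's frozen
control reference stats, never against their own draws, so scores live on
the cohort's scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust
from .synthetic import LongitudinalSeries

__all__ = ["ReferenceBands", "on_off_fold_changes", "reference_bands",
           "score_trajectory_report"]


@dataclass
class ReferenceBands:
    """Median and quartiles of cohort IFN scores per karyotype group."""

    control: dict[str, float]       # {"q1", "median", "q3"}
    t21: dict[str, float]

    def __post_init__(self):
        for band in (self.control, self.t21):
            if not band["q1"] <= band["median"] <= band["q3"]:
                raise ValueError("quartiles out of order")


def on_off_fold_changes(
    series: LongitudinalSeries,
    gene_list: list[str] | None = None,
    log_means: bool = True,
) -> pd.DataFrame:
    """Per-feature log2 fold change of on-drug vs off-drug draws.

    Default contrasts geometric means (means of log2 values); two-sided
    Mann-Whitney p per feature across draws, BH across features. With a
    single draw in one status the fold change is still computed but p is
    missing (warned). ``gene_list`` restricts the features (e.g. the
    non-chr21 ISG panel).
    """
    expr = series.expression
    if gene_list is not None:
        missing = [g for g in gene_list if g not in expr.index]
        if missing:
            raise KeyError(f"features absent from series: {missing[:5]}")
        expr = expr.loc[gene_list]
    if (expr.to_numpy() <= 0).any():
        raise ValueError("feature values must be positive")
    on_cols = series.status.index[series.status == "on"]
    off_cols = series.status.index[series.status == "off"]
    if len(on_cols) == 0 or len(off_cols) == 0:
        raise ValueError("need at least one draw in each treatment status")

    log_on, log_off = np.log2(expr[on_cols]), np.log2(expr[off_cols])
    if log_means:
        l2fc = log_on.mean(axis=1) - log_off.mean(axis=1)
    else:
        l2fc = np.log2(expr[on_cols].mean(axis=1) / expr[off_cols].mean(axis=1))

    if len(on_cols) == 1 or len(off_cols) == 1:
        warnings.warn("single draw in one status; fold changes computed, p missing")
        pvals = np.full(len(expr), np.nan)
    else:
        pvals = np.array([
            stats.mannwhitneyu(log_on.iloc[i], log_off.iloc[i],
                               alternative="two-sided", method="auto").pvalue
            for i in range(len(expr))
        ])
    return pd.DataFrame({"log2fc_on_off": l2fc, "p": pvals,
                         "q": bh_adjust(pvals)}, index=expr.index)


def reference_bands(
    cohort_scores: pd.Series,
    metadata: pd.DataFrame,
    group: str = "karyotype",
) -> ReferenceBands:
    """Median/Q1/Q3 of cohort IFN scores per karyotype group (type-7 quantiles)."""
    kar = metadata.loc[cohort_scores.index, group]
    bands = {}
    for name in ("control", "T21"):
        vals = cohort_scores[kar == name].dropna()
        if len(vals) == 0:
            raise ValueError(f"no {name} samples for reference bands")
        bands[name] = {
            "q1": float(vals.quantile(0.25)),
            "median": float(vals.quantile(0.5)),
            "q3": float(vals.quantile(0.75)),
        }
    return ReferenceBands(control=bands["control"], t21=bands["T21"])


def _classify(score: float, bands: ReferenceBands) -> str:
    if bands.control["q1"] <= score <= bands.control["q3"]:
        return "within_control_range"
    if bands.t21["q1"] <= score <= bands.t21["q3"]:
        return "within_t21_range"
    if bands.control["q3"] < score < bands.t21["q1"]:
        return "between_ranges"
    if score < bands.control["q1"]:
        return "below_control_range"
    return "above_t21_range"


def score_trajectory_report(
    draw_scores: pd.Series,
    status: pd.Series,
    bands: ReferenceBands,
) -> dict:
    """Per-draw band classification plus an on-vs-off score contrast.

    ``draw_scores`` must come from scoring the series against the cohort's
    frozen reference stats. Classification is order-invariant; the summary
    flags whether the on-drug median falls below the off-drug median and
    reports the two-sided Mann-Whitney p.
    """
    if bands is None:
        raise ValueError("reference bands are required")
    status = status.loc[draw_scores.index]
    classes = draw_scores.map(lambda s: _classify(float(s), bands))
    on = draw_scores[status == "on"].to_numpy(float)
    off = draw_scores[status == "off"].to_numpy(float)
    if len(on) and len(off):
        p = float(stats.mannwhitneyu(on, off, alternative="two-sided",
                                     method="auto").pvalue)
    else:
        p = np.nan
    return {
        "classification": pd.DataFrame({"score": draw_scores, "status": status,
                                        "band": classes}),
        "on_median": float(np.median(on)) if len(on) else np.nan,
        "off_median": float(np.median(off)) if len(off) else np.nan,
        "on_below_off": bool(len(on) and len(off)
                             and np.median(on) < np.median(off)),
        "mannwhitney_p": p,
    }
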