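"""Group comparison and replicate-level aggregation.

Per replicate, participant-level metric values are averaged into group means
and the two groups are compared with a two-sample t test (Welch's
unequal-variance test by default; Student's pooled test by flag). Across
replicates, the sweep-style summaries report the mean of the group means,
raincloud-ready spread quantiles, the median p value, and the fraction of
replicates reaching significance at alpha = .05.

Participants whose metric is undefined (NaN marker, e.g. every trial of one
truth class excluded as inconclusive) are dropped from the group mean with
the dropped count recorded — never imputed.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES

ALPHA = 0.05

QUANTILES = (0.10, 0.25, 0.50, 0.75, 0.90)


def _two_sample_t(a: np.ndarray, b: np.ndarray, welch: bool) -> Tuple[float, float, float]:
    """(t, p, df) for a two-sided two-sample comparison."""
    if a.size < 2 or b.size < 2:
        return math.nan, math.nan, math.nan
    with warnings.catch_warnings():
        # near-ceiling steps produce nearly identical samples; the resulting
        # precision-loss warning is expected there and p ~ 1 is correct
        warnings.filterwarnings(
            "ignore", message="Precision loss occurred", category=RuntimeWarning
        )
        res = stats.ttest_ind(a, b, equal_var=not welch)
    df = getattr(res, "df", math.nan)
    return float(res.statistic), float(res.pvalue), float(df)


def summarize_replicate(
    metric_table: pd.DataFrame,
    groups: Optional[Sequence[str]] = None,
    metrics: Optional[Sequence[str]] = None,
    welch: bool = True,
) -> pd.DataFrame:
    """Group means and a between-group t test for one replicate's metric table.

    Returns one row per metric with the two group means, their difference,
    the t statistic, two-sided p value, degrees of freedom, and the count of
    undefined participant values dropped from each group.
    """
    if groups is None:
        groups = sorted(metric_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    g1, g2 = groups
    if metrics is None:
        metrics = [m for m in METRIC_NAMES if m in metric_table.columns]

    rows = []
    sub1 = metric_table[metric_table["group"] == g1]
    sub2 = metric_table[metric_table["group"] == g2]
    for m in metrics:
        a = sub1[m].to_numpy(dtype=float)
        b = sub2[m].to_numpy(dtype=float)
        a_ok, b_ok = a[~np.isnan(a)], b[~np.isnan(b)]
        t, p, df = _two_sample_t(a_ok, b_ok, welch)
        rows.append(
            {
                "metric": m,
                "group_a": g1,
                "group_b": g2,
                "mean_a": a_ok.mean() if a_ok.size else math.nan,
                "mean_b": b_ok.mean() if b_ok.size else math.nan,
                "diff": (a_ok.mean() - b_ok.mean())
                if a_ok.size and b_ok.size
                else math.nan,
                "t": t,
                "p": p,
                "df": df,
                "n_a": int(a_ok.size),
                "n_b": int(b_ok.size),
                "n_dropped_a": int(a.size - a_ok.size),
                "n_dropped_b": int(b.size - b_ok.size),
            }
        )
    return pd.DataFrame(rows)


def summarize_replicates(
    metric_table: pd.DataFrame,
    groups: Optional[Sequence[str]] = None,
    metrics: Optional[Sequence[str]] = None,
    welch: bool = True,
) -> pd.DataFrame:
    """Per-replicate summaries for a metric table spanning many replicates."""
    if "replicate" not in metric_table.columns:
        metric_table = metric_table.assign(replicate=0)
    parts = []
    for rep, sub in metric_table.groupby("replicate", sort=True):
        s = summarize_replicate(sub, groups=groups, metrics=metrics, welch=welch)
        s.insert(0, "replicate", rep)
        parts.append(s)
    return pd.concat(parts, ignore_index=True)


def summarize_across_replicates(
    replicate_summaries: pd.DataFrame, alpha: float = ALPHA
) -> pd.DataFrame:
    """Sweep-level summary across replicates, tidy by (metric, group).

    For each metric and group: the mean of the per-replicate group means and
    their spread quantiles (q10..q90, raincloud-style); alongside, per metric:
    the median p value, the median absolute t statistic, and the fraction of
    replicates with p < alpha.
    """
    rows = []
    for metric, sub in replicate_summaries.groupby("metric", sort=False):
        p = sub["p"].to_numpy(dtype=float)
        p_ok = p[~np.isnan(p)]
        median_p = float(np.median(p_ok)) if p_ok.size else math.nan
        frac_sig = float(np.mean(p_ok < alpha)) if p_ok.size else math.nan
        t_abs = np.abs(sub["t"].to_numpy(dtype=float))
        t_ok = t_abs[~np.isnan(t_abs)]
        median_t = float(np.median(t_ok)) if t_ok.size else math.nan
        for side in ("a", "b"):
            means = sub[f"mean_{side}"].to_numpy(dtype=float)
            means = means[~np.isnan(means)]
            row = {
                "metric": metric,
                "group": sub[f"group_{side}"].iloc[0],
                "mean": float(np.mean(means)) if means.size else math.nan,
            }
            for q in QUANTILES:
                row[f"q{int(q * 100)}"] = (
                    float(np.quantile(means, q)) if means.size else math.nan
                )
            row["median_p"] = median_p
            row["median_abs_t"] = median_t
            row["frac_significant"] = frac_sig
            row["n_replicates"] = int(len(sub))
            rows.append(row)
    return pd.DataFrame(rows)
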