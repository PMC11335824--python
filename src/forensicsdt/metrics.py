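"""Performance models for source-decision data.

Implements the measurement models commonly applied to forensic comparison
decisions: proportion correct, the diagnosticity ratio (hit rate / false-alarm
rate), the equal-variance Gaussian index d' = z(H) - z(F), the corrected
area-based index A' (Zhang-Mueller form), the empirical trapezoidal ROC area
(equal to the pairwise wins-plus-half-ties statistic), and the table-derived
diagnostic accuracies (sensitivity, specificity, PPV, NPV, and the
inconclusive predictive values IPPV/INPV).

Extreme hit or false-alarm rates (exactly 0 or 1) make d' and the
diagnosticity ratio degenerate; two standard corrections are provided:

* ``macmillan_kaplan`` -- replace a rate of 0 by 0.5/n and a rate of 1 by
  (n - 0.5)/n, leaving all other rates untouched (the default).
* ``loglinear`` -- add 0.5 to each count and 1 to each trial total, i.e.
  every rate becomes (count + 0.5)/(n + 1).

Undefined quantities (zero denominators, uncorrected extreme rates) are
reported as NaN markers, never as silent numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .classification import (
    DEFAULT_SCALE,
    SAME,
    BinaryTable,
    RecordsLike,
    TernaryTable,
    records_to_frame,
    scale_midpoint,
)

CORRECTIONS = ("none", "macmillan_kaplan", "loglinear")
POLICIES = ("exclude", "midpoint")


@dataclass(frozen=True)
class RatePair:
    """A hit rate and false-alarm rate with their trial counts."""

    hit_rate: float
    fa_rate: float
    n_signal: int
    n_noise: int

    def __post_init__(self) -> None:
        if self.n_signal < 1 or self.n_noise < 1:
            raise ValueError("n_signal and n_noise must be >= 1")
        for name in ("hit_rate", "fa_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class MetricSet:
    """Per-unit performance numbers; NaN marks an undefined value."""

    proportion_correct: float = math.nan
    diagnosticity: float = math.nan
    d_prime: float = math.nan
    a_prime: float = math.nan
    auc: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    ippv: float = math.nan
    inpv: float = math.nan

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Metric column order for tidy output tables.
METRIC_NAMES = tuple(f.name for f in fields(MetricSet))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def rates_and_predictive_values(table: BinaryTable) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV and proportion correct from a 2x2 table.

    Each quantity whose denominator is zero is returned as NaN; the others are
    still computed.
    """
    h, m = table.hits, table.misses
    fa, cr = table.false_alarms, table.correct_rejections
    out = MetricSet()
    out.sensitivity = _safe_div(h, h + m)
    out.specificity = _safe_div(cr, fa + cr)
    out.ppv = _safe_div(h, h + fa)
    out.npv = _safe_div(cr, cr + m)
    out.proportion_correct = _safe_div(h + cr, table.total)
    return out


def ternary_predictive_values(table: TernaryTable) -> MetricSet:
    """Diagnostic accuracies for a 2x3 table with inconclusive decisions.

    Inconclusive decisions enter the denominators of sensitivity and
    specificity (they are decisions on trials of that ground-truth state) but
    never the numerators. IPPV is the share of inconclusive calls that were
    same-source pairs; INPV = 1 - IPPV.
    """
    out = MetricSet()
    out.sensitivity = _safe_div(table.hits, table.n_same)
    out.specificity = _safe_div(table.correct_rejections, table.n_diff)
    out.ppv = _safe_div(table.hits, table.hits + table.false_alarms)
    out.npv = _safe_div(
        table.correct_rejections, table.correct_rejections + table.misses
    )
    n_inc = table.n_inconclusive
    out.ippv = _safe_div(table.inconclusive_same, n_inc)
    out.inpv = 1.0 - out.ippv if n_inc > 0 else math.nan
    out.proportion_correct = _safe_div(
        table.hits + table.correct_rejections, table.total
    )
    return out


def _corrected_rates(
    hit_count: float, n_signal: int, fa_count: float, n_noise: int, method: str
) -> Tuple[float, float]:
    """Corrected (hit, false-alarm) rates from (possibly fractional) counts."""
    if method not in CORRECTIONS:
        raise ValueError(f"unknown correction {method!r}; choose from {CORRECTIONS}")
    if method == "loglinear":
        return (hit_count + 0.5) / (n_signal + 1), (fa_count + 0.5) / (n_noise + 1)
    h = hit_count / n_signal
    f = fa_count / n_noise
    if method == "macmillan_kaplan":
        if h == 0.0:
            h = 0.5 / n_signal
        elif h == 1.0:
            h = (n_signal - 0.5) / n_signal
        if f == 0.0:
            f = 0.5 / n_noise
        elif f == 1.0:
            f = (n_noise - 0.5) / n_noise
    return h, f


def correct_rates(table: BinaryTable, method: str = "macmillan_kaplan") -> RatePair:
    """Hit/false-alarm rates from a 2x2 table with an extreme-rate correction.

    ``macmillan_kaplan`` touches only rates equal to exactly 0 or 1;
    ``loglinear`` transforms every rate as (count + 0.5)/(n + 1); ``none``
    passes the raw rates through.
    """
    n_s, n_d = table.n_same, table.n_diff
    if n_s < 1 or n_d < 1:
        raise ValueError("table must have at least one trial of each truth state")
    h, f = _corrected_rates(table.hits, n_s, table.false_alarms, n_d, method)
    return RatePair(hit_rate=h, fa_rate=f, n_signal=n_s, n_noise=n_d)


def proportion_correct(table: BinaryTable) -> float:
    """Hits plus correct rejections over total trials."""
    if table.total == 0:
        raise ValueError("empty table")
    return (table.hits + table.correct_rejections) / table.total


def diagnosticity_ratio(pair: RatePair) -> float:
    """Hit rate divided by false-alarm rate; NaN when the false-alarm rate is 0."""
    if pair.fa_rate == 0.0:
        return math.nan
    return pair.hit_rate / pair.fa_rate


def d_prime(pair: RatePair) -> float:
    """z(hit rate) - z(false-alarm rate) under the equal-variance Gaussian model.

    Raises on a rate of exactly 0 or 1: apply :func:`correct_rates` first.
    """
    h, f = pair.hit_rate, pair.fa_rate
    if not (0.0 < h < 1.0) or not (0.0 < f < 1.0):
        raise ValueError(
            "d' undefined for a rate of exactly 0 or 1; apply correct_rates "
            "(macmillan_kaplan or loglinear) before computing d'"
        )
    return float(ndtri(h) - ndtri(f))


def a_prime(pair_or_hit, fa_rate: Optional[float] = None) -> float:
    """Corrected A': average of extreme proper-ROC areas through one (F, H) point.

    Uses the Zhang-Mueller piecewise form, chosen by where the operating point
    falls relative to chance (0.5) and the diagonal. Below-chance points
    (F > H) are reflected through the chance diagonal: the value is one minus
    A' of the swapped pair. Always lies in [0, 1].
    """
    if fa_rate is None:
        h, f = pair_or_hit.hit_rate, pair_or_hit.fa_rate
    else:
        h, f = float(pair_or_hit), float(fa_rate)
    for name, v in (("hit rate", h), ("false-alarm rate", f)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if f > h:
        return 1.0 - a_prime(f, h)
    if f == h:
        return 0.5
    base = 0.75 + (h - f) / 4.0
    if f <= 0.5 <= h:
        return base - f * (1.0 - h)
    if h < 0.5:
        return base - f / (4.0 * h)
    return base - (1.0 - h) / (4.0 * (1.0 - f))


def empirical_auc(same_ratings: Sequence[float], diff_ratings: Sequence[float]) -> float:
    """Trapezoidal area under the empirical ROC of a rating scale.

    The ROC is traced by sweeping a decision threshold across every distinct
    rating value (each point is the pair of exceedance rates), anchored at
    (0, 0) and (1, 1), and integrated by the trapezoidal rule. Numerically
    identical to the pairwise statistic (wins + half-ties)/(n_same * n_diff).
    """
    same = np.asarray(same_ratings, dtype=float)
    diff = np.asarray(diff_ratings, dtype=float)
    if same.size == 0 or diff.size == 0:
        raise ValueError("both rating lists must be nonempty")
    thresholds = np.unique(np.concatenate([same, diff]))[::-1]
    same_sorted = np.sort(same)
    diff_sorted = np.sort(diff)
    # exceedance rates P(rating >= t) at each threshold, descending in t
    tpr = 1.0 - np.searchsorted(same_sorted, thresholds, side="left") / same.size
    fpr = 1.0 - np.searchsorted(diff_sorted, thresholds, side="left") / diff.size
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def _binary_metricset(
    h: float,
    m: float,
    fa: float,
    cr: float,
    n_s: float,
    n_d: float,
    same_ratings: np.ndarray,
    diff_ratings: np.ndarray,
    correction: str,
    inc_s: float = 0.0,
    inc_d: float = 0.0,
) -> MetricSet:
    """Assemble a MetricSet from (possibly fractional) outcome counts."""
    out = MetricSet()
    total = n_s + n_d
    out.proportion_correct = _safe_div(h + cr + 0.5 * (inc_s + inc_d), total)
    out.sensitivity = _safe_div(h + 0.5 * inc_s, n_s)
    out.specificity = _safe_div(cr + 0.5 * inc_d, n_d)
    out.ppv = _safe_div(h, h + fa)
    out.npv = _safe_div(cr, cr + m)
    if n_s >= 1 and n_d >= 1:
        ch, cf = _corrected_rates(h + 0.5 * inc_s, int(n_s), fa + 0.5 * inc_d, int(n_d), correction)
        out.diagnosticity = ch / cf if cf > 0 else math.nan
        if 0.0 < ch < 1.0 and 0.0 < cf < 1.0:
            out.d_prime = float(ndtri(ch) - ndtri(cf))
        raw_h = _safe_div(h + 0.5 * inc_s, n_s)
        raw_f = _safe_div(fa + 0.5 * inc_d, n_d)
        out.a_prime = a_prime(raw_h, raw_f)
    if same_ratings.size > 0 and diff_ratings.size > 0:
        out.auc = empirical_auc(same_ratings, diff_ratings)
    n_inc = inc_s + inc_d
    if n_inc > 0:
        out.ippv = inc_s / n_inc
        out.inpv = inc_d / n_inc
    return out


def _metrics_from_arrays(
    is_same: np.ndarray,
    rating: np.ndarray,
    window: Optional[Tuple[float, float]],
    policy: str,
    correction: str,
    midpoint: float,
) -> MetricSet:
    n_s = int(np.sum(is_same))
    n_d = int(is_same.size - n_s)

    if window is None:
        says_same = rating >= midpoint
        h = float(np.sum(is_same & says_same))
        cr = float(np.sum(~is_same & ~says_same))
        return _binary_metricset(
            h=h,
            m=n_s - h,
            fa=float(np.sum(~is_same & says_same)),
            cr=cr,
            n_s=n_s,
            n_d=n_d,
            same_ratings=rating[is_same],
            diff_ratings=rating[~is_same],
            correction=correction,
        )

    if policy not in POLICIES:
        raise ValueError(f"unknown inconclusive policy {policy!r}; choose from {POLICIES}")
    wlo, whi = window
    if wlo > whi:
        raise ValueError(f"inverted inconclusive window [{wlo}, {whi}]")
    inc = (rating >= wlo) & (rating <= whi)
    inc_s = float(np.sum(inc & is_same))
    inc_d = float(np.sum(inc & ~is_same))

    if policy == "exclude":
        keep = ~inc
        is_same_k = is_same[keep]
        rating_k = rating[keep]
        n_sk = int(np.sum(is_same_k))
        n_dk = int(is_same_k.size - n_sk)
        says_same = rating_k >= midpoint
        h = float(np.sum(is_same_k & says_same))
        fa = float(np.sum(~is_same_k & says_same))
        cr = float(np.sum(~is_same_k & ~says_same))
        out = _binary_metricset(
            h=h,
            m=n_sk - h,
            fa=fa,
            cr=cr,
            n_s=n_sk,
            n_d=n_dk,
            same_ratings=rating_k[is_same_k],
            diff_ratings=rating_k[~is_same_k],
            correction=correction,
        )
        n_inc = inc_s + inc_d
        if n_inc > 0:
            out.ippv = inc_s / n_inc
            out.inpv = inc_d / n_inc
        return out

    # midpoint policy: inconclusive trials earn half credit for rate-based
    # metrics, substitute the scale midpoint as their rating for AUC
    says_same = (rating >= midpoint) & ~inc
    h = float(np.sum(is_same & says_same))
    fa = float(np.sum(~is_same & says_same))
    cr = float(np.sum(~is_same & ~says_same & ~inc))
    m = float(np.sum(is_same & ~says_same & ~inc))
    rating_sub = np.where(inc, midpoint, rating)
    return _binary_metricset(
        h=h,
        m=m,
        fa=fa,
        cr=cr,
        n_s=n_s,
        n_d=n_d,
        same_ratings=rating_sub[is_same],
        diff_ratings=rating_sub[~is_same],
        correction=correction,
        inc_s=inc_s,
        inc_d=inc_d,
    )


def participant_metrics(
    records: RecordsLike,
    window: Optional[Tuple[float, float]] = None,
    policy: str = "exclude",
    correction: str = "macmillan_kaplan",
    midpoint: Optional[float] = None,
    scale: Tuple[float, float] = DEFAULT_SCALE,
) -> MetricSet:
    """All performance models on one unit's trials (a participant or a pooled group).

    ``window`` activates ternary coding; ``policy`` chooses how inconclusive
    trials are handled: ``"exclude"`` drops them before computing metrics,
    ``"midpoint"`` scores them as half correct (and substitutes the scale
    midpoint as their rating for AUC). Fields that are undefined for the
    configuration (e.g. a truth class entirely excluded) are NaN markers.
    """
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("no records")
    if midpoint is None:
        midpoint = scale_midpoint(scale)
    is_same = df["truth"].to_numpy() == SAME
    rating = df["rating"].to_numpy(dtype=float)
    return _metrics_from_arrays(is_same, rating, window, policy, correction, midpoint)


def metrics_table(
    dataset: pd.DataFrame,
    window_by_group: Optional[Dict[str, Optional[Tuple[float, float]]]] = None,
    policy: str = "exclude",
    correction: str = "macmillan_kaplan",
    midpoint: Optional[float] = None,
    scale: Tuple[float, float] = DEFAULT_SCALE,
    unit: str = "participant",
) -> pd.DataFrame:
    """Tidy metric table: one row per (replicate, group, participant).

    ``window_by_group`` maps a group label to its inconclusive window (or
    None); groups not in the map are coded binary. With ``unit="group"`` the
    counts are pooled across participants first and one row per (replicate,
    group) is returned (classification-table style aggregation).
    """
    if midpoint is None:
        midpoint = scale_midpoint(scale)
    window_by_group = window_by_group or {}
    df = dataset
    if "replicate" not in df.columns:
        df = df.assign(replicate=0)
    if unit == "participant":
        keys = ["replicate", "group", "participant_id"]
    elif unit == "group":
        keys = ["replicate", "group"]
    else:
        raise ValueError(f"unknown unit {unit!r}")

    is_same = (df["truth"].to_numpy() == SAME)
    rating = df["rating"].to_numpy(dtype=float)
    codes, key_frame = pd.factorize(
        pd.MultiIndex.from_frame(df[keys]), sort=True
    )
    order = np.argsort(codes, kind="stable")
    boundaries = np.searchsorted(codes[order], np.arange(len(key_frame) + 1))

    rows = []
    for i, key in enumerate(key_frame):
        idx = order[boundaries[i] : boundaries[i + 1]]
        group_label = key[keys.index("group")]
        window = window_by_group.get(group_label)
        ms = _metrics_from_arrays(
            is_same[idx], rating[idx], window, policy, correction, midpoint
        )
        rows.append(dict(zip(keys, key)) | ms.as_dict())
    return pd.DataFrame(rows, columns=keys + list(METRIC_NAMES))
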