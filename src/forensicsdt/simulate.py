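"""Beta-distribution resampling engine for rating-scale experiments.

Confidence ratings for same-source and different-source trials are drawn from
beta distributions rescaled to the rating scale, parameterized by a mean and
standard deviation per group and trial type (method of moments). A whole
expert/novice style experiment — n participants per group, a fixed number of
same- and different-source trials each, yoked trial sequences across matched
participants — is simulated many times over, giving replicate datasets from
which the sampling variability of every performance model can be studied.

Ratings are kept continuous: the inconclusive windows (e.g. 5.5-7.5) and the
midpoint substitution (6.5) used downstream only make sense on a continuous
scale. An integer-rounding mode is available for fidelity experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .classification import DEFAULT_SCALE, DIFFERENT, SAME


class FeasibilityError(ValueError):
    """A (mean, sd) pair admits no beta distribution on the scale."""


@dataclass(frozen=True)
class GroupParams:
    """Rating-distribution moments for one group.

    ``mean_same``/``sd_same`` describe the group's confidence ratings on
    same-source trials, ``mean_diff``/``sd_diff`` on different-source trials,
    all in scale units on ``scale`` (default 1-12).
    """

    mean_same: float
    sd_same: float
    mean_diff: float
    sd_diff: float
    scale: Tuple[float, float] = DEFAULT_SCALE

    def __post_init__(self) -> None:
        # raises FeasibilityError if either pair is invalid
        beta_from_moments(self.mean_same, self.sd_same, self.scale)
        beta_from_moments(self.mean_diff, self.sd_diff, self.scale)


@dataclass(frozen=True)
class ExperimentDesign:
    """Shape of one simulated experiment and its replication."""

    n_participants_per_group: int = 44
    n_same: int = 12
    n_diff: int = 12
    n_replicates: int = 100
    seed: Optional[int] = None
    yoked: bool = True

    def __post_init__(self) -> None:
        for name in ("n_participants_per_group", "n_same", "n_diff", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_same + self.n_diff


def beta_from_moments(
    mean: float, sd: float, scale: Tuple[float, float] = DEFAULT_SCALE
) -> Tuple[float, float]:
    """Method-of-moments beta shape parameters for a scaled mean and SD.

    The moments are mapped to the unit interval, m = (mean - lo)/(hi - lo) and
    v = (sd/(hi - lo))^2, and the common factor k = m(1 - m)/v - 1 gives
    alpha = m*k, beta = (1 - m)*k. Requires lo < mean < hi and v < m(1 - m).
    """
    lo, hi = scale
    if not (lo < mean < hi):
        raise FeasibilityError(
            f"mean {mean} must lie strictly inside the scale ({lo}, {hi})"
        )
    if sd <= 0:
        raise FeasibilityError(f"sd must be positive, got {sd}")
    span = hi - lo
    m = (mean - lo) / span
    v = (sd / span) ** 2
    bound = m * (1.0 - m)
    if v >= bound:
        raise FeasibilityError(
            f"variance {v:.6g} (unit scale) is not below the feasibility bound "
            f"m(1-m) = {bound:.6g} for mean {mean}; reduce sd below "
            f"{span * math.sqrt(bound):.4g} or move the mean toward the scale center"
        )
    k = bound / v - 1.0
    return m * k, (1.0 - m) * k


def feasible_mean_interval(
    sd: float, scale: Tuple[float, float] = DEFAULT_SCALE
) -> Tuple[float, float]:
    """Open interval of means admitting a beta distribution at this SD."""
    lo, hi = scale
    span = hi - lo
    v = (sd / span) ** 2
    if v >= 0.25:
        raise FeasibilityError(f"sd {sd} infeasible for any mean on scale {scale}")
    r = 0.5 * (1.0 - math.sqrt(1.0 - 4.0 * v))
    return lo + span * r, hi - span * r


def default_group_params() -> Dict[str, GroupParams]:
    """Illustrative expert/novice parameters.

    The raw study's fitted moments are not published; these defaults were
    calibrated once so that the probability of a rating at or above the scale
    midpoint matches the expert and novice hit and false-alarm rates of the
    published classification tables (experts decisive and conservative,
    novices diffuse and liberal). See docs/methods.md.
    """
    return {
        "expert": GroupParams(mean_same=8.4, sd_same=2.5, mean_diff=3.9, sd_diff=2.0),
        "novice": GroupParams(mean_same=8.0, sd_same=2.8, mean_diff=6.6, sd_diff=2.8),
    }


def simulate_experiment(
    params_by_group: Dict[str, GroupParams],
    design: ExperimentDesign,
    seed: Optional[int] = None,
    round_to_int: bool = False,
) -> pd.DataFrame:
    """Draw a replicated trial-level rating dataset.

    Returns a tidy DataFrame with columns ``replicate, participant_id, group,
    trial_id, truth, rating``. Participants with the same index across groups
    are matched; with ``design.yoked`` they share the same randomized trial
    sequence (trial identifiers and truth ordering). One root seed spawns an
    independent child stream per replicate, so the full dataset is
    reproducible from (params, design, seed).
    """
    if not params_by_group:
        raise ValueError("params_by_group must name at least one group")
    if seed is None:
        seed = design.seed
    root = np.random.SeedSequence(seed)
    children = root.spawn(design.n_replicates)

    groups = list(params_by_group)
    shapes = {
        g: (
            beta_from_moments(p.mean_same, p.sd_same, p.scale),
            beta_from_moments(p.mean_diff, p.sd_diff, p.scale),
            p.scale,
        )
        for g, p in params_by_group.items()
    }
    n_p = design.n_participants_per_group
    n_s, n_d, n_t = design.n_same, design.n_diff, design.n_trials
    base_truth = np.array([True] * n_s + [False] * n_d)

    frames = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        if design.yoked:
            perms = np.array([rng.permutation(n_t) for _ in range(n_p)])
        for g in groups:
            (a_s, b_s), (a_d, b_d), (lo, hi) = shapes[g]
            if not design.yoked:
                perms = np.array([rng.permutation(n_t) for _ in range(n_p)])
            truth_seq = base_truth[perms]  # (n_p, n_t), presentation order
            same_draws = lo + (hi - lo) * rng.beta(a_s, b_s, size=(n_p, n_s))
            diff_draws = lo + (hi - lo) * rng.beta(a_d, b_d, size=(n_p, n_d))
            ratings = np.empty((n_p, n_t), dtype=float)
            ratings[truth_seq] = same_draws.ravel()
            ratings[~truth_seq] = diff_draws.ravel()
            if round_to_int:
                ratings = np.clip(np.rint(ratings), lo, hi)
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "participant_id": np.repeat(
                            [f"{g}-{i + 1:02d}" for i in range(n_p)], n_t
                        ),
                        "group": g,
                        "trial_id": np.tile(
                            [f"t{j + 1:03d}" for j in range(n_t)], n_p
                        ),
                        "truth": np.where(truth_seq.ravel(), SAME, DIFFERENT),
                        "rating": ratings.ravel(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def inject_easy_trials(
    dataset: pd.DataFrame,
    k: int,
    group: str,
    easy_rating: float = 1.0,
) -> pd.DataFrame:
    """Force k different-source trials per participant of one group to an easy rating.

    Emulates trials so easy that every participant gives the extreme
    "sure different" response: for each participant of ``group`` (in every
    replicate) the first ``k`` different-source trials in trial order get
    their rating replaced by ``easy_rating`` deterministically. All other
    records are untouched; a new DataFrame is returned.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    out = dataset.copy()
    if k == 0:
        return out
    mask = (out["group"] == group) & (out["truth"] == DIFFERENT)
    keys = [c for c in ("replicate", "participant_id") if c in out.columns]
    sub = out[mask].sort_values(keys + ["trial_id"], kind="stable")
    counts = sub.groupby(keys, sort=False).size()
    if len(counts) == 0:
        raise ValueError(f"no different-source trials found for group {group!r}")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the {counts.min()} different-source trials available "
            f"per participant in group {group!r}"
        )
    ranks = sub.groupby(keys, sort=False).cumcount()
    out.loc[sub.index[ranks.to_numpy() < k], "rating"] = float(easy_rating)
    return out
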