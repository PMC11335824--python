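"""The six scenario sweeps: systematic manipulations of a simulated experiment.

Each sweep builds a list of :class:`ScenarioStep` objects — transformed group
parameters, design overrides, inconclusive windows, or easy-trial injections —
around a baseline configuration, then delegates to the resampling engine and
the metric/evaluation pipeline:

* response bias: shift one group's mean ratings up (liberal) or down
  (conservative) in fixed increments, spreads unchanged;
* prevalence: vary the number of same-source trials at fixed total;
* inconclusive responses: widen a rating window coded as inconclusive for the
  target group, handled by an exclude or a midpoint (half-credit) policy;
* task difficulty: move both groups' same-source means a fixed fraction
  closer to the scale top and different-source means closer to the bottom,
  compounding per step;
* trial sampling: inject a growing number of deterministically easy
  different-source trials into one of two otherwise identical groups;
* number of trials: fix the easy-trial count and double the total trials.

Running a sweep with a root seed uses the *same* seed for every step, so the
baseline step is bit-identical to the unmodified experiment and steps share
common random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .classification import scale_midpoint
from .evaluation import summarize_across_replicates, summarize_replicates
from .metrics import metrics_table
from .simulate import (
    ExperimentDesign,
    FeasibilityError,
    GroupParams,
    beta_from_moments,
    default_group_params,
    feasible_mean_interval,
    inject_easy_trials,
    simulate_experiment,
)

#: Metrics reported by the sweep pipelines (the four headline models plus the
#: two table rates used by the inconclusive analyses).
SWEEP_METRICS = (
    "proportion_correct",
    "d_prime",
    "a_prime",
    "auc",
    "sensitivity",
    "specificity",
)


@dataclass
class ScenarioStep:
    """One point of a sweep: a fully specified experiment configuration."""

    scenario: str
    step_index: float
    params_by_group: Dict[str, GroupParams]
    design: ExperimentDesign
    window_by_group: Optional[Dict[str, Tuple[float, float]]] = None
    policy: str = "exclude"
    k_easy: int = 0
    easy_group: Optional[str] = None
    infeasible: bool = False
    note: str = ""


def _shift_params(p: GroupParams, delta: float, clamp: bool) -> Tuple[GroupParams, bool, str]:
    """Shift both means of one group by delta; flag or clamp infeasible shifts."""
    notes = []
    means = {}
    infeasible = False
    for which, mean, sd in (
        ("mean_same", p.mean_same + delta, p.sd_same),
        ("mean_diff", p.mean_diff + delta, p.sd_diff),
    ):
        try:
            beta_from_moments(mean, sd, p.scale)
        except FeasibilityError:
            if clamp:
                lo_f, hi_f = feasible_mean_interval(sd, p.scale)
                eps = 1e-9 * (p.scale[1] - p.scale[0])
                clamped = min(max(mean, lo_f + eps), hi_f - eps)
                notes.append(f"{which} clamped from {mean:.3g} to {clamped:.6g}")
                mean = clamped
            else:
                infeasible = True
                notes.append(f"{which}={mean:.3g} infeasible at sd={sd}")
        means[which] = mean
    if infeasible:
        return p, True, "; ".join(notes)
    return (
        replace(p, mean_same=means["mean_same"], mean_diff=means["mean_diff"]),
        False,
        "; ".join(notes),
    )


def sweep_response_bias(
    params_by_group: Optional[Dict[str, GroupParams]] = None,
    target: str = "expert",
    delta: float = 0.5,
    n_steps_each_side: int = 4,
    design: Optional[ExperimentDesign] = None,
    clamp: bool = False,
) -> List[ScenarioStep]:
    """Shift the target group's mean ratings by s*delta, s = -n..+n.

    Negative steps make the group more conservative (both means lower),
    positive steps more liberal; spreads and the comparison group are
    untouched. A shift that pushes a mean outside the feasible open interval
    marks the step infeasible (or clamps it just inside, with ``clamp=True``).
    """
    params_by_group = params_by_group or default_group_params()
    design = design or ExperimentDesign()
    if target not in params_by_group:
        raise ValueError(f"target group {target!r} not in params")
    steps = []
    for s in range(-n_steps_each_side, n_steps_each_side + 1):
        shifted, infeasible, note = _shift_params(
            params_by_group[target], s * delta, clamp
        )
        params = dict(params_by_group)
        params[target] = shifted
        steps.append(
            ScenarioStep(
                scenario="response_bias",
                step_index=s,
                params_by_group=params,
                design=design,
                infeasible=infeasible,
                note=note,
            )
        )
    return steps


def sweep_prevalence(
    params_by_group: Optional[Dict[str, GroupParams]] = None,
    design: Optional[ExperimentDesign] = None,
    n_same_values: Sequence[int] = (3, 6, 9, 12, 15, 18, 21),
    total_trials: int = 24,
) -> List[ScenarioStep]:
    """Vary the share of same-source trials at a fixed total trial count."""
    params_by_group = params_by_group or default_group_params()
    design = design or ExperimentDesign()
    steps = []
    for n_same in n_same_values:
        if not (1 <= n_same <= total_trials - 1):
            raise ValueError(
                f"n_same={n_same} must lie in [1, {total_trials - 1}]"
            )
        steps.append(
            ScenarioStep(
                scenario="prevalence",
                step_index=n_same,
                params_by_group=params_by_group,
                design=replace(design, n_same=n_same, n_diff=total_trials - n_same),
            )
        )
    return steps


def sweep_inconclusive(
    params_by_group: Optional[Dict[str, GroupParams]] = None,
    design: Optional[ExperimentDesign] = None,
    half_widths: Sequence[float] = (0, 1, 2, 3, 4),
    policy: str = "exclude",
    target: str = "expert",
) -> List[ScenarioStep]:
    """Widen the inconclusive rating window around the scale midpoint.

    Step s codes the target group's ratings in [mid - s, mid + s] as
    inconclusive (s = 1 gives 5.5-7.5 on the 1-12 scale, s = 2 gives 4.5-8.5,
    ...). Step 0 uses no window at all, reproducing the plain binary
    experiment. ``policy`` is ``"exclude"`` (drop inconclusive trials) or
    ``"midpoint"`` (half credit / midpoint rating substitution).
    """
    params_by_group = params_by_group or default_group_params()
    design = design or ExperimentDesign()
    if list(half_widths) != sorted(half_widths):
        raise ValueError("half_widths must be non-decreasing (nested windows)")
    scale = params_by_group[target].scale
    mid = scale_midpoint(scale)
    steps = []
    for s in half_widths:
        if s < 0:
            raise ValueError("window half-width must be >= 0")
        window = None if s == 0 else (mid - s, mid + s)
        steps.append(
            ScenarioStep(
                scenario="inconclusive",
                step_index=s,
                params_by_group=params_by_group,
                design=design,
                window_by_group={target: window} if window else None,
                policy=policy,
            )
        )
    return steps


def sweep_difficulty(
    params_by_group: Optional[Dict[str, GroupParams]] = None,
    design: Optional[ExperimentDesign] = None,
    n_steps: int = 4,
    fraction: float = 0.25,
) -> List[ScenarioStep]:
    """Make the task progressively easier for every group.

    Per step (compounding), each group's same-source mean moves ``fraction``
    of the remaining distance toward the scale top and the different-source
    mean the same fraction toward the scale bottom; spreads are unchanged.
    The means approach the bounds asymptotically and never reach them.
    """
    params_by_group = params_by_group or default_group_params()
    design = design or ExperimentDesign()
    steps = [
        ScenarioStep(
            scenario="difficulty",
            step_index=0,
            params_by_group=params_by_group,
            design=design,
        )
    ]
    current = dict(params_by_group)
    for s in range(1, n_steps + 1):
        nxt = {}
        for g, p in current.items():
            lo, hi = p.scale
            nxt[g] = replace(
                p,
                mean_same=p.mean_same + fraction * (hi - p.mean_same),
                mean_diff=p.mean_diff - fraction * (p.mean_diff - lo),
            )
        current = nxt
        steps.append(
            ScenarioStep(
                scenario="difficulty",
                step_index=s,
                params_by_group=current,
                design=design,
            )
        )
    return steps


def sweep_easy_trials(
    base_params: Optional[GroupParams] = None,
    design: Optional[ExperimentDesign] = None,
    k_values: Sequence[int] = (0, 1, 2, 3, 4),
    groups: Tuple[str, str] = ("pre", "post"),
    easy_rating: float = 1.0,
) -> List[ScenarioStep]:
    """Null experiment (both groups share one distribution) plus k easy trials.

    Both groups draw from identical parameters — a training study whose
    intervention has no effect — and step k overwrites k different-source
    ratings per participant of the second (post-test) group with the extreme
    easy rating.
    """
    base_params = base_params or default_group_params()["novice"]
    design = design or ExperimentDesign()
    pre, post = groups
    params = {pre: base_params, post: base_params}
    steps = []
    for k in k_values:
        if k > design.n_diff:
            raise ValueError(f"k={k} exceeds n_diff={design.n_diff}")
        steps.append(
            ScenarioStep(
                scenario="easy_trials",
                step_index=k,
                params_by_group=params,
                design=design,
                k_easy=int(k),
                easy_group=post,
            )
        )
    return steps


def sweep_n_trials(
    base_params: Optional[GroupParams] = None,
    design: Optional[ExperimentDesign] = None,
    totals: Sequence[int] = (12, 24, 48, 96, 192),
    k_easy: int = 4,
    groups: Tuple[str, str] = ("pre", "post"),
    easy_rating: float = 1.0,
) -> List[ScenarioStep]:
    """Double the total trial count at a fixed number of easy post-test trials."""
    base_params = base_params or default_group_params()["novice"]
    design = design or ExperimentDesign()
    pre, post = groups
    params = {pre: base_params, post: base_params}
    steps = []
    for total in totals:
        if total % 2 != 0:
            raise ValueError(f"total trials must be even, got {total}")
        if k_easy > total // 2:
            raise ValueError(f"k_easy={k_easy} exceeds n_diff={total // 2}")
        steps.append(
            ScenarioStep(
                scenario="n_trials",
                step_index=total,
                params_by_group=params,
                design=replace(design, n_same=total // 2, n_diff=total // 2),
                k_easy=k_easy,
                easy_group=post,
            )
        )
    return steps


def run_step(
    step: ScenarioStep,
    seed: Optional[int] = None,
    correction: str = "macmillan_kaplan",
    metrics: Sequence[str] = SWEEP_METRICS,
    easy_rating: float = 1.0,
) -> Optional[pd.DataFrame]:
    """Simulate one step and return its per-participant metric table.

    Returns None for a step marked infeasible.
    """
    if step.infeasible:
        return None
    data = simulate_experiment(step.params_by_group, step.design, seed=seed)
    if step.k_easy > 0:
        data = inject_easy_trials(
            data, step.k_easy, group=step.easy_group, easy_rating=easy_rating
        )
    table = metrics_table(
        data,
        window_by_group=step.window_by_group,
        policy=step.policy,
        correction=correction,
    )
    keep = ["replicate", "group", "participant_id"] + [
        m for m in metrics if m in table.columns
    ]
    return table[keep]


def run_sweep(
    steps: Sequence[ScenarioStep],
    seed: Optional[int] = None,
    groups: Optional[Sequence[str]] = None,
    correction: str = "macmillan_kaplan",
    metrics: Sequence[str] = SWEEP_METRICS,
    welch: bool = True,
) -> pd.DataFrame:
    """Run every step of a sweep with a common seed; tidy sweep-level summary.

    One row per (step, metric, group) with the across-replicate mean, spread
    quantiles, median p, and fraction of significant replicates. Infeasible
    steps appear with ``infeasible=True`` and NaN statistics.
    """
    rows = []
    for step in steps:
        base = {
            "scenario": step.scenario,
            "step": step.step_index,
            "infeasible": step.infeasible,
        }
        table = run_step(step, seed=seed, correction=correction, metrics=metrics)
        if table is None:
            rows.append(pd.DataFrame([base | {"note": step.note}]))
            continue
        reps = summarize_replicates(table, groups=groups, metrics=metrics, welch=welch)
        summary = summarize_across_replicates(reps)
        for col, val in reversed(list(base.items())):
            summary.insert(0, col, val)
        rows.append(summary)
    return pd.concat(rows, ignore_index=True)
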