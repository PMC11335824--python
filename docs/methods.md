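# Methods

## Setting and data model

The unit of observation is one participant × trial rating: a bounded
confidence rating (default scale [1, 12]) about whether two impressions share
a source, together with the ground truth (`same` / `different`). Binary
coding calls a rating a "same-source" decision when it is at or above the
scale midpoint (6.5 by default) and "different-source" otherwise; the
boundary value codes as "same" by a fixed tie rule (an integer scale never
produces it, but simulated continuous ratings can). Ternary coding adds a
closed inconclusive window [lo, hi]: a rating inside the window (endpoints
included) is an inconclusive decision, anything outside follows the binary
rule. Tallying decisions against truth gives the 2×2 table (hits, misses,
false alarms, correct rejections) or the 2×3 table with inconclusive counts
per truth state; the counts always partition the input records.

## Performance models

* **Proportion correct** (H + CR)/N. Intuitive but confounded with response
  bias and prevalence.
* **Diagnosticity ratio** hit rate / false-alarm rate. Reported for
  completeness; it explodes as the false-alarm rate approaches zero.
* **d′** = z(hit rate) − z(false-alarm rate), equal-variance Gaussian model.
  The standard-normal quantile is `scipy.special.ndtri`. Rates of exactly
  0 or 1 are rejected; callers apply a correction first.
* **A′**, Zhang–Mueller corrected form: with F ≤ H,
  A = 3/4 + (H−F)/4 − penalty, where the penalty is F(1−H) when
  F ≤ 0.5 ≤ H, F/(4H) when both are below 0.5, and (1−H)/(4(1−F)) when both
  are above. Below-chance points (F > H) are reflected through the chance
  diagonal: A(H, F) = 1 − A(F, H). Validated against the (1,0) → 1 and
  (h,h) → 0.5 anchors and the hand-evaluated mid-branch value
  A(0.75, 0.25) = 0.8125; always in [0, 1].
* **Empirical AUC**: the ROC is traced by sweeping a threshold across all
  distinct rating values (points are the exceedance-rate pairs), anchored at
  (0,0) and (1,1), and integrated with the trapezoidal rule. Ties contribute
  half credit through the trapezoids, so the value equals the pairwise
  statistic (wins + ties/2)/(n_same × n_diff); the test suite checks this
  identity to 1e-12 against a brute-force oracle and against
  scikit-learn's independent implementation.

**Extreme-rate corrections.** `macmillan_kaplan` (default) replaces only
rates equal to exactly 0 or 1 by 0.5/n and (n − 0.5)/n; `loglinear`
transforms every rate as (count + 0.5)/(n + 1); `none` passes raw rates
through. With either correction active, d′ and the diagnosticity ratio are
finite for every possible table.

**Predictive values.** PPV/NPV condition on the examiner's conclusive call;
sensitivity/specificity condition on ground truth. In ternary tables,
inconclusive decisions enter the sensitivity/specificity denominators (they
are decisions on trials of that truth state) but never the numerators, while
IPPV/INPV describe the truth composition of the inconclusive calls
themselves.

**Aggregation modes.** Metrics are computed per participant and then averaged
per group per replicate (the raincloud-style pipeline), or on counts pooled
across participants (classification-table style). Both are exposed
(`metrics_table(..., unit="participant" | "group")`) because they answer
different questions and diverge for small per-participant trial counts (see
Limitations).

## Inconclusive-response policies

When a window is active, two scoring policies are implemented:

* **exclude** — inconclusive trials are dropped before any metric is
  computed (per participant, after coding). If a participant's entire truth
  class is excluded, the rate-based metrics carry NaN markers, never
  imputed numbers.
* **midpoint** — inconclusive trials stay in: they earn 0.5 accuracy credit
  in proportion correct, and their rating is replaced by the scale midpoint
  (6.5) for the AUC computation. For the rate-based indices
  (sensitivity/specificity, d′, A′, diagnosticity) the same "half correct,
  half incorrect" idea is applied as half-credit counts:
  effective hits = H + 0.5·inc_same, effective false alarms =
  FA + 0.5·inc_diff, over the full per-class denominators. The proportion-
  correct and AUC rules are the published convention; extending half credit
  to the other indices is this package's documented choice so that every
  metric responds to the policy coherently.

## Synthetic-data generator

The generator emulates rating-scale experiments as draws from beta
distributions rescaled to the rating scale. Each group contributes two
(mean, SD) pairs — same-source and different-source ratings — converted to
beta shapes by the method of moments on the unit interval
(k = m(1−m)/v − 1; α = mk, β = (1−m)k), which requires the rescaled variance
to satisfy v < m(1−m); infeasible pairs raise an error naming the bound
(sweeps can instead mark a step infeasible, or clamp with an explicit flag).

A design specifies 44 participants per group, 12 same- + 12 different-source
trials, and 100 replicates by default. Matched participants across groups are
yoked: each pair shares one randomized trial sequence (trial identifiers and
truth ordering), as in matched expert/novice designs. One root seed spawns an
independent child stream per replicate (`numpy` `SeedSequence`), so datasets
are bit-for-bit reproducible and replicates are independently re-runnable.
Ratings are continuous — the inconclusive windows (e.g. 5.5–7.5) and the 6.5
midpoint substitution presuppose that — with an optional integer-rounding
mode for fidelity experiments.

**Default parameters.** The fitted moments of the motivating study are not
published. The shipped defaults are therefore *illustrative*: beta means were
calibrated once so that P(rating ≥ 6.5) matches the published group hit and
false-alarm rates (expert sensitivity .7689 / false-alarm .1183; novice
.7029 / .5213), with SDs chosen as realistic for decisive experts
(sd_same 2.5, sd_diff 2.0) and diffuse novices (2.8 both):
expert (mean_same 8.4, mean_diff 3.9), novice (8.0, 6.6) on [1, 12]. These
reproduce the qualitative structure — conservative high-separation experts,
liberal low-separation novices — not any particular figure's group means.
User-supplied parameters load from YAML.

The generator reproduces the sampling structure of a rating experiment, not
all features of real data: no participant heterogeneity within group (all
experts share one distribution), no trial-difficulty structure beyond the
same/different split (stimulus effects enter only through the deterministic
easy-trial injection), no sequential or feedback effects, unimodal
distributions only. Passing simulation tests therefore validates the
measurement pipeline's behavior under known conditions; it does not certify
any claim about real examiner populations.

## Scenario sweeps

All sweeps run every step with the same root seed, so step 0 (or the middle
step) is bit-identical to the unmodified experiment and steps share common
random numbers.

* **Response bias** — shift the target group's two means by s·δ (δ = 0.5,
  s = −4…+4 by default); SDs and the comparison group untouched.
* **Prevalence** — n_same ∈ {3, 6, …, 21} of 24 total trials.
* **Inconclusive** — window [6.5 − s, 6.5 + s], s = 0…4 (s = 0 means *no*
  window, so the baseline is exactly the binary experiment rather than a
  zero-width window that could catch a continuous rating of exactly 6.5),
  with the exclude or midpoint policy applied to the target group.
* **Difficulty** — compounding per step, each group's mean_same moves 25% of
  the remaining distance toward the scale top and mean_diff 25% toward the
  bottom (4 steps by default); the means approach the bounds asymptotically.
* **Easy trials** — both groups ("pre"/"post") share one distribution (a
  null training effect); step k deterministically overwrites k
  different-source ratings per post-test participant with 1.0 ("sure
  different"), modelling trials everyone gets right.
* **Trial count** — total trials double from 12 to 192 (split evenly) at a
  fixed k = 4 easy post-test trials.

Step counts are cosmetic and configurable; the defaults give 9 bias steps and
5 steps elsewhere.

## Evaluation

Per replicate: group means of each metric over participants (NaN-marked
participants dropped and counted) and a two-sided two-sample t test on the
participant values — Welch's unequal-variance test by default, since the
scenario manipulations routinely induce variance heterogeneity; Student's
pooled test by flag. Across replicates: mean of group means, q10–q90 spread
quantiles (raincloud-ready), the median p, the median |t|, and the fraction
of replicates with p < .05. "Median t-test statistic" is operationalized as
the median of per-replicate p values (with constant df the orderings agree);
the median |t| is reported alongside.

## Numerical and design choices

* Boundary ties: rating = midpoint codes "same"; window endpoints are
  inconclusive (closed interval).
* Undefined values are NaN markers throughout and empty cells in written
  tables, never zeros and never imputed.
* Infeasible bias shifts mark the step infeasible and report it; silent
  clamping is opt-in.
* Per-participant metrics use raw rates for sensitivity/specificity/A′/AUC
  and corrected rates (Macmillan–Kaplan default) for d′ and the
  diagnosticity ratio.
* The easy-trial injection overwrites the first k different-source trials in
  trial order per participant — deterministic, reproducible, and exactly k
  per participant.

## Limitations

* Per-participant d′ with 12 trials per class is capped by the extreme-rate
  correction at z(11.5/12) − z(0.5/12) ≈ 3.46, and with very few trials in a
  class (e.g. 3 same-source trials at extreme prevalence) the corrected
  rates live on a coarse grid whose caps bias the per-participant group mean
  substantially. The prevalence-robustness property of d′/A′/AUC is
  therefore assessed on pooled group counts, where it holds cleanly; the
  per-participant mode genuinely shows the small-sample estimator artifact,
  which is a finding about the estimator, not the underlying
  discriminability.
* Under the exclude policy with very wide windows, few conclusive trials
  remain and per-participant d′ becomes non-monotone for the same reason;
  the bounded metrics (sensitivity, specificity, AUC) inflate monotonically.
* A′ is implemented from its published corrected formula and checked against
  closed-form anchors and symmetry properties, not against a numerical
  proper-ROC area construction.
* Response-bias indices (c, β), binormal ROC fitting, and likelihood-ratio
  frameworks are out of scope.

## Problem sizes

Default test and acceptance runs use the full study-scale configuration
(44 + 44 participants, 24 trials, 100 replicates) for the pipeline-level
checks; unit tests and examples use smaller designs (4–20 replicates) chosen
for readability.
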