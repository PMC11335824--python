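# forensicsdt

Signal-detection performance measurement for forensic pattern-matching
decisions.

Forensic examiners — fingerprint, firearms, face, handwriting — make binary
source decisions: did this trace and this reference come from the same source
or not? Researchers who study such decisions score them against ground truth
and summarize performance with models from signal detection theory, and those
modeling choices (which index, which correction, how inconclusive responses
are handled, how trials are sampled) can change the conclusions drawn about
expert performance. `forensicsdt` is a toolkit for cognitive scientists and
applied researchers who need those measurements to be explicit, reproducible,
and stress-testable by simulation.

## What it computes

From trial-level confidence ratings (1 = "sure different" … 12 = "sure same"
by default), coded binary at the scale midpoint or ternary with an
inconclusive window:

- **Classification tables** — hits *H*, misses *M*, false alarms *FA*,
  correct rejections *CR*, plus inconclusive counts per ground-truth state.
- **Table rates** — sensitivity *H/(H+M)*, specificity *CR/(FA+CR)*,
  PPV *H/(H+FA)*, NPV *CR/(CR+M)*, proportion correct *(H+CR)/N*, and for
  ternary tables the inconclusive predictive values
  IPPV = inc_same/(inc_same+inc_diff), INPV = 1 − IPPV.
- **Diagnosticity ratio** — hit rate / false-alarm rate.
- **d′** — *z(H rate) − z(FA rate)* under the equal-variance Gaussian model,
  with the Macmillan–Kaplan (0 → 0.5/n, 1 → (n−0.5)/n) or log-linear
  ((count+0.5)/(n+1)) extreme-rate corrections.
- **A′** — the corrected area-based single-point index (Zhang–Mueller
  piecewise form, below-chance points reflected through the diagonal).
- **Empirical AUC** — trapezoidal area under the ROC traced by sweeping a
  threshold across the rating scale; identical to the pairwise
  wins-plus-half-ties (Mann–Whitney) statistic.

A beta-distribution resampling engine simulates whole replicated experiments
(yoked expert/novice pairs, n participants × n trials × n replicates) from
per-group rating means and SDs, and six scenario sweeps probe how the models
respond to response bias, prevalence, inconclusive-response handling
(exclude vs. half-credit midpoint policies), task difficulty, easy-trial
contamination, and total trial count. An evaluation layer summarizes each
sweep as per-replicate group means, Welch *t* comparisons, median *p*, and
the fraction of replicates reaching significance.

## Worked example

```python
import forensicsdt as f
from forensicsdt.fixtures import expert_study_records

table = f.tabulate(expert_study_records())       # BinaryTable(396, 119, 64, 477)
ms = f.rates_and_predictive_values(table)
print(f"{ms.sensitivity:.2%} {ms.specificity:.2%} {ms.proportion_correct:.2%}")
# 76.89% 88.17% 82.67%
print(round(f.diagnosticity_ratio(f.correct_rates(table, "none")), 2))  # 6.5
t3 = f.tabulate(expert_study_records(), window=(6, 7))  # ratings 6-7 inconclusive
print(f"{f.ternary_predictive_values(t3).ippv:.2%}")     # 46.94%
```

The expert decisions split into 396 hits, 119 misses, 64 false alarms and 477
correct rejections: a sensitivity of 76.89% (how often same-source pairs were
called "same"), specificity 88.17%, and 82.67% of all 1056 decisions correct.
The diagnosticity ratio of 6.5 says "same" calls were 6.5 times more likely
on same-source than different-source pairs. When the two least-confident
rating values are recoded as inconclusive decisions, 46.94% of those
inconclusive pairs were in fact same-source (IPPV).

The `examples/` directory holds one short script per capability
(`classification_tables.py`, `resampled_experiment.py`,
`inconclusive_policies.py`, `trial_count_power.py`); each prints the numbers
it computes with a line on what they mean. A thin CLI mirrors the library:

```bash
forensicsdt metrics ratings.csv --inconclusive 6:7
forensicsdt simulate --seed 1 --out out/
forensicsdt prevalence --seed 1 --out sweep/
```

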