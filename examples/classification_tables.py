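"""Classification tables and diagnostic accuracies from trial-level ratings.

Builds the packaged worked-example datasets (synthetic integer ratings whose
tallies match the published expert/novice study tables), tabulates them
against ground truth, and prints every table-derived performance number.
"""

import forensicsdt as f
from forensicsdt.fixtures import expert_study_records, novice_study_records

for name, records in (("expert", expert_study_records()),
                      ("novice", novice_study_records())):
    table = f.tabulate(records)
    ms = f.rates_and_predictive_values(table)
    pair = f.correct_rates(table, "none")
    print(f"\n{name}: H={table.hits} M={table.misses} "
          f"FA={table.false_alarms} CR={table.correct_rejections}")
    print(f"  sensitivity {ms.sensitivity:.2%}   specificity {ms.specificity:.2%}")
    print(f"  PPV {ms.ppv:.2%}   NPV {ms.npv:.2%}")
    print(f"  proportion correct {ms.proportion_correct:.2%}")
    print(f"  diagnosticity ratio {f.diagnosticity_ratio(pair):.2f}   "
          f"d' {f.d_prime(pair):.2f} (pooled, uncorrected)")

# Recode the least-confident ratings (6 and 7) as inconclusive decisions:
# sensitivity/specificity drop (inconclusives count in the denominators only)
# while PPV/NPV rise (the hardest trials leave the conclusive columns).
t3 = f.tabulate(expert_study_records(), window=(6.0, 7.0))
m3 = f.ternary_predictive_values(t3)
print(f"\nexpert, ratings 6-7 inconclusive: "
      f"H={t3.hits} M={t3.misses} inc_same={t3.inconclusive_same} | "
      f"FA={t3.false_alarms} CR={t3.correct_rejections} "
      f"inc_diff={t3.inconclusive_different}")
print(f"  sensitivity {m3.sensitivity:.2%}   specificity {m3.specificity:.2%}")
print(f"  PPV {m3.ppv:.2%}   NPV {m3.npv:.2%}")
print(f"  IPPV {m3.ippv:.2%}   INPV {m3.inpv:.2%} "
      f"(source split among the {t3.n_inconclusive} inconclusive calls)")
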