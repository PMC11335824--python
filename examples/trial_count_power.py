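"""Spurious training effects from a few easy trials, and how many trials dilute them.

Both "pre" and "post" groups draw from the same distribution (a training
intervention with zero true effect), but the post-test set contains a few
trials so easy that everyone rates them 1 ("sure different"). A handful of
such trials makes the null difference look significant; doubling the total
trial count shrinks the easy-trial share and the spurious effect with it.
"""

import forensicsdt as f

design = f.ExperimentDesign(n_replicates=20)

summary = f.run_sweep(f.sweep_easy_trials(design=design), seed=7)
print("median pre-vs-post p for proportion correct, by number of easy trials:")
sub = summary[(summary["metric"] == "proportion_correct")
              & (summary["group"] == "post")].sort_values("step")
for r in sub.itertuples(index=False):
    flag = "  <- spuriously significant" if r.median_p < 0.05 else ""
    print(f"  k={int(r.step)} easy trials of 24: median p = {r.median_p:.4f}{flag}")

summary = f.run_sweep(f.sweep_n_trials(design=design), seed=7)
print("\nmedian p at a fixed 4 easy trials, by total trial count:")
sub = summary[(summary["metric"] == "proportion_correct")
              & (summary["group"] == "post")].sort_values("step")
for r in sub.itertuples(index=False):
    print(f"  {int(r.step):>3d} trials: median p = {r.median_p:.4f}")
print("\nmore trials dilute the easy-trial contamination, "
      "but surprisingly many are needed.")
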