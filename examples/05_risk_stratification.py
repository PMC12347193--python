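"""Tercile risk stratification with Kaplan-Meier curves and log-rank tests.

Predicted hazard scores are cut at their 33rd and 66th percentiles into
low / intermediate / high risk groups; Kaplan-Meier curves with Greenwood
95% intervals summarize each group, and pairwise log-rank tests quantify
the separation.
"""

import numpy as np

from omisurv import (
    TrainConfig,
    ensemble_predict,
    km_estimate,
    logrank_test,
    make_splits,
    recovery_config,
    simulate_cohort,
    tercile_stratify,
    train_cv,
)
from omisurv.experiments import build_integrated, standardize

bundle = simulate_cohort(recovery_config(seed=0, n_samples=600))
plan = make_splits(bundle.cohort_labels, bundle.survival, k=10, seed=0)
im = build_integrated(bundle, fit_ids=[bundle.clinical.index[i]
                                       for i in plan.trainval_idx])
x = standardize(im.values, plan.trainval_idx)
cs = train_cv(x, bundle.survival, plan, TrainConfig(seed=0))

scores = ensemble_predict(cs, x[plan.test_idx])
rec = bundle.survival.subset(plan.test_idx)
strata = tercile_stratify(scores)
print(f"hazard-score cuts: 33rd pct = {strata.cut_low:.3f}, "
      f"66th pct = {strata.cut_high:.3f}")

groups = {}
for label in ("low", "intermediate", "high"):
    idx = np.flatnonzero(strata.labels == label)
    groups[label] = rec.subset(idx)
    km = km_estimate(groups[label])
    median = km.event_times[km.survival <= 0.5]
    med = f"{median[0]:7.0f} d" if median.size else "   not reached"
    print(f"  {label:12s} n={len(idx):3d}  events={groups[label].n_events:3d}  "
          f"median survival: {med}")

print("\npairwise log-rank tests:")
for a, b in (("low", "intermediate"), ("intermediate", "high"), ("low", "high")):
    stat, p = logrank_test(groups[a], groups[b])
    print(f"  {a:12s} vs {b:12s}: chi2 = {stat:6.1f}, p = {p:.2e}")
print("small p-values: the terciles separate distinct survival experiences")
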