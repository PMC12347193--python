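"""Primary cancer-type classification from the shared encoder.

A single linear head on the patient embedding classifies the cohort
(cancer type). Stage is excluded from the clinical covariates: its
distribution differs across cancers, so including it would leak the label.
"""

import numpy as np

from omisurv import TrainConfig, classification_report, fit_model, separable_config, simulate_cohort
from omisurv.experiments import build_integrated, standardize

bundle = simulate_cohort(separable_config(seed=0, n_samples=500, n_cohorts=6))
im = build_integrated(bundle, include_stage=False)
x = standardize(im.values)
y = bundle.cohort_labels
n_train = 400

model = fit_model(
    x[:n_train], y[:n_train], kind="classify",
    cfg=TrainConfig(n_classes=6, epochs=40, seed=0),
    x_val=x[n_train:], val_target=y[n_train:],
)
pred = model.predict(x[n_train:]).argmax(axis=1)
rep = classification_report(pred, y[n_train:], n_classes=6)

print(f"test accuracy over {len(pred)} held-out patients: {rep.accuracy:.3f}")
print(f"weighted F1: {rep.weighted_f1:.3f}\n")
print("class  precision  recall  f1  support")
for row in rep.to_dataframe().itertuples(index=False):
    print(f"  {row[0]}      {row.precision:.2f}     {row.recall:.2f}   "
          f"{row.f1:.2f}   {row.support}")
print("\nconfusion matrix (rows true, columns predicted):")
print(rep.confusion)
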