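"""Modality ablation: how performance degrades as data layers are withheld.

Blocks outside each named mask are zeroed through the integration padding
mechanism and the cross-validation recipe is re-run: 1-modal (expression
only), 3-modal (the transcriptomic trio), then adding protein, mutation,
and finally clinical covariates.
"""

from omisurv import TrainConfig, make_splits, modality_ablation, recovery_config, simulate_cohort
from omisurv.experiments import build_integrated, standardize
from omisurv.integrate import IntegratedMatrix

bundle = simulate_cohort(recovery_config(seed=0, n_samples=600))
plan = make_splits(bundle.cohort_labels, bundle.survival, k=3, seed=0)
im = build_integrated(bundle, fit_ids=[bundle.clinical.index[i]
                                       for i in plan.trainval_idx])
x = standardize(im.values, plan.trainval_idx)
im_std = IntegratedMatrix(
    sample_ids=im.sample_ids, feature_ids=im.feature_ids, values=x,
    block_offsets=im.block_offsets, padding_mask=im.padding_mask,
)

rows = modality_ablation(im_std, bundle.survival, plan, TrainConfig(seed=0))
print("mask      kept blocks                                   test C  ensemble C")
for r in rows:
    kept = ",".join(k.split("_")[0] for k in r["kept"])
    print(f"{r['mask']:9s} {kept:45s} {r['test_cindex']:.3f}   "
          f"{r['ensemble_cindex']:.3f}")
print("\nevery block carries signal on the same latent risk factors, so the")
print("C-index degrades gracefully as layers are withheld and recovers as")
print("they are added back")
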