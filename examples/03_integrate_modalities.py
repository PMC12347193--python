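"""Union-based feature integration: per-cohort unions, zero-padding, and
cross-modality concatenation with clinical covariates.

Cohorts retain different feature subsets after preprocessing; integration
forms the sorted union per modality, zero-pads what a cohort lacks (masked,
so no silent zeros), then concatenates the modality blocks in canonical
order over the outer join of patients.
"""

import numpy as np

from omisurv import (
    concat_modalities,
    encode_clinical,
    pad_and_align,
    recovery_config,
    simulate_cohort,
    union_features,
)

bundle = simulate_cohort(recovery_config(seed=0, n_samples=300))

# two pseudo-cohorts keeping different feature subsets of one modality
expr = bundle.matrices["gene_expression"]
cohort_a = expr.subset_features(np.arange(0, 40))
cohort_b = expr.subset_features(np.arange(20, 60))
space = union_features([cohort_a, cohort_b], cohort_names=["A", "B"])
print(f"cohort A: {cohort_a.n_features} features, cohort B: {cohort_b.n_features}, "
      f"union: {space.width}")

aligned = pad_and_align(cohort_a, space)
print(f"cohort A aligned to the union: {aligned.n_features} columns, "
      f"{aligned.padding_mask.mean():.0%} zero-padded")

clinical_block, enc = encode_clinical(bundle.clinical, include_stage=True)
print(f"\nclinical covariates encode to {clinical_block.n_features} columns: "
      f"{clinical_block.feature_ids}")

im = concat_modalities(list(bundle.matrices.values()) + [clinical_block])
print(f"\nintegrated matrix: {im.n_samples} samples x {im.width} features")
for mod, (start, width) in im.block_offsets.items():
    print(f"  {mod:16s} columns [{start:3d}, {start + width:3d})")
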