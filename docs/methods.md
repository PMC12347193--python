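# Methods

## Model and training procedure

The encoder is a feedforward self-normalizing network: seven hidden blocks,
each `linear -> SELU -> Alpha-Dropout`, followed by a final linear layer
producing a 48-dimensional patient embedding. SELU uses the fixed constants
λ = 1.05071 and α = 1.6733; with zero-mean weights of variance 1/fan-in
(LeCun-normal initialization) these constants make zero mean / unit variance
a stable fixed point of the layer map, which is what lets a seven-layer
network train on wide, sparse inputs without batch normalization.
Alpha-Dropout is implemented in its canonical self-normalizing form: a unit
is dropped to the SELU negative-saturation value −λα with probability *p*,
then the affine correction `a·x + b` with `a = (q + (λα)² p q)^(-1/2)`,
`b = −a·(−λα)·p`, `q = 1 − p` restores the pre-dropout mean and variance
exactly for standardized activations. (A batch-standardizing variant —
subtract the batch mean, divide by the batch standard deviation, mask,
re-add the mean — satisfies the same stability contract only approximately
and couples units through batch statistics; we implement the affine form,
which is the one whose mean/variance preservation we verify by Monte
Carlo.) The embedding layer itself is not followed by activation or
dropout; heads consume the raw embedding.

Hidden widths are not architecturally constrained; the default is a
geometric taper from the input width to the embedding width over the seven
blocks (e.g. 241 → 196 → 160 → … → 59 → 48 for the synthetic-scale input),
which scales the same shape to any input dimension and is fully
configurable.

Heads are single linear layers sharing the backbone: a scalar hazard score
(higher score = higher hazard = shorter expected survival, fixed
project-wide), `n_classes` logits (33 by default), or a scalar regression
output. The survival loss is the negative Cox partial log-likelihood with
Breslow tie handling, averaged over events; it is shift-invariant in the
scores and undefined (raised as `NonAdmissibleError`) on an all-censored
batch — the practical failure mode on cohorts with very few events.
Classification uses softmax cross-entropy; TLS regression uses the Huber
loss (δ = 1.0 on the ratio scale by default; the head output is unbounded
during training and optionally clamped to [0, 1] at report time).

Baseline training: Adam (β = 0.9/0.999), learning rate 1e-3, minibatches of
64 (a survival minibatch without an event has no admissible comparisons and
is skipped), dropout 0.25, at most 30 epochs with early stopping on
validation loss (patience 5, best parameters restored). Fine-tuning
unfreezes every layer and uses learning rate 4e-5, dropout 0.35, weight
decay 1e-2 ("high"; applied L2-style to weight matrices only), 10 epochs,
no early stopping. When fine-tuning attaches a head for a *different* task,
the new head starts from the neutral prediction (zero weights, bias at the
target mean for regression) rather than from a random projection of the
already-trained embedding, whose scale and orientation would otherwise
dominate the few-shot updates. All randomness flows from explicit seeds;
training is deterministic given seed, config, and data.

## Data protocol

Per cancer type, samples are split 80/20 into a train-validation pool and a
hold-out test set; 10-fold cross-validation over the pooled train-validation
samples yields ten checkpoints, one per fold. Ensembling averages the ten
per-checkpoint prediction vectors elementwise before the metric is
computed; both the mean single-checkpoint C-index and the ensemble C-index
are reported. The stratified split variant balances the event indicator
across folds to within one sample. Integration statistics that could leak
(clinical encoding vocabularies, age standardization, per-feature
z-scoring) are fit on the train-validation pool only. Stage columns are
omitted from the clinical encoding for cancer-type classification, where
the stage distribution is label-informative.

Preprocessing order is fixed: all-NaN filter → quasi-constant (modal-value
fraction ≥ 0.998 over observed entries) → exact duplicates (first feature
in order kept; values canonicalized to 10 decimals so serialization
round-trips do not split duplicate groups; the missing pattern participates
in equality) → variance filter (population variance, strict >) → expression
floor (gene expression only; a feature is kept iff *some* sample exceeds
log2 = 7, i.e. 127 FPKM — the mean-exceedance reading is available as a
config option) → within-(modality, cohort) mean imputation. Variance
thresholds are per-modality: 0.25 for the log/z-scale modalities
(expression, miRNA, protein) but 0.005 for methylation and 0.02 for
mutation, because beta values are compressed into [0, 1] and a binary
feature's population variance cannot exceed 0.25, so a uniform 0.25
threshold would delete those blocks wholesale. Filters act on columns only
and never touch sample order.

Survival conventions: time in days, strictly positive; δ = 1 marks an
observed event. The concordance index is Harrell's: a pair is admissible
iff the strictly earlier time belongs to an event; score ties count 1/2;
pairs tied on time are excluded (including event-vs-censored ties — with
continuous simulated times this is measure-zero and the implementation
matches lifelines exactly on tie-free data). Kaplan–Meier estimates are
tabulated at distinct event times with Greenwood-variance 95% intervals on
the log-survival scale, clipped to [0, 1]; the log-rank test delegates to
lifelines. Tercile stratification cuts at the 33rd and 66th percentiles
(linear interpolation), labels by `score ≤ cut_low` / `≤ cut_high` / above,
so ties at a cut resolve downward deterministically.

## What the synthetic generator emulates — and what it does not

Each simulated patient carries a latent state of four risk factors and four
nuisance factors. The risk score is η = β·z with default effect sizes
β = (1.4, 1.2, 0.9, 0.7) in the recovery conditions, calibrated once so
that the concordance of the true η against the generated outcomes is ≈ 0.85.
Event times are exponential with hazard `baseline · exp(η)` (Weibull-like
shape is out of scope); independent exponential censoring has its rate set
by bisection so the expected censored fraction matches the target (default
0.30). Modality blocks are noisy linear readouts of the latent state mapped
to each modality's natural scale: expression ≈ N(7.5, 1.6²) on the
log2 scale (so informative features pass the expression floor), methylation
through a logistic squash into (0, 1), miRNA and protein on log/z scales,
mutations by thresholding a standardized latent readout at per-feature
rates in [0.25, 0.5]. Cancer-type clusters shift the *nuisance* factors
only (along signed coordinate axes, pairwise separation ≥ √2 × the
separation parameter), so cohort structure does not distort the risk-score
distribution; the "separable" preset (separation 5) makes labels linearly
recoverable from the latent state with ≥ 99% accuracy. The TLS ratio is
`logistic(−a·η_std + noise)`, anti-correlated with risk by default, with a
configurable missing-label fraction (default 6.5%, ≈ 7 missing in a
108-patient cohort).

Pathological columns for auditing the preprocessing cascade are injected at
registered positions: all-missing, constant, quasi-constant, exact
duplicates (copied after missing-value injection so the duplicate shares
its source's missing pattern), and low-variance columns. One generator
property to note: a literal "99.9%-constant" column is representable only
for n ≥ 500 (the modal fraction is at most (n−1)/n), so below that the
injected quasi-constant column is constant except for one sample offset by
0.05 — its near-zero variance guarantees removal by the variance stage
instead; the audit asserts that the *set* of removed columns equals the
registry, not which stage removed each. Missing values are injected such
that every clean column stays observed at least once per cohort, matching
the imputation contract.

The generator reproduces the structural and statistical properties the
pipeline assumes — block widths and scales, cohort labels, missingness,
proportional-hazards outcomes, a bounded risk-linked TLS ratio — but makes
no attempt to mimic real per-gene marginal distributions, inter-gene
correlation structure, batch effects, or platform noise. Passing tests
therefore demonstrate that the machinery is correct and can recover planted
signal at realistic sizes; they do not certify performance on real cohorts.

## Problem sizes

Studies run at a reduced scale chosen for minutes-level CPU runtimes: the
recovery experiment uses five replicate cohorts of 600 patients and ~240
integrated features with 10-fold cross-validation (50 trained networks);
the ablation sweep uses 3 folds per mask (75 networks across five masks and
five seeds) since the per-mask ordering, not the absolute level, is the
quantity of interest; the log-rank type-I study uses 1000 replicates of two
50-patient groups; the cascade audit 20 random configurations of 50 × (12–45)
blocks. Full-paper scale (tens of thousands of features, >10⁴ patients) is
reachable through the same configs but is not a test target.

## Known limitations

* The Cox loss is computed per minibatch, so very small batches see noisy
  risk sets; with the default batch 64 and ≥ 30% events this is benign.
* Harrell's C (not a time-truncated or IPCW variant) is the only
  discrimination metric; it is optimistic under heavy censoring.
* The TLS head is evaluated for bias (paired test) and group separation,
  not calibrated accuracy; the few-shot regime barely moves a fresh head
  beyond the neutral prediction on 80 patients.
* No batch-effect correction, identifier mapping, competing risks, or
  time-dependent covariates.
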