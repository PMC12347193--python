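# omisurv

Self-normalizing neural networks for pan-cancer multi-omics modelling:
censored overall-survival prediction, primary cancer-type classification, and
tertiary-lymphoid-structure (TLS) ratio regression from a shared patient
embedding.

## Who this is for

Computational oncology and biostatistics groups who want a fully tested,
reduced-scale implementation of the multi-omics survival workflow: the
per-modality feature-filter cascade, union-based integration with
zero-padding across cohorts and modalities, a SELU/Alpha-Dropout encoder
trained with the Cox partial likelihood, cross-validated checkpoint
ensembling, tercile risk stratification with Kaplan–Meier / log-rank
analysis, few-shot fine-tuning, and modality ablation. Everything runs on
synthetic cohorts with known ground truth, so every stage is verifiable
without any data downloads.

## The model

Patients are described by up to six blocks — gene expression
(log2(FPKM+1)), DNA methylation (beta values), miRNA expression, protein
(RPPA), binary mutations, and encoded clinical covariates (age, gender,
race, stage). After per-modality filtering (all-NaN, quasi-constant at
0.998, duplicates, low variance, expression floor at log2 = 7 ≙ 127 FPKM)
and within-cohort mean imputation, features are unified per modality,

&nbsp;&nbsp;&nbsp;&nbsp;*V*<sub>m</sub> = ∪<sub>i</sub> *v*<sub>i</sub>,

zero-padded, and concatenated across modalities into *V*<sub>c</sub>. The
encoder is seven blocks of linear → SELU → Alpha-Dropout,

&nbsp;&nbsp;&nbsp;&nbsp;SELU(x) = λx for x > 0, λα(e<sup>x</sup> − 1)
otherwise, with λ = 1.05071, α = 1.6733,

ending in a 48-dimensional patient embedding **x** ∈ ℝ⁴⁸. LeCun-normal
initialization and the Alpha-Dropout affine correction keep activations
near zero mean and unit variance through depth. Linear heads on the
embedding produce a scalar hazard score (trained with the negative Cox
partial log-likelihood, Breslow ties), 33 class logits, or a TLS-ratio
estimate (Huber loss). Survival uses the standard conventions: observed
time T = min(T<sub>s</sub>, T<sub>c</sub>), event indicator δ = 1 for an
observed death; evaluation is Harrell's concordance index; stratification
cuts hazard scores at their 33rd/66th percentiles.

## Worked example

`python examples/04_survival_training.py` simulates a 600-patient six-block
cohort whose true (oracle) risk score has a concordance of ~0.85 against
the generated outcomes, then runs the full pipeline:

```
integrated input: 600 samples x 241 features
per-fold validation C-index: 0.781 0.822 0.781 0.783 0.839 0.805 0.773 0.743 0.876 0.784

hold-out (121 patients):
  mean single-checkpoint C-index : 0.808
  10-checkpoint ensemble C-index : 0.840
  oracle (true risk) C-index     : 0.849
```

The ensemble of the ten cross-validation checkpoints recovers almost the
whole oracle margin over chance (0.5). `examples/05_risk_stratification.py`
stratifies the same hold-out predictions into terciles:

```
  low          n= 40  events= 12  median survival:    not reached
  intermediate n= 40  events= 31  median survival:     549 d
  high         n= 41  events= 38  median survival:      54 d
  low          vs high        : chi2 =   71.2, p = 3.23e-17
```

Each `examples/` script covers one capability (simulation, preprocessing,
integration, survival training, stratification, classification, TLS
regression, modality ablation) and prints what the numbers mean. A thin CLI
(`omisurv simulate / preprocess / train / predict / evaluate`) covers the
shell-friendly stages.

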