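"""Training orchestration: splits, k-fold cross-validation, checkpoint
ensembling, fine-tuning, and modality ablation.

The protocol mirrors standard pan-cancer practice: a per-cohort 80/20
train-validation / hold-out split, 10-fold cross-validation over the pooled
train-validation set (one trained checkpoint per fold), evaluation by
concordance index, and test-time ensembling by averaging the per-checkpoint
prediction vectors before computing the metric. Fine-tuning unfreezes every
layer and re-trains briefly with a very small learning rate, high weight
decay, and raised dropout. Modality ablation re-trains with chosen blocks
zeroed through the integration padding mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .integrate import IntegratedMatrix
from .matrix import InvalidInputError
from .nn import Adam, Backbone, Model, SNNConfig
from .survival import (
    NonAdmissibleError,
    SurvivalData,
    concordance_index,
    cox_loss,
    cox_loss_grad,
)

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "CheckpointSet",
    "ABLATION_MASKS",
    "make_splits",
    "fit_model",
    "train_cv",
    "ensemble_predict",
    "fine_tune",
    "modality_ablation",
]

#: Named modality subsets for the ablation study. 3-modal is the
#: transcriptomic trio; protein and mutation are added in turn; 6-modal is
#: everything including clinical.
ABLATION_MASKS: Mapping[str, tuple[str, ...]] = {
    "1-modal": ("gene_expression",),
    "3-modal": ("gene_expression", "dna_methylation", "mirna"),
    "4-modal": ("gene_expression", "dna_methylation", "mirna", "protein"),
    "5-modal": ("gene_expression", "dna_methylation", "mirna", "protein", "mutation"),
    "6-modal": (
        "gene_expression",
        "dna_methylation",
        "mirna",
        "protein",
        "mutation",
        "clinical",
    ),
}


@dataclass
class SplitPlan:
    """Hold-out and cross-validation fold assignment over sample indices."""

    test_idx: np.ndarray
    trainval_idx: np.ndarray
    folds: list[np.ndarray]  # validation indices per fold, partitioning trainval
    seed: int
    stratified: bool

    def fold_train_idx(self, k: int) -> np.ndarray:
        val = set(self.folds[k].tolist())
        return np.array([i for i in self.trainval_idx if i not in val])


def make_splits(
    cohorts: Sequence[str] | np.ndarray,
    records: SurvivalData,
    k: int = 10,
    stratify: bool = False,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Per-cohort 80/20 hold-out plus k folds over the pooled remainder.

    Each cohort contributes ``round(test_fraction * n_cohort)`` samples to the
    hold-out set (within one sample of the exact fraction). The k folds
    partition the pooled train-validation set; with ``stratify=True`` the
    event indicator is balanced across folds to within one sample per fold
    (raises if the pool has no events, since there is nothing to stratify on).
    """
    cohorts = np.asarray(cohorts)
    n = len(cohorts)
    if len(records) != n:
        raise InvalidInputError("records must align with cohort labels")
    rng = np.random.default_rng(seed)
    test: list[int] = []
    for c in np.unique(cohorts):
        idx = np.flatnonzero(cohorts == c)
        if idx.size < 2:
            raise InvalidInputError(f"cohort {c!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test.extend(idx[:n_test].tolist())
    test_idx = np.sort(np.array(test, dtype=int))
    trainval_idx = np.setdiff1d(np.arange(n), test_idx)

    events = records.event[trainval_idx]
    if stratify:
        if events.sum() == 0:
            raise NonAdmissibleError(
                "stratified split requested but the pool has zero events"
            )
        folds: list[list[int]] = [[] for _ in range(k)]
        for group in (1, 0):
            members = rng.permutation(trainval_idx[events == group])
            for j, i in enumerate(members):
                folds[j % k].append(int(i))
        fold_arrays = [np.sort(np.array(f, dtype=int)) for f in folds]
    else:
        perm = rng.permutation(trainval_idx)
        fold_arrays = [np.sort(chunk) for chunk in np.array_split(perm, k)]
    return SplitPlan(
        test_idx=test_idx,
        trainval_idx=trainval_idx,
        folds=fold_arrays,
        seed=seed,
        stratified=stratify,
    )


@dataclass
class TrainConfig:
    """Baseline training hyperparameters (all logged with each run)."""

    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 64
    dropout: float = 0.25
    weight_decay: float = 0.0
    patience: int = 5  # early stopping on validation loss; 0 disables
    embedding_dim: int = 48
    hidden_widths: Sequence[int] | None = None
    n_classes: int = 33
    seed: int = 0


def _softmax_ce_grad(logits: np.ndarray, labels: np.ndarray):
    m = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(m)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-300)))
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def _huber_grad(pred: np.ndarray, target: np.ndarray, delta: float = 1.0):
    r = pred - target
    quad = np.abs(r) <= delta
    loss = float(
        np.mean(np.where(quad, 0.5 * r * r, delta * (np.abs(r) - 0.5 * delta)))
    )
    grad = np.where(quad, r, delta * np.sign(r)) / len(r)
    return loss, grad


def _batch_loss_grad(model: Model, x, target, kind: str):
    out, cache = model.forward_cached(x)
    if kind == "hazard":
        loss, g = cox_loss_grad(out, target)
    elif kind == "classify":
        loss, g = _softmax_ce_grad(out, target)
    else:
        loss, g = _huber_grad(out, target)
    return loss, model.backward(g, cache)


def _eval_loss(model: Model, x, target, kind: str) -> float:
    model.eval()
    out = model.forward(x)
    if kind == "hazard":
        return cox_loss(out, target)
    if kind == "classify":
        loss, _ = _softmax_ce_grad(out, target)
        return loss
    loss, _ = _huber_grad(out, target)
    return loss


def fit_model(
    x: np.ndarray,
    target,
    kind: str = "hazard",
    cfg: TrainConfig | None = None,
    x_val: np.ndarray | None = None,
    val_target=None,
    model: Model | None = None,
    log: list | None = None,
) -> Model:
    """Train one model by minibatch Adam on the task loss.

    ``kind`` selects the head and loss: ``'hazard'`` (Cox partial
    likelihood over each minibatch; batches without an event are skipped),
    ``'classify'`` (softmax cross-entropy over integer labels), or
    ``'regress'`` (Huber). With a validation set and ``patience > 0``, early
    stopping restores the best-validation-loss parameters. Fully
    deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if kind == "hazard" and target.n_events == 0:
        raise NonAdmissibleError("cannot train on a set with zero events")
    if model is None:
        snn = SNNConfig(
            input_dim=x.shape[1],
            hidden_widths=cfg.hidden_widths,
            embedding_dim=cfg.embedding_dim,
            dropout_rate=cfg.dropout,
            seed=cfg.seed,
        )
        model = Model(Backbone(snn), kind, cfg.n_classes)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5B1F)))
    best_loss, best_params, best_age = np.inf, None, 0
    for epoch in range(cfg.epochs):
        model.train()
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            if kind == "hazard":
                tb = target.subset(idx)
                if tb.n_events == 0:
                    continue  # no admissible comparisons in this batch
                loss, grads = _batch_loss_grad(model, x[idx], tb, kind)
            else:
                loss, grads = _batch_loss_grad(model, x[idx], target[idx], kind)
            opt.step(grads)
            epoch_losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if x_val is not None and cfg.patience > 0:
            try:
                vloss = _eval_loss(model, x_val, val_target, kind)
            except NonAdmissibleError:
                vloss = np.inf
            entry["val_loss"] = vloss
            if vloss < best_loss - 1e-9:
                best_loss = vloss
                best_params = [p.copy() for p in model.parameters()]
                best_age = 0
            else:
                best_age += 1
                if best_age >= cfg.patience:
                    if log is not None:
                        log.append(entry)
                    break
        if log is not None:
            log.append(entry)
    if best_params is not None:
        model.load_params(best_params)
    model.eval()
    return model


@dataclass
class CheckpointSet:
    """The k models trained in cross-validation, plus their fold metrics."""

    models: list[Model]
    fold_metrics: list[float]  # validation C-index per fold
    config: TrainConfig
    plan: SplitPlan | None = None

    def __post_init__(self) -> None:
        cfgs = {tuple(m.backbone.config.hidden_widths) for m in self.models}
        dims = {m.backbone.config.input_dim for m in self.models}
        if len(cfgs) > 1 or len(dims) > 1:
            raise InvalidInputError("checkpoints must share one architecture")

    def __len__(self) -> int:
        return len(self.models)


def train_cv(
    x: np.ndarray,
    records: SurvivalData,
    plan: SplitPlan,
    cfg: TrainConfig | None = None,
) -> CheckpointSet:
    """Train one hazard model per cross-validation fold.

    Each fold's model trains on the other folds and early-stops on its own
    validation fold; the validation concordance index is logged per fold. A
    fold whose training set has no events is non-admissible and raises,
    naming the fold.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(x, dtype=np.float64)
    models: list[Model] = []
    metrics: list[float] = []
    for k, val_idx in enumerate(plan.folds):
        train_idx = plan.fold_train_idx(k)
        rec_train = records.subset(train_idx)
        if rec_train.n_events == 0:
            raise NonAdmissibleError(f"non-admissible fold {k}: zero events")
        fold_cfg = replace(cfg, seed=cfg.seed * 1000 + k)
        model = fit_model(
            x[train_idx],
            rec_train,
            kind="hazard",
            cfg=fold_cfg,
            x_val=x[val_idx],
            val_target=records.subset(val_idx),
        )
        models.append(model)
        try:
            c = concordance_index(
                model.predict(x[val_idx]), records.subset(val_idx)
            )
        except NonAdmissibleError:
            c = np.nan
        metrics.append(float(c))
    return CheckpointSet(models=models, fold_metrics=metrics, config=cfg, plan=plan)


def ensemble_predict(cs: CheckpointSet, x: np.ndarray) -> np.ndarray:
    """Elementwise mean of the per-checkpoint prediction vectors."""
    if len(cs) == 0:
        raise InvalidInputError("empty checkpoint set")
    preds = [m.predict(x) for m in cs.models]
    return np.mean(preds, axis=0)


@dataclass
class FineTuneConfig:
    """The few-shot adaptation regime: all layers unfrozen, very small
    learning rate, high weight decay and dropout, few epochs."""

    lr: float = 4e-5
    epochs: int = 10
    dropout: float = 0.35
    weight_decay: float = 1e-2
    batch_size: int = 32
    seed: int = 0


def fine_tune(
    model: Model,
    x: np.ndarray,
    target,
    cfg: FineTuneConfig | None = None,
    kind: str | None = None,
    log: list | None = None,
) -> Model:
    """Adapt a trained model to a new cohort or task.

    Every layer (backbone and head) stays in the optimizer's parameter list.
    The input model is left untouched; a fine-tuned copy is returned. For a
    survival target the new cohort must contain at least one event.
    """
    cfg = cfg or FineTuneConfig()
    kind = kind or model.kind
    if kind == "hazard" and target.n_events == 0:
        raise NonAdmissibleError("fine-tuning cohort has zero events")
    tuned = model.copy() if kind == model.kind else None
    if tuned is None:
        tuned = Model(model.backbone, kind)  # reuse encoder, fresh head
        tuned.backbone = model.copy().backbone
        # a new task head starts from the neutral prediction: zero weights,
        # bias at the target mean (regression) or zero logits
        tuned.head_w[...] = 0.0
        tuned.head_b[...] = (
            float(np.mean(target)) if kind == "regress" else 0.0
        )
    tuned = tuned.with_dropout(cfg.dropout)
    train_cfg = TrainConfig(
        lr=cfg.lr,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        dropout=cfg.dropout,
        weight_decay=cfg.weight_decay,
        patience=0,
        seed=cfg.seed,
    )
    if log is not None:
        log.append(
            {
                "stage": "fine_tune",
                "lr": cfg.lr,
                "epochs": cfg.epochs,
                "dropout": cfg.dropout,
                "weight_decay": cfg.weight_decay,
                "unfrozen_parameters": len(tuned.parameters()),
            }
        )
    return fit_model(x, target, kind=kind, cfg=train_cfg, model=tuned, log=log)


def modality_ablation(
    im: IntegratedMatrix,
    records: SurvivalData,
    plan: SplitPlan,
    cfg: TrainConfig | None = None,
    masks: Mapping[str, Sequence[str]] | None = None,
) -> list[dict]:
    """Retrain and evaluate with modality subsets withheld.

    For each named mask, blocks *not* in the mask are zeroed through the
    integration padding mechanism, the cross-validation recipe is re-run, and
    the hold-out metrics are reported: the mean single-checkpoint test
    C-index and the ensemble C-index.
    """
    masks = dict(masks) if masks is not None else dict(ABLATION_MASKS)
    if any(len(v) == 0 for v in masks.values()):
        raise InvalidInputError("an ablation mask must keep at least one modality")
    results = []
    test_records = records.subset(plan.test_idx)
    for name, keep in masks.items():
        unknown = [m for m in keep if m not in im.block_offsets]
        if unknown:
            raise InvalidInputError(f"mask {name!r} names unknown block {unknown[0]!r}")
        drop = [m for m in im.block_offsets if m not in keep]
        masked = im.zero_blocks(drop) if drop else im
        cs = train_cv(masked.values, records, plan, cfg)
        x_test = masked.values[plan.test_idx]
        test_cs = [
            concordance_index(m.predict(x_test), test_records) for m in cs.models
        ]
        ens_c = concordance_index(ensemble_predict(cs, x_test), test_records)
        results.append(
            {
                "mask": name,
                "kept": tuple(keep),
                "test_cindex": float(np.mean(test_cs)),
                "ensemble_cindex": float(ens_c),
                "fold_val_cindex": list(cs.fold_metrics),
            }
        )
    return results
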