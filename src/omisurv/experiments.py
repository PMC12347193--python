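"""End-to-end study runners on synthetic cohorts.

These functions wire the whole pipeline together — simulate, preprocess,
integrate, split, train, ensemble, evaluate — at a reduced scale chosen so a
full study runs in minutes on one CPU: cohorts of hundreds of samples and a
few hundred integrated features rather than the five-figure dimensions of
real pan-cancer matrices. They are used by the example scripts and by the
repository's acceptance checks.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np
from scipy import stats

from .integrate import IntegratedMatrix, concat_modalities, encode_clinical
from .pipeline import (
    SplitPlan,
    TrainConfig,
    ensemble_predict,
    make_splits,
    modality_ablation,
    train_cv,
)
from .preprocess import PreprocessConfig, run_cascade
from .simulate import (
    CohortBundle,
    SimConfig,
    gen_multiomics,
    recovery_config,
    simulate_cohort,
)
from .survival import SurvivalData, concordance_index, logrank_test, tercile_stratify

__all__ = [
    "standardize",
    "build_integrated",
    "recovery_study",
    "ablation_study",
    "finetune_study",
    "logrank_type1_study",
    "tls_type1_study",
    "cascade_audit",
]


def standardize(
    x: np.ndarray, fit_idx: np.ndarray | None = None
) -> np.ndarray:
    """Per-feature z-scoring with statistics fit on ``fit_idx`` rows.

    The final step of the log+z ingestion convention: each integrated column
    is centered and scaled using training-set statistics only, so no hold-out
    information leaks into the transform. Zero-variance columns are left
    centered but unscaled.
    """
    x = np.asarray(x, dtype=np.float64)
    fit = x if fit_idx is None else x[fit_idx]
    mu = fit.mean(axis=0)
    sd = fit.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (x - mu) / sd


def build_integrated(
    bundle: CohortBundle,
    fit_ids: list[str] | None = None,
    include_stage: bool = True,
    preprocess_cfg: PreprocessConfig | None = None,
) -> IntegratedMatrix:
    """Preprocess every modality block, encode clinical, and concatenate."""
    blocks = []
    for mod in bundle.matrices:
        clean, _ = run_cascade(bundle.matrices[mod], preprocess_cfg)
        blocks.append(clean)
    clinical_block, _ = encode_clinical(
        bundle.clinical, fit_on=fit_ids, include_stage=include_stage
    )
    blocks.append(clinical_block)
    return concat_modalities(blocks)


def _prepare(
    seed: int, n_samples: int, k: int, cfg: SimConfig | None = None
) -> tuple[IntegratedMatrix, np.ndarray, SurvivalData, SplitPlan, CohortBundle]:
    sim_cfg = cfg if cfg is not None else recovery_config(seed, n_samples)
    bundle = simulate_cohort(sim_cfg)
    plan = make_splits(
        bundle.cohort_labels, bundle.survival, k=k, stratify=False, seed=seed
    )
    fit_ids = [bundle.clinical.index[i] for i in plan.trainval_idx]
    im = build_integrated(bundle, fit_ids=fit_ids)
    x = standardize(im.values, plan.trainval_idx)
    return im, x, bundle.survival, plan, bundle


def recovery_study(
    seed: int = 0,
    n_seeds: int = 5,
    n_samples: int = 600,
    k: int = 10,
    train_cfg: TrainConfig | None = None,
) -> dict:
    """Train the survival pipeline on fresh synthetic cohorts and measure
    hold-out performance.

    For each of ``n_seeds`` replicate cohorts (oracle concordance of the true
    risk score about 0.85): per-cohort 80/20 hold-out, ``k``-fold CV training
    of hazard models, checkpoint ensembling, hold-out concordance, and a
    tercile stratification of the ensemble hazard scores with a low-vs-high
    log-rank test.
    """
    runs = []
    for s in range(n_seeds):
        run_seed = seed + s
        im, x, records, plan, bundle = _prepare(run_seed, n_samples, k)
        cfg = train_cfg or TrainConfig()
        cfg = replace(cfg, seed=run_seed)
        cs = train_cv(x, records, plan, cfg)
        x_test = x[plan.test_idx]
        rec_test = records.subset(plan.test_idx)
        ens = ensemble_predict(cs, x_test)
        single = [concordance_index(m.predict(x_test), rec_test) for m in cs.models]
        strata = tercile_stratify(ens)
        _, p_lh = logrank_test(
            rec_test.subset(np.flatnonzero(strata.labels == "low")),
            rec_test.subset(np.flatnonzero(strata.labels == "high")),
        )
        oracle = concordance_index(bundle.truth.risk, records)
        runs.append(
            {
                "seed": run_seed,
                "oracle_cindex": float(oracle),
                "ensemble_cindex": float(concordance_index(ens, rec_test)),
                "mean_checkpoint_cindex": float(np.mean(single)),
                "fold_val_cindex": list(cs.fold_metrics),
                "tercile_logrank_p_low_high": float(p_lh),
                "n_test": int(len(rec_test)),
            }
        )
    return {
        "runs": runs,
        "n_samples": n_samples,
        "k": k,
        "ensemble_cindices": [r["ensemble_cindex"] for r in runs],
    }


def ablation_study(
    seed: int = 0,
    n_seeds: int = 5,
    n_samples: int = 600,
    k: int = 3,
    masks: Mapping[str, tuple[str, ...]] | None = None,
    train_cfg: TrainConfig | None = None,
) -> dict:
    """Modality-ablation experiment on replicate synthetic cohorts.

    Every molecular block carries independent signal on the same latent risk
    factors, so hold-out concordance should degrade gracefully — be
    non-decreasing, up to noise — in the number of unmasked blocks. Uses
    ``k``-fold CV (3 by default: the ablation sweep retrains per mask per
    seed, and the per-mask ordering is stable under fewer folds).
    """
    from .pipeline import ABLATION_MASKS

    masks = dict(masks) if masks is not None else dict(ABLATION_MASKS)
    per_mask: dict[str, list[float]] = {name: [] for name in masks}
    for s in range(n_seeds):
        run_seed = seed + s
        im, x, records, plan, _ = _prepare(run_seed, n_samples, k)
        im_std = IntegratedMatrix(
            sample_ids=im.sample_ids,
            feature_ids=im.feature_ids,
            values=x,
            block_offsets=im.block_offsets,
            padding_mask=im.padding_mask,
        )
        cfg = replace(train_cfg or TrainConfig(), seed=run_seed)
        for row in modality_ablation(im_std, records, plan, cfg, masks):
            per_mask[row["mask"]].append(row["ensemble_cindex"])
    return {
        "masks": {name: vals for name, vals in per_mask.items()},
        "mean_ensemble_cindex": {
            name: float(np.mean(vals)) for name, vals in per_mask.items()
        },
        "n_seeds": n_seeds,
    }


def finetune_study(seed: int = 0, n_seeds: int = 5) -> dict:
    """Paired zero-shot vs. fine-tuned comparison under domain shift.

    A base hazard model trains on one synthetic cohort; a second cohort is
    generated with re-drawn loading matrices (a strong feature-to-risk shift,
    emulating an external sequencing platform). Zero-shot transfer is
    evaluated on the shifted cohort's hold-out, then the few-shot fine-tuning
    regime (all layers unfrozen, lr 4e-5, dropout 0.35, high weight decay,
    10 epochs) adapts the model on the shifted cohort's training half.
    """
    from .integrate import concat_modalities
    from .pipeline import FineTuneConfig, fine_tune, fit_model

    pairs = []
    for s in range(n_seeds):
        cfg_a = replace(recovery_config(seed + s, 400), missing_rate=0.0)
        cfg_b = replace(recovery_config(seed + s + 1000, 200), missing_rate=0.0)
        a, b = simulate_cohort(cfg_a), simulate_cohort(cfg_b)
        x_a = standardize(concat_modalities(list(a.matrices.values())).values)
        x_b = standardize(concat_modalities(list(b.matrices.values())).values)
        base = fit_model(
            x_a, a.survival, "hazard", TrainConfig(seed=seed + s, epochs=20)
        )
        n_tr = len(x_b) * 4 // 5
        rec_tr = b.survival.subset(np.arange(n_tr))
        rec_te = b.survival.subset(np.arange(n_tr, len(x_b)))
        zero = concordance_index(base.predict(x_b[n_tr:]), rec_te)
        tuned = fine_tune(base, x_b[:n_tr], rec_tr, FineTuneConfig(seed=seed + s))
        ft = concordance_index(tuned.predict(x_b[n_tr:]), rec_te)
        pairs.append({"seed": seed + s, "zero_shot": float(zero), "fine_tuned": float(ft)})
    return {
        "pairs": pairs,
        "n_improved": sum(p["fine_tuned"] >= p["zero_shot"] for p in pairs),
    }


def logrank_type1_study(
    seed: int = 0,
    n_reps: int = 1000,
    n_per_group: int = 50,
    alpha: float = 0.05,
    censoring_fraction: float = 0.2,
) -> dict:
    """Empirical type-I error of the log-rank test under the null.

    Both groups are drawn from the same exponential survival distribution
    with independent exponential censoring; the rejection rate at ``alpha``
    should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    c_rate = censoring_fraction / (1.0 - censoring_fraction)  # exp/exp censoring
    for _ in range(n_reps):
        t = rng.exponential(1.0, size=2 * n_per_group)
        c = rng.exponential(1.0 / c_rate, size=2 * n_per_group)
        time = np.maximum(np.minimum(t, c), 1e-9)
        event = (t <= c).astype(int)
        a = SurvivalData(time[:n_per_group], event[:n_per_group])
        b = SurvivalData(time[n_per_group:], event[n_per_group:])
        _, p = logrank_test(a, b)
        rejections += p < alpha
    return {
        "rejection_rate": rejections / n_reps,
        "n_reps": n_reps,
        "alpha": alpha,
    }


def tls_type1_study(
    seed: int = 0,
    n_reps: int = 500,
    n_patients: int = 20,
    noise_sd: float = 0.05,
    alpha: float = 0.05,
) -> dict:
    """False-rejection rate of the paired predicted-vs-manual comparison
    when predictions are unbiased (manual ratio plus zero-mean noise)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        manual = rng.beta(2.0, 8.0, size=n_patients)
        predicted = np.clip(
            manual + rng.normal(0.0, noise_sd, size=n_patients), 0.0, 1.0
        )
        _, p = stats.ttest_rel(predicted, manual)
        rejections += p < alpha
    return {
        "false_rejection_rate": rejections / n_reps,
        "n_reps": n_reps,
        "alpha": alpha,
    }


def cascade_audit(
    seed: int = 0, n_configs: int = 20, n_samples: int = 50
) -> dict:
    """Audit the preprocessing cascade against the generator's registry.

    For each random configuration, pathological columns (all-missing,
    constant, quasi-constant, duplicate, low-variance) are injected at known
    positions into every modality block; the cascade must remove exactly the
    registered columns and no others.
    """
    rng = np.random.default_rng(seed)
    excess = missed = 0
    for rep in range(n_configs):
        widths = {
            "gene_expression": int(rng.integers(25, 45)),
            "dna_methylation": int(rng.integers(25, 45)),
            "mirna": int(rng.integers(15, 30)),
            "protein": int(rng.integers(12, 25)),
            "mutation": int(rng.integers(15, 30)),
        }
        pathologies = {
            mod: {
                "all_missing": int(rng.integers(0, 3)),
                "constant": int(rng.integers(0, 3)),
                "quasi_constant": int(rng.integers(0, 3)),
                "duplicate": int(rng.integers(0, 3)),
                "low_variance": int(rng.integers(0, 3)),
            }
            for mod in widths
        }
        cfg = SimConfig(
            n_samples=n_samples,
            modality_widths=widths,
            pathologies=pathologies,
            missing_rate=0.02,
            seed=int(rng.integers(0, 2**31)),
        )
        matrices, truth = gen_multiomics(cfg)
        for mod, m in matrices.items():
            clean, _ = run_cascade(m)
            removed = set(m.feature_ids) - set(clean.feature_ids)
            registered = truth.pathological_ids(mod)
            excess += len(removed - registered)
            missed += len(registered - removed)
    return {
        "n_configs": n_configs,
        "excess_removals": excess,
        "missed_removals": missed,
    }
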