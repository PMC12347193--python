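"""Per-modality feature-filter cascade and within-group mean imputation.

The cascade turns a raw modality block into a machine-learning-ready matrix:

1. drop features missing in every sample;
2. drop constant / quasi-constant features (modal-value fraction >= 0.998);
3. drop exact duplicate features (first in feature order is kept);
4. drop low-variance features (population variance <= threshold);
5. for gene expression only, drop features never exceeding the log2 expression
   floor (default 7, i.e. 127 FPKM on the raw scale);
6. impute remaining missing entries with the feature mean within each
   (modality, cohort) group.

Filters act on columns only: samples are never dropped or reordered. Each
stage emits a :class:`~omisurv.matrix.FilterReport` so the run is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .matrix import FilterReport, InvalidInputError, OmicsMatrix

__all__ = [
    "PreprocessConfig",
    "drop_all_nan_features",
    "drop_quasi_constant",
    "drop_duplicate_features",
    "variance_filter",
    "expression_floor_filter",
    "impute_within",
    "run_cascade",
]

#: Decimal places used to canonicalize values before duplicate detection, so
#: that serialization round-trips do not mask exact duplicates.
_DUP_ROUND_DECIMALS = 10


def _report(
    stage: str, m: OmicsMatrix, dropped: list[str], params: Mapping[str, object]
) -> FilterReport:
    return FilterReport(
        stage_name=stage,
        features_in=m.n_features,
        features_out=m.n_features - len(dropped),
        dropped_ids=dropped,
        parameters=dict(params),
    )


def drop_all_nan_features(m: OmicsMatrix) -> tuple[OmicsMatrix, FilterReport]:
    """Remove exactly the features that are missing for every sample."""
    if m.n_samples == 0 or m.n_features == 0:
        raise InvalidInputError("drop_all_nan_features requires a non-empty matrix")
    all_missing = np.isnan(m.values).all(axis=0)
    dropped = [f for f, d in zip(m.feature_ids, all_missing) if d]
    report = _report("drop_all_nan", m, dropped, {})
    return m.subset_features(~all_missing), report


def drop_quasi_constant(
    m: OmicsMatrix, threshold: float = 0.998
) -> tuple[OmicsMatrix, FilterReport]:
    """Remove features whose single most frequent observed value covers at
    least ``threshold`` of the observed samples.

    Missing entries are excluded from the count; a feature with no observed
    entries is treated as constant and dropped.
    """
    if not 0.5 < threshold <= 1.0:
        raise InvalidInputError(f"threshold must be in (0.5, 1.0], got {threshold}")
    if m.n_samples < 2:
        raise InvalidInputError("quasi-constant filter needs at least 2 samples")
    drop = np.zeros(m.n_features, dtype=bool)
    for j in range(m.n_features):
        col = m.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            drop[j] = True
            continue
        _, counts = np.unique(obs, return_counts=True)
        drop[j] = counts.max() / obs.size >= threshold
    dropped = [f for f, d in zip(m.feature_ids, drop) if d]
    report = _report("drop_quasi_constant", m, dropped, {"threshold": threshold})
    return m.subset_features(~drop), report


def drop_duplicate_features(m: OmicsMatrix) -> tuple[OmicsMatrix, FilterReport]:
    """Among features with identical value vectors, keep only the first.

    Values are rounded to 10 decimals before comparison; the missing pattern
    participates in equality (two columns are duplicates only if they agree on
    both observed values and missing positions). The report records, for each
    dropped feature, the retained representative it duplicated.
    """
    seen: dict[bytes, str] = {}
    drop = np.zeros(m.n_features, dtype=bool)
    representative: dict[str, str] = {}
    rounded = np.round(m.values, _DUP_ROUND_DECIMALS)
    # canonicalize NaN payloads and -0.0 so byte-level hashing is exact
    rounded = np.where(np.isnan(rounded), np.inf, rounded) + 0.0
    for j, fid in enumerate(m.feature_ids):
        key = rounded[:, j].tobytes()
        if key in seen:
            drop[j] = True
            representative[fid] = seen[key]
        else:
            seen[key] = fid
    dropped = [f for f, d in zip(m.feature_ids, drop) if d]
    report = _report(
        "drop_duplicates", m, dropped, {"representatives": representative}
    )
    return m.subset_features(~drop), report


def variance_filter(
    m: OmicsMatrix, threshold: float = 0.25
) -> tuple[OmicsMatrix, FilterReport]:
    """Keep features whose population variance (observed entries, n
    denominator) is strictly greater than ``threshold``."""
    if threshold < 0:
        raise InvalidInputError(f"variance threshold must be >= 0, got {threshold}")
    with np.errstate(invalid="ignore"):
        var = np.nanvar(m.values, axis=0, ddof=0)
    var = np.where(np.isnan(var), 0.0, var)  # fully-missing column -> variance 0
    keep = var > threshold
    dropped = [f for f, k in zip(m.feature_ids, keep) if not k]
    report = _report("variance_filter", m, dropped, {"threshold": threshold})
    return m.subset_features(keep), report


def expression_floor_filter(
    m: OmicsMatrix, cutoff: float = 7.0, aggregation: str = "any"
) -> tuple[OmicsMatrix, FilterReport]:
    """Keep gene-expression features containing high expression.

    On the log2(FPKM+1) scale a cutoff of 7 corresponds to a raw FPKM of
    ``2**7 - 1 = 127``. With ``aggregation='any'`` (default) a feature is kept
    iff at least one sample exceeds the cutoff; ``aggregation='mean'`` keeps a
    feature iff its observed mean exceeds the cutoff.
    """
    if m.modality != "gene_expression":
        raise InvalidInputError(
            f"expression floor filter applies to gene_expression, got {m.modality!r}"
        )
    if aggregation not in ("any", "mean"):
        raise InvalidInputError(f"unknown aggregation {aggregation!r}")
    with np.errstate(invalid="ignore"):
        if aggregation == "any":
            stat = np.nanmax(
                np.where(np.isnan(m.values), -np.inf, m.values), axis=0
            )
        else:
            stat = np.nanmean(m.values, axis=0)
    keep = stat > cutoff
    dropped = [f for f, k in zip(m.feature_ids, keep) if not k]
    report = _report(
        "expression_floor", m, dropped, {"cutoff": cutoff, "aggregation": aggregation}
    )
    return m.subset_features(keep), report


def impute_within(m: OmicsMatrix, group_by: str | None = "cohort") -> OmicsMatrix:
    """Replace each missing entry by the mean of that feature's observed values
    within the sample's imputation group.

    With ``group_by='cohort'`` (and cohort labels present) means are computed
    per (modality, cohort) group; otherwise a single global group is used.
    A feature fully missing within a group is a contract breach and raises,
    naming the feature and group.
    """
    if not np.isnan(m.values).any():
        return m
    values = m.values.copy()
    if group_by == "cohort" and m.cohort is not None:
        groups = [(g, np.flatnonzero(m.cohort == g)) for g in dict.fromkeys(m.cohort)]
    else:
        groups = [("all", np.arange(m.n_samples))]
    for gname, rows in groups:
        block = values[rows]
        miss = np.isnan(block)
        if not miss.any():
            continue
        n_obs = (~miss).sum(axis=0)
        bad = np.flatnonzero((n_obs == 0) & miss.any(axis=0))
        if bad.size:
            raise InvalidInputError(
                f"feature {m.feature_ids[bad[0]]!r} is fully missing within "
                f"group {gname!r}; run drop_all_nan_features per group first"
            )
        with np.errstate(invalid="ignore"):
            means = np.nanmean(block, axis=0)
        block[miss] = np.broadcast_to(means, block.shape)[miss]
        values[rows] = block
    return OmicsMatrix(
        sample_ids=list(m.sample_ids),
        feature_ids=list(m.feature_ids),
        values=values,
        modality=m.modality,
        cohort=None if m.cohort is None else m.cohort.copy(),
    )


#: Default per-modality variance thresholds. Bounded (methylation beta) and
#: binary (mutation) modalities use smaller thresholds than the log/z-scale
#: ones: a binary feature's population variance can never exceed 0.25, so the
#: 0.25 default would remove the whole block.
DEFAULT_VARIANCE_THRESHOLDS: Mapping[str, float] = {
    "gene_expression": 0.25,
    "mirna": 0.25,
    "protein": 0.25,
    "dna_methylation": 0.005,
    "mutation": 0.02,
    "clinical": 0.0,
}


@dataclass
class PreprocessConfig:
    """Tunable parameters of the filter cascade."""

    quasi_constant_threshold: float = 0.998
    variance_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_THRESHOLDS)
    )
    expression_floor: float = 7.0
    floor_aggregation: str = "any"
    impute_by_cohort: bool = True

    def variance_threshold_for(self, modality: str) -> float:
        return float(self.variance_thresholds.get(modality, 0.25))


def run_cascade(
    m: OmicsMatrix, config: PreprocessConfig | None = None
) -> tuple[OmicsMatrix, list[FilterReport]]:
    """Apply the full filter cascade in its canonical order and impute.

    Order: all-NaN -> quasi-constant -> duplicates -> variance -> expression
    floor (gene expression only) -> within-group mean imputation. The cascade
    is idempotent: a second pass drops nothing.
    """
    config = config or PreprocessConfig()
    reports: list[FilterReport] = []
    m, r = drop_all_nan_features(m)
    reports.append(r)
    m, r = drop_quasi_constant(m, config.quasi_constant_threshold)
    reports.append(r)
    m, r = drop_duplicate_features(m)
    reports.append(r)
    m, r = variance_filter(m, config.variance_threshold_for(m.modality))
    reports.append(r)
    if m.modality == "gene_expression":
        m, r = expression_floor_filter(
            m, config.expression_floor, config.floor_aggregation
        )
        reports.append(r)
    m = impute_within(m, group_by="cohort" if config.impute_by_cohort else None)
    return m, reports
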