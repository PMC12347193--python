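"""Union-based feature integration within and across modalities.

Within one modality, cohorts (cancer types) keep different feature subsets
after preprocessing; :func:`union_features` forms the sorted union feature
space and :func:`pad_and_align` zero-pads each cohort's matrix onto it,
recording the padded positions in a mask. Across modalities,
:func:`concat_modalities` outer-joins samples on patient id and concatenates
the blocks in a fixed canonical order, again zero-filling (and masking) blocks
a sample lacks. Clinical covariates (age, gender, race, stage) are encoded by
:func:`encode_clinical` into a numeric block of the same kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import MODALITIES, InvalidInputError, OmicsMatrix

__all__ = [
    "FeatureSpace",
    "IntegratedMatrix",
    "ClinicalEncoding",
    "union_features",
    "pad_and_align",
    "encode_clinical",
    "concat_modalities",
]

CLINICAL_COLUMNS = ("age", "gender", "race", "stage")


@dataclass
class FeatureSpace:
    """Sorted union of feature ids for one modality across cohorts."""

    modality: str
    feature_ids: list[str]
    source_cohorts: Mapping[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise InvalidInputError("FeatureSpace feature_ids must be unique")

    @property
    def width(self) -> int:
        return len(self.feature_ids)

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "feature_ids": list(self.feature_ids),
            "source_cohorts": {k: sorted(v) for k, v in self.source_cohorts.items()},
        }


def union_features(
    per_cohort: Sequence[OmicsMatrix],
    cohort_names: Sequence[str] | None = None,
) -> FeatureSpace:
    """Form the sorted union of feature ids over same-modality cohort blocks.

    If every cohort carries an identical feature list, that list is returned
    unchanged (already its own union); otherwise the union is sorted
    lexicographically for a deterministic ordering.
    """
    if not per_cohort:
        raise InvalidInputError("union_features requires at least one matrix")
    modality = per_cohort[0].modality
    if any(m.modality != modality for m in per_cohort):
        raise InvalidInputError("all matrices must share one modality")
    if cohort_names is None:
        cohort_names = [f"cohort_{i}" for i in range(len(per_cohort))]
    lists = [m.feature_ids for m in per_cohort]
    if all(l == lists[0] for l in lists):
        union = list(lists[0])
    else:
        union = sorted(set().union(*map(set, lists)))
    sources: dict[str, set] = {f: set() for f in union}
    for name, m in zip(cohort_names, per_cohort):
        for f in m.feature_ids:
            sources[f].add(name)
    return FeatureSpace(modality=modality, feature_ids=union, source_cohorts=sources)


def pad_and_align(m: OmicsMatrix, space: FeatureSpace) -> OmicsMatrix:
    """Reindex ``m`` onto ``space``, zero-filling absent features.

    Padded entries are exactly 0 and flagged in the returned matrix's
    ``padding_mask``. A feature of ``m`` not present in ``space`` is an error.
    """
    pos = {f: j for j, f in enumerate(space.feature_ids)}
    orphans = [f for f in m.feature_ids if f not in pos]
    if orphans:
        raise InvalidInputError(
            f"feature {orphans[0]!r} of the input matrix is not in the feature space"
        )
    values = np.zeros((m.n_samples, space.width))
    mask = np.ones((m.n_samples, space.width), dtype=bool)
    cols = [pos[f] for f in m.feature_ids]
    values[:, cols] = m.values
    mask[:, cols] = False
    return OmicsMatrix(
        sample_ids=list(m.sample_ids),
        feature_ids=list(space.feature_ids),
        values=values,
        modality=m.modality,
        cohort=None if m.cohort is None else m.cohort.copy(),
        padding_mask=mask,
    )


@dataclass
class ClinicalEncoding:
    """Fitted encoding of the clinical covariates.

    Age is standardized with mean/sd estimated on the fitting subset;
    gender, race and (optionally) stage are one-hot encoded over the
    categories observed in the fitting subset. A category unseen at fit time
    transforms to an all-zero code for that variable.
    """

    age_mean: float
    age_sd: float
    categories: Mapping[str, list[str]]
    include_stage: bool

    @property
    def feature_ids(self) -> list[str]:
        ids = ["age"]
        for var, cats in self.categories.items():
            ids.extend(f"{var}={c}" for c in cats)
        return ids

    def transform(self, table: pd.DataFrame) -> OmicsMatrix:
        _check_clinical_schema(table, self.include_stage)
        cols = [((table["age"].astype(float) - self.age_mean) / self.age_sd).to_numpy()]
        for var, cats in self.categories.items():
            obs = table[var].astype(str).to_numpy()
            for c in cats:
                cols.append((obs == c).astype(float))
        return OmicsMatrix(
            sample_ids=[str(i) for i in table.index],
            feature_ids=self.feature_ids,
            values=np.column_stack(cols),
            modality="clinical",
        )


def _check_clinical_schema(table: pd.DataFrame, include_stage: bool) -> None:
    required = {"age", "gender", "race"} | ({"stage"} if include_stage else set())
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(
            f"clinical table is missing required column(s): {sorted(missing)}"
        )


def encode_clinical(
    table: pd.DataFrame,
    fit_on: Sequence[str] | None = None,
    include_stage: bool = True,
) -> tuple[OmicsMatrix, ClinicalEncoding]:
    """Encode the clinical covariate table into a numeric block.

    ``fit_on`` selects the sample ids (index values) used to estimate the age
    mean/sd and the categorical vocabularies — pass the training samples to
    avoid information leaking from the test set. ``include_stage=False``
    omits every stage-derived column (used for cancer-type classification,
    where stage distribution leaks the label).
    """
    _check_clinical_schema(table, include_stage)
    if fit_on is None:
        fit = table
    else:
        fit_on = [str(i) for i in fit_on]
        if not fit_on:
            raise InvalidInputError("fit_on must be non-empty")
        fit = table.loc[fit_on]
    age = fit["age"].astype(float)
    sd = float(age.std(ddof=0))
    cat_vars = ["gender", "race"] + (["stage"] if include_stage else [])
    encoding = ClinicalEncoding(
        age_mean=float(age.mean()),
        age_sd=sd if sd > 0 else 1.0,
        categories={v: sorted(fit[v].astype(str).unique()) for v in cat_vars},
        include_stage=include_stage,
    )
    return encoding.transform(table), encoding


@dataclass
class IntegratedMatrix:
    """Zero-padded concatenation of modality blocks over the union sample set.

    ``block_offsets`` maps each modality to its ``(start, width)`` slice of the
    concatenated axis, in the canonical block order. ``padding_mask`` marks
    every zero that was introduced by alignment or a missing modality (there
    are no silent zeros: masked entries are exactly 0).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    block_offsets: dict[str, tuple[int, int]]
    padding_mask: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def block_slice(self, modality: str) -> slice:
        start, width = self.block_offsets[modality]
        return slice(start, start + width)

    def zero_blocks(self, modalities: Iterable[str]) -> "IntegratedMatrix":
        """Return a copy with the given modality blocks zeroed and masked.

        This is the modality-ablation hook: zeroing a block through the
        padding mechanism is identical to integrating without that block and
        re-padding.
        """
        values = self.values.copy()
        mask = self.padding_mask.copy()
        for mod in modalities:
            if mod not in self.block_offsets:
                raise InvalidInputError(f"unknown modality block {mod!r}")
            sl = self.block_slice(mod)
            values[:, sl] = 0.0
            mask[:, sl] = True
        return IntegratedMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=list(self.feature_ids),
            values=values,
            block_offsets=dict(self.block_offsets),
            padding_mask=mask,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )


def concat_modalities(blocks: Sequence[OmicsMatrix]) -> IntegratedMatrix:
    """Concatenate per-modality blocks into one wide matrix.

    Samples are outer-joined on patient id: the integrated sample set is the
    union over blocks (ordered by first appearance in canonical block order),
    and a sample absent from a block gets that block zero-filled and masked.
    Blocks are placed in the canonical modality order regardless of the order
    they are passed in.
    """
    if not blocks:
        raise InvalidInputError("concat_modalities requires at least one block")
    by_mod: dict[str, OmicsMatrix] = {}
    for b in blocks:
        if b.modality in by_mod:
            raise InvalidInputError(f"duplicate modality block {b.modality!r}")
        by_mod[b.modality] = b
    ordered = [by_mod[m] for m in MODALITIES if m in by_mod]

    sample_ids: list[str] = []
    seen: set[str] = set()
    for b in ordered:
        for s in b.sample_ids:
            if s not in seen:
                seen.add(s)
                sample_ids.append(s)
    n = len(sample_ids)
    row_of = {s: i for i, s in enumerate(sample_ids)}

    total = sum(b.n_features for b in ordered)
    values = np.zeros((n, total))
    mask = np.ones((n, total), dtype=bool)
    offsets: dict[str, tuple[int, int]] = {}
    feature_ids: list[str] = []
    start = 0
    for b in ordered:
        offsets[b.modality] = (start, b.n_features)
        rows = [row_of[s] for s in b.sample_ids]
        sl = slice(start, start + b.n_features)
        values[rows, sl] = b.values
        if b.padding_mask is not None:
            mask[rows, sl] = b.padding_mask
        else:
            mask[rows, sl] = False
        feature_ids.extend(f"{b.modality}:{f}" for f in b.feature_ids)
        start += b.n_features
    return IntegratedMatrix(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        values=values,
        block_offsets=offsets,
        padding_mask=mask,
    )
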