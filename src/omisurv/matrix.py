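"""Core in-memory containers for per-modality omics matrices.

An :class:`OmicsMatrix` is a dense samples-by-features block from one molecular
modality (gene expression, DNA methylation, miRNA, protein, mutation, or an
encoded clinical table). Missing entries are stored as ``NaN``; every observed
entry must be finite. The container deliberately stays close to a labelled
NumPy array: the preprocessing cascade and union integration are defined on
columns, and keeping a plain ``float64`` array makes those filters exact and
fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical modality names, in the block order used for integration.
MODALITIES = (
    "gene_expression",
    "dna_methylation",
    "mirna",
    "protein",
    "mutation",
    "clinical",
)


class OmisurvError(Exception):
    """Base class for errors raised by omisurv."""


class InvalidInputError(OmisurvError, ValueError):
    """An operation received input that violates its preconditions."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise InvalidInputError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclass
class OmicsMatrix:
    """One modality's samples-by-features numeric matrix.

    Parameters
    ----------
    sample_ids
        Ordered unique sample (patient) identifiers, length ``n``.
    feature_ids
        Ordered unique feature names within the modality, length ``p``.
    values
        ``(n, p)`` float array; ``NaN`` marks a missing entry.
    modality
        One of :data:`MODALITIES`.
    cohort
        Optional per-sample cohort / cancer-type label, length ``n``.
    padding_mask
        Optional boolean ``(n, p)`` array marking entries that were
        zero-padded during union alignment (set by ``integrate.pad_and_align``).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    modality: str
    cohort: np.ndarray | None = None
    padding_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        if self.modality not in MODALITIES:
            raise InvalidInputError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise InvalidInputError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if np.isinf(self.values).any():
            raise InvalidInputError("non-finite (inf) entries are not allowed")
        if self.cohort is not None:
            self.cohort = np.asarray(self.cohort, dtype=object)
            if self.cohort.shape != (len(self.sample_ids),):
                raise InvalidInputError("cohort labels must align with sample_ids")
        if self.padding_mask is not None:
            self.padding_mask = np.asarray(self.padding_mask, dtype=bool)
            if self.padding_mask.shape != self.values.shape:
                raise InvalidInputError("padding_mask shape must match values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing (NaN) entries."""
        return np.isnan(self.values)

    def subset_features(self, keep: np.ndarray) -> "OmicsMatrix":
        """Return a copy restricted to the column indices/boolean mask ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return OmicsMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[j] for j in keep],
            values=self.values[:, keep].copy(),
            modality=self.modality,
            cohort=None if self.cohort is None else self.cohort.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        modality: str,
        cohort: Sequence[str] | None = None,
    ) -> "OmicsMatrix":
        return cls(
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=np.float64),
            modality=modality,
            cohort=None if cohort is None else np.asarray(cohort, dtype=object),
        )


@dataclass
class FilterReport:
    """Audit record for one preprocessing stage.

    ``features_out == features_in - len(dropped_ids)`` always holds; reports
    compose in cascade order so the full run is reconstructible from the list.
    """

    stage_name: str
    features_in: int
    features_out: int
    dropped_ids: list[str]
    parameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features_out != self.features_in - len(self.dropped_ids):
            raise InvalidInputError(
                f"inconsistent FilterReport for {self.stage_name!r}: "
                f"{self.features_in} - {len(self.dropped_ids)} != {self.features_out}"
            )

    def to_dict(self) -> dict:
        return {
            "stage_name": self.stage_name,
            "features_in": self.features_in,
            "features_out": self.features_out,
            "dropped_ids": list(self.dropped_ids),
            "parameters": dict(self.parameters),
        }
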