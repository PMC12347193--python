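"""File readers/writers and checkpoint (de)serialization.

Matrices travel as TSV/CSV with a header row of feature ids and a first
column of sample ids; missing entries are an empty field or ``NA``. Survival
records are a three-column table (sample_id, time_days, event). Checkpoints
are a JSON config (with a content hash) plus an ``.npz`` parameter container;
loading verifies the hash and shapes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import FilterReport, InvalidInputError, OmicsMatrix, OmisurvError
from .nn import Backbone, Model, SNNConfig
from .survival import SurvivalData

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_survival",
    "write_survival",
    "save_checkpoint",
    "load_checkpoint",
    "write_filter_reports",
    "CheckpointError",
]


class CheckpointError(OmisurvError):
    """A checkpoint file is corrupt or incompatible with the requested model."""


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    modality: str,
    sep: str | None = None,
) -> OmicsMatrix:
    """Parse a samples-by-features TSV/CSV into an :class:`OmicsMatrix`.

    The delimiter follows the file extension (``.csv`` -> comma, otherwise
    tab) unless given explicitly. ``NA`` / empty fields become missing
    entries; duplicate ids or non-numeric cells raise with context.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path, sep))
    header_feats = header[1:]
    if len(set(header_feats)) != len(header_feats):
        dup = next(
            f for i, f in enumerate(header_feats) if f in header_feats[:i]
        )
        raise InvalidInputError(f"{path}: duplicated feature id {dup!r}")
    df = pd.read_csv(
        path,
        sep=_sep_for(path, sep),
        index_col=0,
        na_values=["NA"],
        keep_default_na=True,
    )
    ids = [str(i) for i in df.index]
    feats = [str(c) for c in df.columns]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).loc[pd.Series(ids).duplicated()].iloc[0]
        raise InvalidInputError(f"{path}: duplicated sample id {dup!r}")
    if len(set(feats)) != len(feats):
        dup = pd.Series(feats).loc[pd.Series(feats).duplicated()].iloc[0]
        raise InvalidInputError(f"{path}: duplicated feature id {dup!r}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        for line_no, (_, row) in enumerate(df.iterrows(), start=2):
            if pd.to_numeric(row, errors="coerce").isna().sum() != row.isna().sum():
                raise InvalidInputError(
                    f"{path}: non-numeric value on line {line_no}"
                ) from exc
        raise InvalidInputError(f"{path}: non-numeric values") from exc
    return OmicsMatrix(
        sample_ids=ids, feature_ids=feats, values=values, modality=modality
    )


def write_matrix(m: OmicsMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    df = m.to_dataframe()
    df.to_csv(path, sep=_sep_for(path, sep), na_rep="NA", index_label="sample_id")


def read_survival(path: str | Path, sep: str | None = None) -> SurvivalData:
    """Parse survival records with columns sample_id, time_days, event."""
    path = Path(path)
    required = {"sample_id", "time_days", "event"}
    try:
        df = pd.read_csv(path, sep=_sep_for(path, sep))
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty and required - set(df.columns):
        import warnings

        warnings.warn(f"{path}: empty survival file", stacklevel=2)
        return SurvivalData(np.empty(0), np.empty(0, dtype=int), [])
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {sorted(missing)}")
    time = pd.to_numeric(df["time_days"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    bad_time = df.index[time.isna() | (time <= 0)].tolist()
    bad_event = df.index[~event.isin([0, 1])].tolist()
    if bad_time or bad_event:
        raise InvalidInputError(
            f"{path}: invalid rows — non-positive/missing time at "
            f"{bad_time[:5]}, non-binary event at {bad_event[:5]} "
            "(0-based data rows)"
        )
    return SurvivalData(
        time.to_numpy(),
        event.to_numpy(dtype=int),
        [str(s) for s in df["sample_id"]],
    )


def write_survival(data: SurvivalData, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    ids = data.sample_ids or [f"S{i}" for i in range(len(data))]
    pd.DataFrame(
        {"sample_id": ids, "time_days": data.time, "event": data.event}
    ).to_csv(path, sep=_sep_for(path, sep), index=False)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def save_checkpoint(model: Model, path: str | Path) -> None:
    """Write a model as ``<path>.json`` (config + hash) and ``<path>.npz``."""
    path = Path(path)
    state = model.state_dict()
    meta = {
        "config": state["config"],
        "kind": state["kind"],
        "n_classes": state["n_classes"],
        "n_params": len(state["params"]),
    }
    meta["hash"] = _config_hash(meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(
        path.with_suffix(".npz"),
        **{f"p{i}": p for i, p in enumerate(state["params"])},
    )


def load_checkpoint(path: str | Path, into: Model | None = None) -> Model:
    """Reconstruct a model; verifies the config hash and parameter shapes.

    With ``into`` given, the stored parameters are loaded into that model
    instead; an architecture mismatch (e.g. different input_dim) raises."""
    path = Path(path)
    try:
        meta = json.loads(path.with_suffix(".json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"cannot read checkpoint metadata: {exc}") from exc
    stored_hash = meta.pop("hash", None)
    if stored_hash != _config_hash(meta):
        raise CheckpointError(f"{path}: config hash mismatch (corrupt checkpoint?)")
    import zipfile

    try:
        with np.load(path.with_suffix(".npz")) as npz:
            params = [npz[f"p{i}"] for i in range(meta["n_params"])]
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as exc:
        raise CheckpointError(f"{path}: corrupt parameter container: {exc}") from exc
    if into is not None:
        if into.backbone.config.to_dict() != meta["config"]:
            raise CheckpointError(
                "checkpoint architecture does not match the target model "
                f"(stored input_dim {meta['config']['input_dim']}, "
                f"target {into.backbone.config.input_dim})"
            )
        model = into
    else:
        config = SNNConfig(**meta["config"])
        model = Model(Backbone(config), meta["kind"], meta["n_classes"])
    try:
        model.load_params(params)
    except InvalidInputError as exc:
        raise CheckpointError(str(exc)) from exc
    return model


def write_filter_reports(reports: list[FilterReport], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in reports], indent=2, default=str)
    )
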