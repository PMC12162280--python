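"""Clinical cohort data model: schemas, label coding, preprocessing, CSV I/O.

A :class:`Cohort` couples a raw feature table (continuous laboratory values and
categorical covariates) with a ±1 outcome label (+1 = relapse within 3 years).
A :class:`Preprocessor` learns train-fold statistics (z-scoring for continuous
columns, reference-level one-hot expansion for categorical columns) and applies
them unchanged to validation/test folds, so no information leaks across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LABEL_COLUMN = "label"


class SchemaError(ValueError):
    """A column required by the schema is missing or malformed."""


class ValidationError(ValueError):
    """Cell-level validation failure (unknown category, missing value, bad label)."""


@dataclass(frozen=True)
class ColumnSpec:
    """Descriptor for one raw column.

    For categorical columns ``categories`` lists the admissible levels with the
    designated reference level first; the reference level encodes to an all-zero
    one-hot block, matching regression coding with a dropped reference.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.categories) < 2:
            raise SchemaError(f"categorical column {self.name!r} needs >= 2 levels")
        if self.kind == "continuous" and self.categories:
            raise SchemaError(f"continuous column {self.name!r} must not list categories")

    @property
    def reference(self) -> str:
        return self.categories[0]

    @property
    def encoded_names(self) -> list[str]:
        if self.kind == "continuous":
            return [self.name]
        return [f"{self.name}={lvl}" for lvl in self.categories[1:]]


Schema = tuple[ColumnSpec, ...]


def bcs_schema() -> Schema:
    """The Budd-Chiari study variable set.

    Reference levels follow the clinical convention used in the study design:
    age ≤50, occupation "others", inferior-vena-cava obstruction type, and
    simple balloon dilation as the index intervention.  Age enters dichotomized
    at 50 years by default; a continuous-age schema can be built manually.
    """
    return (
        ColumnSpec("age_group", "categorical", ("<=50", ">50")),
        ColumnSpec("occupation", "categorical", ("others", "farmer_or_worker")),
        ColumnSpec("bcs_type", "categorical", ("inferior_vena_cava", "hepatic_vein", "mixed")),
        ColumnSpec(
            "intervention",
            "categorical",
            ("balloon_dilation", "stent_implantation", "catheter_thrombolysis", "tips"),
        ),
        ColumnSpec("NEU", "continuous"),
        ColumnSpec("PLT", "continuous"),
        ColumnSpec("PT", "continuous"),
        ColumnSpec("ALB", "continuous"),
        ColumnSpec("GLU", "continuous"),
        ColumnSpec("AFP", "continuous"),
    )


def load_schema(path) -> Schema:
    """Load a schema from YAML: a list of {name, kind, categories} mappings."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    return tuple(
        ColumnSpec(e["name"], e["kind"], tuple(e.get("categories") or ())) for e in entries
    )


def packaged_schema_path():
    """Path of the shipped example schema reproducing the study variable set."""
    from importlib.resources import files

    return files("mksvrb").joinpath("data/bcs_schema.yaml")


def encoded_width(schema: Schema) -> int:
    """Width of the encoded design: continuous columns + (levels − 1) per categorical."""
    return sum(1 if c.kind == "continuous" else len(c.categories) - 1 for c in schema)


@dataclass
class Cohort:
    """A clinical feature table plus ±1 outcome labels.

    ``frame`` holds raw (un-encoded) columns in schema order; ``labels`` is an
    integer vector in {−1, +1} with +1 meaning relapse within 3 years.
    """

    frame: pd.DataFrame
    labels: np.ndarray
    schema: Schema

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.frame):
            raise ValidationError("labels must be a vector aligned to the feature table")
        bad = ~np.isin(self.labels, (-1, 1))
        if bad.any():
            raise ValidationError(
                f"labels must be -1/+1; offending row index {int(np.flatnonzero(bad)[0])}"
            )
        _validate_frame(self.frame, self.schema)

    @property
    def n(self) -> int:
        return len(self.frame)

    def subset(self, indices: Iterable[int]) -> "Cohort":
        idx = np.asarray(list(indices), dtype=int)
        return Cohort(self.frame.iloc[idx].reset_index(drop=True), self.labels[idx], self.schema)


def _validate_frame(frame: pd.DataFrame, schema: Schema) -> None:
    for col in schema:
        if col.name not in frame.columns:
            raise SchemaError(f"missing required column {col.name!r}")
        series = frame[col.name]
        if series.isna().any():
            row = int(series.index[series.isna()][0])
            raise ValidationError(f"missing value in column {col.name!r} at row {row}")
        if col.kind == "categorical":
            values = series.astype(str)
            known = set(col.categories)
            bad = ~values.isin(known)
            if bad.any():
                row = int(values.index[bad][0])
                raise ValidationError(
                    f"unknown category {values.iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r} "
                    f"in column {col.name!r} at row {row}"
                )
        else:
            if not np.issubdtype(series.dtype, np.number):
                try:
                    frame[col.name] = series.astype(float)
                except (TypeError, ValueError) as exc:
                    raise ValidationError(
                        f"non-numeric value in continuous column {col.name!r}"
                    ) from exc


def _coerce_labels(raw: pd.Series) -> np.ndarray:
    """Accept {0,1} or {−1,+1}; canonical internal coding is {−1,+1}."""
    values = raw.to_numpy()
    out = np.empty(len(values), dtype=int)
    for i, v in enumerate(values):
        try:
            iv = int(float(v))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric label {v!r} at row {i}") from exc
        if float(v) != iv or iv not in (-1, 0, 1):
            raise ValidationError(f"label {v!r} at row {i} not in {{0,1}} or {{-1,+1}}")
        out[i] = iv
    has0 = (out == 0).any()
    hasm1 = (out == -1).any()
    if has0 and hasm1:
        raise ValidationError("label column mixes 0/1 and -1/+1 codings")
    if has0:
        out = np.where(out == 0, -1, 1)
    return out


def read_cohort_csv(path, schema: Schema) -> Cohort:
    """Read a cohort CSV (comma-separated, UTF-8, header row, '.' decimals).

    Expects one row per patient with all schema columns plus a ``label``
    column coded {0,1} or {−1,+1}.
    """
    frame = pd.read_csv(path, encoding="utf-8")
    if LABEL_COLUMN not in frame.columns:
        raise SchemaError(f"missing required column {LABEL_COLUMN!r}")
    labels = _coerce_labels(frame[LABEL_COLUMN])
    features = frame[[c.name for c in schema if c.name in frame.columns]].copy()
    for col in schema:
        if col.name not in frame.columns:
            raise SchemaError(f"missing required column {col.name!r}")
        if col.kind == "categorical":
            features[col.name] = features[col.name].astype(str)
    return Cohort(features.reset_index(drop=True), labels, schema)


def write_cohort_csv(cohort: Cohort, path) -> None:
    out = cohort.frame.copy()
    out[LABEL_COLUMN] = cohort.labels
    out.to_csv(path, index=False, encoding="utf-8")


@dataclass
class Preprocessor:
    """Train-fold feature encoder: z-scoring plus reference-drop one-hot.

    Continuous columns are centred and scaled with training-fold mean and
    sample standard deviation (denominator n−1).  Parameters are frozen at fit
    time; transforming any other fold reuses them unchanged.
    """

    schema: Schema
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    fitted: bool = False

    def fit(self, cohort: Cohort, train_indices: Sequence[int]) -> "Preprocessor":
        idx = np.asarray(list(train_indices), dtype=int)
        if idx.size == 0:
            raise ValidationError("train_indices must be non-empty")
        for col in self.schema:
            if col.kind != "continuous":
                continue
            vals = cohort.frame[col.name].to_numpy(dtype=float)[idx]
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            if sd == 0.0:
                raise ValidationError(
                    f"continuous column {col.name!r} has zero variance on the training fold"
                )
            self.means[col.name] = float(np.mean(vals))
            self.sds[col.name] = sd
        self.fitted = True
        return self

    @property
    def encoded_columns(self) -> list[str]:
        names: list[str] = []
        for col in self.schema:
            names.extend(col.encoded_names)
        return names

    def column_blocks(self) -> dict[str, slice]:
        """Map each schema column to its slice of encoded columns."""
        blocks: dict[str, slice] = {}
        start = 0
        for col in self.schema:
            width = len(col.encoded_names)
            blocks[col.name] = slice(start, start + width)
            start += width
        return blocks

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise ValidationError("preprocessor not fitted")
        _validate_frame(frame, self.schema)
        parts: list[np.ndarray] = []
        for col in self.schema:
            if col.kind == "continuous":
                vals = frame[col.name].to_numpy(dtype=float)
                parts.append(((vals - self.means[col.name]) / self.sds[col.name])[:, None])
            else:
                vals = frame[col.name].astype(str).to_numpy()
                block = np.zeros((len(frame), len(col.categories) - 1))
                for j, lvl in enumerate(col.categories[1:]):
                    block[:, j] = vals == lvl
                parts.append(block)
        return np.hstack(parts) if parts else np.zeros((len(frame), 0))


def fit_preprocessor(cohort: Cohort, train_indices: Sequence[int]) -> Preprocessor:
    """Learn z-scoring statistics and one-hot maps on the training fold."""
    return Preprocessor(schema=cohort.schema).fit(cohort, train_indices)
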