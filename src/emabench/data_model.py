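"""Core domain types for long-format EMA assessment tables.

An ecological momentary assessment (EMA) study yields a long table in which
every row is one completed questionnaire (an *assessment*) of one user at one
point in time.  All downstream machinery — instance construction, splitting,
heuristics, evaluation — consumes the :class:`EMADataset` container defined
here, which wraps a :class:`pandas.DataFrame` together with a feature schema
and a target specification.

The minimal information a dataset must carry is an assessment id, a user id,
a timestamp, one or more feature columns, and a target column.  Missing
answers are represented as NaN in memory and as empty cells on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KIND_NUMERIC",
    "KIND_CATEGORICAL",
    "KIND_BOOLEAN",
    "ID_COL",
    "USER_COL",
    "TIME_COL",
    "TARGET_COL",
    "SchemaError",
    "ValidationError",
    "FeatureSpec",
    "FeatureSchema",
    "TargetSpec",
    "Assessment",
    "EMADataset",
    "DatasetSummary",
    "read_dataset",
    "write_dataset",
    "summarize",
]

KIND_NUMERIC = "numeric"
KIND_CATEGORICAL = "categorical"
KIND_BOOLEAN = "boolean"
_KINDS = (KIND_NUMERIC, KIND_CATEGORICAL, KIND_BOOLEAN)

# canonical internal column names
ID_COL = "assessment_id"
USER_COL = "user_id"
TIME_COL = "timestamp"
TARGET_COL = "target_raw"

RAW_CONTINUOUS = "continuous_0_1"
RAW_ORDINAL = "ordinal"


class SchemaError(ValueError):
    """A configuration / schema problem (wrong columns, unknown kinds...)."""


class ValidationError(ValueError):
    """A dataset invariant violation (duplicate ids, out-of-range target...)."""


@dataclass(frozen=True)
class FeatureSpec:
    """One feature column: its name, kind and (for categoricals) level set."""

    name: str
    kind: str = KIND_NUMERIC
    categories: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` with unique names."""

    features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        if not names:
            raise SchemaError("a feature schema needs at least one feature")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def kind_of(self, name: str) -> str:
        for f in self.features:
            if f.name == name:
                return f.kind
        raise SchemaError(f"unknown feature {name!r}")

    @property
    def numeric_names(self) -> list[str]:
        return [f.name for f in self.features if f.kind == KIND_NUMERIC]

    @property
    def non_numeric_names(self) -> list[str]:
        return [f.name for f in self.features if f.kind != KIND_NUMERIC]

    @classmethod
    def from_kinds(cls, kinds: Mapping[str, str]) -> "FeatureSchema":
        return cls(tuple(FeatureSpec(n, k) for n, k in kinds.items()))


@dataclass(frozen=True)
class TargetSpec:
    """What the target column contains and how many ordinal classes it bins to.

    ``raw_kind`` is ``continuous_0_1`` for targets recorded on a [0, 1]
    visual-analogue-type scale (binned downstream into ``n_classes`` ordinal
    classes) or ``ordinal`` for natively discrete targets in
    ``{0..n_classes-1}`` which bypass binning.
    """

    name: str = "target"
    raw_kind: str = RAW_CONTINUOUS
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.raw_kind not in (RAW_CONTINUOUS, RAW_ORDINAL):
            raise SchemaError(f"unknown target raw_kind {self.raw_kind!r}")
        if self.n_classes < 2:
            raise SchemaError("n_classes must be >= 2")


@dataclass(frozen=True)
class Assessment:
    """One completed questionnaire (one row of the long table)."""

    assessment_id: str
    user_id: str
    timestamp: pd.Timestamp
    answers: dict
    target_raw: float


class EMADataset:
    """Long-format EMA dataset: one row per assessment.

    The backing frame holds the canonical columns ``assessment_id``,
    ``user_id``, ``timestamp`` (tz-aware UTC), ``target_raw`` and one column
    per schema feature.  Rows are kept in a canonical order — by user, then
    timestamp, then assessment id (the deterministic tie-break every causal
    operation downstream relies on).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        schema: FeatureSchema,
        target_spec: TargetSpec,
        dataset_label: str = "dataset",
    ) -> None:
        required = [ID_COL, USER_COL, TIME_COL, TARGET_COL]
        for col in required:
            if col not in frame.columns:
                raise SchemaError(f"missing required column {col!r}")
        for name in schema.names:
            if name not in frame.columns:
                raise SchemaError(f"missing feature column {name!r}")
        frame = frame[required + schema.names].copy()
        if frame.empty:
            raise ValidationError("dataset has no assessments")
        if frame[ID_COL].duplicated().any():
            dupes = frame.loc[frame[ID_COL].duplicated(), ID_COL].iloc[0]
            raise ValidationError(f"duplicate assessment_id {dupes!r}")
        ts = pd.to_datetime(frame[TIME_COL], utc=True)
        if ts.isna().any():
            raise ValidationError("every assessment needs a parseable timestamp")
        frame[TIME_COL] = ts
        frame[ID_COL] = frame[ID_COL].astype(str)
        frame[USER_COL] = frame[USER_COL].astype(str)
        tgt = pd.to_numeric(frame[TARGET_COL], errors="coerce")
        if tgt.isna().all():
            raise ValidationError("target column contains no values")
        if target_spec.raw_kind == RAW_CONTINUOUS:
            bad = tgt.dropna()
            if ((bad < 0) | (bad > 1)).any():
                raise ValidationError("continuous target values must lie in [0, 1]")
        else:
            bad = tgt.dropna()
            if ((bad < 0) | (bad > target_spec.n_classes - 1) | (bad % 1 != 0)).any():
                raise ValidationError("ordinal target values must be integers in class range")
        frame[TARGET_COL] = tgt
        for name in schema.numeric_names:
            frame[name] = pd.to_numeric(frame[name], errors="coerce")
        for name in schema.non_numeric_names:
            col = frame[name]
            frame[name] = col.where(col.isna(), col.astype(str))
        frame = frame.sort_values([USER_COL, TIME_COL, ID_COL], kind="mergesort")
        self._frame = frame.reset_index(drop=True)
        self.schema = schema
        self.target_spec = target_spec
        self.dataset_label = dataset_label

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The backing frame in canonical row order (treat as read-only)."""
        return self._frame

    @property
    def feature_cols(self) -> list[str]:
        return self.schema.names

    @property
    def n_users(self) -> int:
        return self._frame[USER_COL].nunique()

    @property
    def n_assessments(self) -> int:
        return len(self._frame)

    def signup_times(self) -> pd.Series:
        """First assessment timestamp per user (the sign-up proxy)."""
        return self._frame.groupby(USER_COL, sort=True)[TIME_COL].min()

    def users_by_signup(self) -> list[str]:
        """Users ordered by sign-up time, ties broken by user id."""
        s = self.signup_times().reset_index()
        s = s.sort_values([TIME_COL, USER_COL], kind="mergesort")
        return s[USER_COL].tolist()

    def assessments(self) -> Iterator[Assessment]:
        feats = self.schema.names
        for row in self._frame.itertuples(index=False):
            d = row._asdict()
            yield Assessment(
                assessment_id=d[ID_COL],
                user_id=d[USER_COL],
                timestamp=d[TIME_COL],
                answers={f: d[f] for f in feats},
                target_raw=d[TARGET_COL],
            )

    def replace_frame(self, frame: pd.DataFrame) -> "EMADataset":
        return EMADataset(frame, self.schema, self.target_spec, self.dataset_label)

    def equals(self, other: "EMADataset") -> bool:
        if self.schema != other.schema or self.target_spec != other.target_spec:
            return False
        try:
            pd.testing.assert_frame_equal(self._frame, other._frame)
        except AssertionError:
            return False
        return True

    def to_schema_config(self) -> dict:
        """A read_dataset schema_config that round-trips this dataset."""
        return {
            "id_col": ID_COL,
            "user_col": USER_COL,
            "time_col": TIME_COL,
            "target_col": TARGET_COL,
            "feature_cols": self.schema.names,
            "feature_kinds": {f.name: f.kind for f in self.schema.features},
            "target_name": self.target_spec.name,
            "target_raw_kind": self.target_spec.raw_kind,
            "n_classes": self.target_spec.n_classes,
            "dataset_label": self.dataset_label,
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EMADataset({self.dataset_label!r}, users={self.n_users}, "
            f"assessments={self.n_assessments}, features={len(self.schema.names)})"
        )


@dataclass(frozen=True)
class DatasetSummary:
    """Table-style per-dataset descriptives.

    ``median_gap_hours`` is the median over consecutive within-user timestamp
    deltas (cross-user deltas never contribute); it is NaN when no user has
    two or more assessments.
    """

    n_users: int
    n_assessments: int
    span_years: float
    median_gap_hours: float

    @property
    def has_gap(self) -> bool:
        return not math.isnan(self.median_gap_hours)


def _within_user_gaps_hours(dataset: EMADataset) -> np.ndarray:
    f = dataset.frame
    deltas = f.groupby(USER_COL)[TIME_COL].diff().dropna()
    return deltas.dt.total_seconds().to_numpy() / 3600.0


def summarize(dataset: EMADataset, per_user: bool = False) -> DatasetSummary:
    """Compute per-dataset descriptives.

    With ``per_user=True`` the gap statistic is the median of per-user median
    gaps instead of the pooled median over all within-user gaps (default).
    """
    f = dataset.frame
    span = (f[TIME_COL].max() - f[TIME_COL].min()).total_seconds() / (365.25 * 24 * 3600)
    if per_user:
        deltas = f.groupby(USER_COL)[TIME_COL].diff().dt.total_seconds() / 3600.0
        med = f.assign(_gap=deltas).groupby(USER_COL)["_gap"].median().dropna()
        gap = float(med.median()) if len(med) else float("nan")
    else:
        gaps = _within_user_gaps_hours(dataset)
        gap = float(np.median(gaps)) if gaps.size else float("nan")
    return DatasetSummary(
        n_users=dataset.n_users,
        n_assessments=dataset.n_assessments,
        span_years=float(span),
        median_gap_hours=gap,
    )


# -- I/O -------------------------------------------------------------------


def read_dataset(path, schema_config: Mapping) -> EMADataset:
    """Read a long-format assessment CSV into an :class:`EMADataset`.

    ``schema_config`` maps column roles; required keys: ``id_col``,
    ``user_col``, ``time_col``, ``target_col``, ``feature_cols``.  Optional:
    ``feature_kinds`` (name → numeric/categorical/boolean, default numeric),
    ``target_raw_kind``, ``n_classes``, ``target_name``, ``dataset_label``.
    Rows whose timestamp cannot be parsed are dropped.
    """
    for key in ("id_col", "user_col", "time_col", "target_col", "feature_cols"):
        if key not in schema_config:
            raise SchemaError(f"schema_config is missing key {key!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    cols = {
        "id_col": schema_config["id_col"],
        "user_col": schema_config["user_col"],
        "time_col": schema_config["time_col"],
        "target_col": schema_config["target_col"],
    }
    for role, col in cols.items():
        if col not in raw.columns:
            raise SchemaError(f"CSV is missing the {role} column {col!r}")
    feature_cols: Sequence[str] = schema_config["feature_cols"]
    for col in feature_cols:
        if col not in raw.columns:
            raise SchemaError(f"CSV is missing the feature column {col!r}")
    kinds = dict(schema_config.get("feature_kinds", {}))
    schema = FeatureSchema(
        tuple(FeatureSpec(c, kinds.get(c, KIND_NUMERIC)) for c in feature_cols)
    )
    target_spec = TargetSpec(
        name=schema_config.get("target_name", "target"),
        raw_kind=schema_config.get("target_raw_kind", RAW_CONTINUOUS),
        n_classes=int(schema_config.get("n_classes", 5)),
    )
    frame = raw.rename(
        columns={
            cols["id_col"]: ID_COL,
            cols["user_col"]: USER_COL,
            cols["time_col"]: TIME_COL,
            cols["target_col"]: TARGET_COL,
        }
    )
    ts = pd.to_datetime(frame[TIME_COL], utc=True, errors="coerce", format="ISO8601")
    frame = frame.loc[ts.notna()].copy()
    frame[TIME_COL] = ts.loc[ts.notna()]
    if frame.empty:
        raise ValidationError("no rows with parseable timestamps")
    return EMADataset(
        frame,
        schema,
        target_spec,
        dataset_label=str(schema_config.get("dataset_label", "dataset")),
    )


def write_dataset(dataset: EMADataset, path) -> None:
    """Write an :class:`EMADataset` to CSV (UTF-8, ISO-8601 UTC timestamps).

    Missing answers become empty cells.  ``read_dataset`` with
    ``dataset.to_schema_config()`` reproduces the dataset exactly.
    """
    out = dataset.frame.copy()
    out[TIME_COL] = out[TIME_COL].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False, encoding="utf-8")
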