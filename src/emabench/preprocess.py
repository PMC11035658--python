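"""Harmonize a dataset into supervised prediction instances.

The prediction task: given the answers of a user's assessment at ``t_now``,
predict the ordinal target class of the same user's next assessment at
``t_next``.  Continuous [0, 1] targets are binned into ``n_classes`` ordinal
classes (default 5, step 0.2); natively ordinal targets bypass binning.
Missing answers are imputed user-wise (mean for numeric features, mode for
categorical/boolean) with a dataset-wide fallback for single-assessment
users.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ID_COL,
    KIND_NUMERIC,
    RAW_CONTINUOUS,
    TARGET_COL,
    TIME_COL,
    USER_COL,
    EMADataset,
    SchemaError,
    ValidationError,
)

__all__ = [
    "PredictionInstance",
    "INSTANCE_ID",
    "T_NOW",
    "T_NEXT",
    "TARGET_CLASS",
    "TARGET_AT_T_NOW",
    "bin_target",
    "impute_missing",
    "LabelCodec",
    "encode_labels",
    "build_instances",
]

# instance-frame column names
INSTANCE_ID = "instance_id"
T_NOW = "t_now"
T_NEXT = "t_next"
TARGET_CLASS = "target_class"
TARGET_AT_T_NOW = "target_at_t_now"


@dataclass(frozen=True)
class PredictionInstance:
    """One (features at t_now → target class at t_next) pair for one user."""

    instance_id: str
    user_id: str
    t_now: pd.Timestamp
    t_next: pd.Timestamp
    features: dict
    target_class: int
    target_at_t_now: int


def bin_target(value: float, n_bins: int = 5) -> int:
    """Bin a [0, 1] value into ``n_bins`` ordinal classes.

    Intervals are half-open, [k/n, (k+1)/n), with the final interval closed
    at 1.0, so the class count is exactly ``n_bins`` with no empty top bin.
    """
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"target value {value} outside [0, 1]")
    return min(int(value * n_bins), n_bins - 1)


def _mode_smallest(values: pd.Series):
    """Most common value; ties broken toward the smallest (sorted order)."""
    counts = values.value_counts()
    top = counts[counts == counts.iloc[0]].index
    return sorted(top)[0]


def impute_missing(dataset: EMADataset) -> EMADataset:
    """User-wise imputation of missing answers.

    A user's missing answer for a feature is filled with the mean (numeric)
    or mode (categorical/boolean) of that user's other answers for the
    feature; users with no other answer fall back to the dataset-wide
    mean/mode.  A feature missing for every assessment has no fallback and
    raises :class:`ValidationError`.  Non-missing answers are never altered.
    """
    frame = dataset.frame.copy()
    for name in dataset.schema.names:
        col = frame[name]
        if col.isna().all():
            raise ValidationError(f"feature {name!r} is missing for every assessment")
        numeric = dataset.schema.kind_of(name) == KIND_NUMERIC
        if numeric:
            global_fill = col.mean()
            per_user = frame.groupby(USER_COL)[name].transform("mean")
        else:
            global_fill = _mode_smallest(col.dropna())
            per_user = frame.groupby(USER_COL)[name].transform(
                lambda s: _mode_smallest(s.dropna()) if s.notna().any() else np.nan
            )
        filled = col.fillna(per_user)
        frame[name] = filled.fillna(global_fill)
    return dataset.replace_frame(frame)


@dataclass(frozen=True)
class LabelCodec:
    """Stable, order-preserving mapping between class indices and labels."""

    labels: tuple[str, ...]

    def encode(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown label {label!r}") from None

    def decode(self, cls: int) -> str:
        if not (0 <= cls < len(self.labels)):
            raise ValidationError(f"class {cls} outside label set")
        return self.labels[cls]


def encode_labels(dataset: EMADataset, labels: Sequence[str] | None = None) -> LabelCodec:
    """Create the class ↔ label mapping for a dataset's target.

    Defaults to string digits "0".."n-1"; a custom label list must match the
    class count.
    """
    n = dataset.target_spec.n_classes
    if labels is None:
        labels = [str(c) for c in range(n)]
    if len(labels) != n:
        raise SchemaError(f"expected {n} labels, got {len(labels)}")
    return LabelCodec(tuple(str(x) for x in labels))


def _binned_targets(dataset: EMADataset) -> np.ndarray:
    tgt = dataset.frame[TARGET_COL].to_numpy()
    if dataset.target_spec.raw_kind == RAW_CONTINUOUS:
        n = dataset.target_spec.n_classes
        return np.array([bin_target(float(v), n) for v in tgt], dtype=int)
    return tgt.astype(int)


def build_instances(dataset: EMADataset, same_time: bool = False) -> pd.DataFrame:
    """Build the instance table from consecutive within-user assessment pairs.

    Per user, assessments are time-sorted (ties by assessment id) and every
    adjacent pair (i, i+1) yields one instance: features from assessment i,
    target class from assessment i+1.  Users with a single assessment yield
    no instance.  With ``same_time=True`` the target is instead the class of
    the t_now assessment itself (the "predict the current state" variant).

    Returns a frame with columns ``instance_id`` (the t_now assessment id),
    ``user_id``, ``t_now``, ``t_next``, the feature columns, ``target_class``
    and ``target_at_t_now``.
    """
    if dataset.frame[dataset.schema.names].isna().any().any():
        raise ValidationError("dataset must be imputed before instance construction")
    f = dataset.frame
    classes = _binned_targets(dataset)
    grp = f[USER_COL].to_numpy()
    # canonical order is (user, time, id); within-user shift is positional
    same_user_next = np.roll(grp, -1) == grp
    same_user_next[-1] = False
    now_idx = np.flatnonzero(same_user_next)
    next_idx = now_idx + 1
    inst = pd.DataFrame(
        {
            INSTANCE_ID: f[ID_COL].to_numpy()[now_idx],
            USER_COL: grp[now_idx],
            T_NOW: f[TIME_COL].to_numpy()[now_idx],
            T_NEXT: f[TIME_COL].to_numpy()[next_idx],
        }
    )
    for name in dataset.schema.names:
        inst[name] = f[name].to_numpy()[now_idx]
    inst[TARGET_CLASS] = classes[now_idx if same_time else next_idx]
    inst[TARGET_AT_T_NOW] = classes[now_idx]
    inst[T_NOW] = pd.to_datetime(inst[T_NOW], utc=True)
    inst[T_NEXT] = pd.to_datetime(inst[T_NEXT], utc=True)
    return inst.reset_index(drop=True)
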