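"""Outer train/test split and the four internal fold-plan approaches.

The outer split orders users by sign-up time (or a seeded random
permutation) and holds out the last fraction of users as the test set —
emulating deployment, where newly joining users are the ones the model must
serve, and exposing any cohort-level concept drift.

Inside the training set four approaches build folds:

* ``time_cut`` — assessment-level: instances ordered by arrival time of the
  labelled assessment (t_next), cut into k contiguous blocks.  Ignores user
  grouping, so one user's instances can sit in training and validation
  folds simultaneously.
* ``user_cut`` — user-level: users shuffled and dealt into k disjoint
  groups (the GroupKFold idea); every instance inherits its user's fold.
* ``average_user`` — user_cut plus an expanding per-user median/mode
  feature transform that smooths within-user variance causally.
* ``user_wise`` — one model per user: each retained user's first 80 % of
  instances train a personal model, the rest test it; users below an
  assessment-count threshold are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    KIND_NUMERIC,
    USER_COL,
    EMADataset,
    FeatureSchema,
    SchemaError,
    ValidationError,
)
from .preprocess import INSTANCE_ID, T_NEXT, T_NOW

__all__ = [
    "OuterSplit",
    "FoldPlan",
    "outer_split",
    "time_cut_folds",
    "user_cut_folds",
    "average_user_transform",
    "user_wise_split",
    "APPROACH_TIME_CUT",
    "APPROACH_USER_CUT",
    "APPROACH_AVERAGE_USER",
    "APPROACH_USER_WISE",
]

APPROACH_TIME_CUT = "time_cut"
APPROACH_USER_CUT = "user_cut"
APPROACH_AVERAGE_USER = "average_user"
APPROACH_USER_WISE = "user_wise"

ORDER_SIGNUP = "signup_sorted"
ORDER_RANDOM = "random"


@dataclass(frozen=True)
class OuterSplit:
    """Assignment of users to the outer train/test sets."""

    ordering: str
    seed: int | None
    train_users: tuple[str, ...]
    test_users: tuple[str, ...]
    test_fraction: float

    @property
    def all_users(self) -> tuple[str, ...]:
        return self.train_users + self.test_users


@dataclass(frozen=True)
class FoldPlan:
    """An approach's fold layout over the training instances.

    For the three single-model approaches, ``assignment`` maps instance id →
    fold id in {0..k-1}.  For ``user_wise``, ``per_user_splits`` maps user →
    (train instance ids, test instance ids) instead.
    """

    approach: str
    k: int
    assignment: Mapping[str, int] | None = None
    per_user_splits: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] | None = None
    min_assessments: int | None = None

    def fold_instance_ids(self, fold: int) -> list[str]:
        assert self.assignment is not None
        return [i for i, f in self.assignment.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        """Audit view: one (instance_id, fold_id) row per training instance."""
        if self.assignment is not None:
            rows = sorted(self.assignment.items())
            return pd.DataFrame(rows, columns=["instance_id", "fold_id"])
        assert self.per_user_splits is not None
        rows = []
        for user in sorted(self.per_user_splits):
            train_ids, test_ids = self.per_user_splits[user]
            rows += [(i, f"{user}:train") for i in train_ids]
            rows += [(i, f"{user}:test") for i in test_ids]
        return pd.DataFrame(rows, columns=["instance_id", "fold_id"])


def outer_split(
    dataset: EMADataset,
    test_fraction: float = 0.2,
    ordering: str = ORDER_SIGNUP,
    seed: int | None = None,
) -> OuterSplit:
    """Split users into outer train/test sets.

    Under ``signup_sorted`` users are ordered by their first assessment
    timestamp and the last ``ceil(test_fraction * n)`` users form the test
    set, so every training user signed up no later than every test user.
    Under ``random`` the order is a seeded permutation instead.
    """
    users = dataset.users_by_signup()
    n = len(users)
    if n < 2:
        raise ValidationError("outer split needs at least 2 users")
    if ordering == ORDER_RANDOM:
        rng = np.random.default_rng(seed)
        users = [users[i] for i in rng.permutation(n)]
    elif ordering != ORDER_SIGNUP:
        raise SchemaError(f"unknown ordering {ordering!r}")
    n_test = int(np.ceil(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise SchemaError(
            f"test_fraction={test_fraction} gives a degenerate test set ({n_test}/{n} users)"
        )
    return OuterSplit(
        ordering=ordering,
        seed=seed,
        train_users=tuple(users[: n - n_test]),
        test_users=tuple(users[n - n_test :]),
        test_fraction=test_fraction,
    )


def time_cut_folds(
    train_instances: pd.DataFrame, k: int = 5, calendar: str | None = None
) -> FoldPlan:
    """Assessment-level folds: k contiguous time blocks of near-equal size.

    Instances are sorted by t_next arrival (ties by user id, then t_now);
    block sizes differ by at most one; no shuffling.  With ``calendar``
    set to a pandas period alias (e.g. ``"M"``) folds are calendar blocks
    instead: one fold per distinct t_next period, ignoring ``k``.
    """
    n = len(train_instances)
    order = train_instances.sort_values(
        [T_NEXT, USER_COL, T_NOW, INSTANCE_ID], kind="mergesort"
    )
    if calendar is not None:
        periods = order[T_NEXT].dt.tz_convert("UTC").dt.tz_localize(None).dt.to_period(calendar)
        codes, uniques = pd.factorize(periods, sort=True)
        if len(uniques) < 2:
            raise ValidationError("calendar mode needs at least 2 periods")
        assignment = dict(zip(order[INSTANCE_ID], codes.tolist()))
        return FoldPlan(
            approach=APPROACH_TIME_CUT, k=len(uniques), assignment=assignment
        )
    if n < k:
        raise ValidationError(f"{n} instances cannot fill {k} folds")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = np.repeat(np.arange(k), sizes)
    assignment = dict(zip(order[INSTANCE_ID], folds.tolist()))
    return FoldPlan(approach=APPROACH_TIME_CUT, k=k, assignment=assignment)


def user_cut_folds(
    train_users: Sequence[str],
    instances: pd.DataFrame,
    k: int = 5,
    seed: int | None = None,
) -> FoldPlan:
    """User-level folds: users shuffled, dealt round-robin into k groups.

    Every instance inherits the fold of its user, so fold user sets are
    pairwise disjoint (group k-fold).
    """
    users = list(train_users)
    if len(users) < k:
        raise ValidationError(f"{len(users)} users cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    shuffled = [users[i] for i in rng.permutation(len(users))]
    user_fold = {u: i % k for i, u in enumerate(shuffled)}
    sub = instances[instances[USER_COL].isin(user_fold)]
    assignment = {
        iid: user_fold[u] for iid, u in zip(sub[INSTANCE_ID], sub[USER_COL])
    }
    return FoldPlan(approach=APPROACH_USER_CUT, k=k, assignment=assignment)


def _expanding_mode(values: Sequence) -> list:
    """Expanding mode; ties broken toward the earliest-observed value."""
    counts: dict = {}
    first_seen: dict = {}
    out = []
    for i, v in enumerate(values):
        counts[v] = counts.get(v, 0) + 1
        if v not in first_seen:
            first_seen[v] = i
        best = min(counts, key=lambda x: (-counts[x], first_seen[x]))
        out.append(best)
    return out


def average_user_transform(
    instances: pd.DataFrame, schema: FeatureSchema, include_targets: bool = False
) -> pd.DataFrame:
    """Replace each feature value by the user's expanding median/mode.

    For each user (time-sorted) the value at position t becomes the median
    (numeric) or mode (categorical/boolean, ties toward the
    earliest-observed value) of that user's values at positions 1..t.
    Strictly causal: position t never sees later positions.  Instance ids,
    order and prediction targets are unchanged.  ``include_targets``
    additionally smooths the known-target-history column
    (``target_at_t_now``, the answer heuristics consume) with the same
    expanding mode; the predicted target itself is never touched.
    """
    out = instances.copy()
    order = out.sort_values([USER_COL, T_NOW, INSTANCE_ID], kind="mergesort").index
    columns = {name: schema.kind_of(name) == KIND_NUMERIC for name in schema.names}
    if include_targets:
        columns["target_at_t_now"] = False
    for name, numeric in columns.items():
        col = out.loc[order, name]
        if numeric:
            transformed = col.groupby(out.loc[order, USER_COL], sort=False).expanding().median()
            transformed = transformed.reset_index(level=0, drop=True)
        else:
            transformed = col.groupby(out.loc[order, USER_COL], sort=False).transform(
                lambda s: pd.Series(_expanding_mode(list(s)), index=s.index)
            )
        out.loc[order, name] = transformed.reindex(order).to_numpy()
    return out


def user_wise_split(
    instances: pd.DataFrame, min_assessments: int = 10
) -> FoldPlan:
    """Per-user temporal 80/20 split for the one-model-per-user approach.

    A user with m instances (m + 1 assessments) keeps the earliest
    ``max(1, floor(0.8 * m))`` instances for training and the rest for
    testing.  Users with fewer than ``min_assessments`` assessments are
    excluded entirely.
    """
    splits: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    ordered = instances.sort_values([USER_COL, T_NOW, INSTANCE_ID], kind="mergesort")
    for user, grp in ordered.groupby(USER_COL, sort=True):
        m = len(grp)
        if m + 1 < min_assessments:
            continue
        n_train = max(1, int(np.floor(0.8 * m)))
        ids = tuple(grp[INSTANCE_ID])
        splits[user] = (ids[:n_train], ids[n_train:])
    if not splits:
        raise ValidationError(
            f"no user reaches the {min_assessments}-assessment threshold"
        )
    return FoldPlan(
        approach=APPROACH_USER_WISE,
        k=len(splits),
        per_user_splits=splits,
        min_assessments=min_assessments,
    )
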