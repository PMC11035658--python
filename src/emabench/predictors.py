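"""The classifier contract and the four training-free baseline heuristics.

The reference model is a random forest (100 trees, Gini impurity) with a
shared seed across approaches, so that ranking differences come from the
splitting approach and not from model initialisation.

The heuristics predict the next target from already-known targets only:

* user-level latest — the user's most recent known target (their "last
  completed questionnaire");
* user-level average — the mode (class targets) or median (raw numeric
  targets) of the user's known targets;
* assessment-level latest / average — the same two statistics over *all*
  users' known targets, ignoring user identity.

All four are causal: the usable pool for an instance contains only records
with time <= t_now.  A brand-new user (empty user-level pool) falls back to
the assessment-level pool, and, if that too is empty, to a configured
global prior class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .data_model import (
    KIND_NUMERIC,
    USER_COL,
    FeatureSchema,
    SchemaError,
    ValidationError,
)
from .preprocess import INSTANCE_ID, T_NOW, TARGET_AT_T_NOW, TARGET_CLASS

__all__ = [
    "ModelSpec",
    "HeuristicSpec",
    "Prediction",
    "HEURISTICS",
    "fit_predict_model",
    "heuristic_predict",
    "history_from_instances",
]

SOURCE_MODEL = "model"
SOURCE_HEURISTIC = "heuristic"
SOURCE_COLD_START = "cold_start_fallback"

LEVEL_USER = "user"
LEVEL_ASSESSMENT = "assessment"
MODE_LAST = "last"
MODE_AVERAGE = "average"

# history-record column names
H_TIME = "time"
H_TARGET = "target"


@dataclass(frozen=True)
class ModelSpec:
    """Random forest contract shared by every approach in one experiment."""

    kind: str = "random_forest"
    n_trees: int = 100
    split_criterion: str = "gini"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "random_forest":
            raise SchemaError(f"unsupported model kind {self.kind!r}")


@dataclass(frozen=True)
class HeuristicSpec:
    """One of the four baseline heuristics (level x mode)."""

    level: str
    mode: str

    def __post_init__(self) -> None:
        if self.level not in (LEVEL_USER, LEVEL_ASSESSMENT):
            raise SchemaError(f"unknown heuristic level {self.level!r}")
        if self.mode not in (MODE_LAST, MODE_AVERAGE):
            raise SchemaError(f"unknown heuristic mode {self.mode!r}")

    @property
    def name(self) -> str:
        return f"bl_{self.level}_{self.mode}"


HEURISTICS = {
    "bl_user_last": HeuristicSpec(LEVEL_USER, MODE_LAST),
    "bl_user_average": HeuristicSpec(LEVEL_USER, MODE_AVERAGE),
    "bl_assessment_last": HeuristicSpec(LEVEL_ASSESSMENT, MODE_LAST),
    "bl_assessment_average": HeuristicSpec(LEVEL_ASSESSMENT, MODE_AVERAGE),
}


@dataclass(frozen=True)
class Prediction:
    instance_id: str
    predicted: int
    source: str


def predictions_frame(
    predictions: Sequence[Prediction], eval_instances: pd.DataFrame
) -> pd.DataFrame:
    """Exportable view: instance_id, y_true, y_pred, source."""
    truth = dict(zip(eval_instances[INSTANCE_ID], eval_instances[TARGET_CLASS]))
    return pd.DataFrame(
        {
            "instance_id": [p.instance_id for p in predictions],
            "y_true": [truth[p.instance_id] for p in predictions],
            "y_pred": [p.predicted for p in predictions],
            "source": [p.source for p in predictions],
        }
    )


def _encode_features(
    train: pd.DataFrame, other: pd.DataFrame, schema: FeatureSchema
) -> tuple[np.ndarray, np.ndarray]:
    """Numeric design matrices; categoricals get training-time integer codes.

    Levels unseen at training time map to a reserved unknown bucket (-1) —
    test users are by construction unseen, so this must not error.
    """
    cols = []
    cols_other = []
    for name in schema.names:
        if schema.kind_of(name) == KIND_NUMERIC:
            cols.append(train[name].to_numpy(dtype=float))
            cols_other.append(other[name].to_numpy(dtype=float))
        else:
            levels = sorted(pd.unique(train[name].astype(str)))
            mapping = {lv: i for i, lv in enumerate(levels)}
            cols.append(train[name].astype(str).map(mapping).to_numpy(dtype=float))
            cols_other.append(
                other[name].astype(str).map(mapping).fillna(-1.0).to_numpy(dtype=float)
            )
    return np.column_stack(cols), np.column_stack(cols_other)


def fit_predict_model(
    train: pd.DataFrame,
    eval_instances: pd.DataFrame,
    spec: ModelSpec,
    schema: FeatureSchema,
) -> list[Prediction]:
    """Fit the random forest on training instances, predict eval instances.

    Deterministic given the spec seed, and invariant to training-row order
    (rows are canonically sorted by instance id before fitting).
    """
    if len(train) == 0:
        raise ValidationError("empty training set")
    train = train.sort_values(INSTANCE_ID, kind="mergesort")
    X_tr, X_ev = _encode_features(train, eval_instances, schema)
    y_tr = train[TARGET_CLASS].to_numpy(dtype=int)
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        criterion=spec.split_criterion,
        random_state=spec.seed,
        n_jobs=1,
    )
    clf.fit(X_tr, y_tr)
    y_hat = clf.predict(X_ev)
    return [
        Prediction(iid, int(p), SOURCE_MODEL)
        for iid, p in zip(eval_instances[INSTANCE_ID], y_hat)
    ]


def history_from_instances(instances: pd.DataFrame) -> pd.DataFrame:
    """Known-target records (user_id, time, target) from an instance table.

    Each instance contributes its t_now assessment's target — the record
    that becomes known the moment the questionnaire is completed.
    """
    return pd.DataFrame(
        {
            USER_COL: instances[USER_COL].to_numpy(),
            H_TIME: instances[T_NOW].to_numpy(),
            H_TARGET: instances[TARGET_AT_T_NOW].to_numpy(dtype=int),
        }
    )


def _canonical_history(history: pd.DataFrame, n_classes: int) -> pd.DataFrame:
    if len(history) and (
        (history[H_TARGET] < 0) | (history[H_TARGET] >= n_classes)
    ).any():
        raise ValidationError("history contains a label outside the label set")
    h = history.drop_duplicates(subset=[USER_COL, H_TIME], keep="first")
    return h.sort_values([H_TIME, USER_COL], kind="mergesort").reset_index(drop=True)


def _pool_modes(counts: np.ndarray) -> int:
    """Modal class of a count vector; ties toward the smallest class."""
    return int(np.argmax(counts))


def heuristic_predict(
    history: pd.DataFrame,
    eval_instances: pd.DataFrame,
    spec: HeuristicSpec,
    n_classes: int,
    global_prior: int = 0,
    strictly_before: bool = False,
) -> list[Prediction]:
    """Predict each eval instance from known-target records.

    ``history`` has columns (user_id, time, target); duplicate (user, time)
    records are dropped.  The usable pool for an instance is every record
    with time <= t_now (or < t_now with ``strictly_before``).  At user
    level the pool is restricted to the instance's own user and so includes
    the user's own t_now record (their "last completed questionnaire").  At
    assessment level the instance's own record at exactly t_now is *not*
    yet part of the shared pool — only targets known before the current
    questionnaire count, regardless of user id.  ``last`` takes the pool's
    latest-time record (ties: the record latest in canonical (time, user)
    order); ``average`` its modal class (ties toward the smallest class).
    Cold-start chain: empty user pool → assessment-level pool of the same
    mode → ``global_prior``.
    """
    h = _canonical_history(history, n_classes)
    times = h[H_TIME].to_numpy()
    targets = h[H_TARGET].to_numpy()
    h_users = h[USER_COL].to_numpy()
    side = "left" if strictly_before else "right"
    t_now = eval_instances[T_NOW].to_numpy()
    cut = np.searchsorted(times, t_now, side=side)
    record_pos = {(u, t): i for i, (u, t) in enumerate(zip(h_users, times))}

    # global (assessment-level) cumulative class counts for average / fallback
    onehot = np.zeros((len(h) + 1, n_classes), dtype=np.int64)
    if len(h):
        np.add.at(onehot, (np.arange(1, len(h) + 1), targets), 1)
        onehot = np.cumsum(onehot, axis=0)

    # per-user record positions for user-level pools
    user_pos: dict[str, np.ndarray] = {}
    if spec.level == LEVEL_USER:
        for u, grp in h.groupby(USER_COL, sort=False):
            user_pos[u] = grp.index.to_numpy()

    preds: list[Prediction] = []
    users = eval_instances[USER_COL].to_numpy()
    iids = eval_instances[INSTANCE_ID].to_numpy()
    for j in range(len(eval_instances)):
        c = cut[j]
        source = SOURCE_HEURISTIC
        cls: int | None = None
        if spec.level == LEVEL_USER:
            pos = user_pos.get(users[j], np.empty(0, dtype=int))
            pos = pos[pos < c]
            if len(pos):
                if spec.mode == MODE_LAST:
                    cls = int(targets[pos[-1]])
                else:
                    counts = np.bincount(targets[pos], minlength=n_classes)
                    cls = _pool_modes(counts)
            else:
                source = SOURCE_COLD_START
        if cls is None:
            # assessment level, or user-level cold-start fallback; the
            # instance's own record at exactly t_now is excluded here
            own_pos = record_pos.get((users[j], t_now[j]))
            if own_pos is not None and own_pos >= c:
                own_pos = None
            if spec.mode == MODE_LAST:
                p = c - 1
                if own_pos is not None and own_pos == p:
                    p -= 1
                if p >= 0:
                    cls = int(targets[p])
            else:
                counts = onehot[c].copy()
                if own_pos is not None:
                    counts[targets[own_pos]] -= 1
                if counts.sum() > 0:
                    cls = _pool_modes(counts)
            if cls is None:
                cls = int(global_prior)
                source = SOURCE_COLD_START
        preds.append(Prediction(str(iids[j]), cls, source))
    return preds
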