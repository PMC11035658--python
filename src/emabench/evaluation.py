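"""Fold-wise and test evaluation, final score, ranking, ordering comparison.

Each splitting approach and each baseline heuristic yields an
:class:`ApproachResult`: the k validation-fold weighted F1 scores, their
mean and standard deviation, the weighted F1 on the outer test set, and the
robustness-penalised final score

    f1_final = f1_test - alpha * sd(fold F1),

so approaches whose fold scores fluctuate are marked down in proportion to
``alpha``.  The fold standard deviation doubles as an estimator of the
generalisation error: the approach is *in range* when it covers the
observed validation-to-test degradation.

Approaches are ranked per dataset by final score (1 = best, average ranks
on ties) and aggregated across datasets as mean and standard deviation of
ranks.  ``compare_orderings`` re-runs the whole pipeline with the sign-up
ordering of users replaced by seeded random permutations and reports how
much the ranking moves — the concept-drift sensitivity diagnostic.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import f1_score

from .data_model import EMADataset, SchemaError, ValidationError, USER_COL
from .preprocess import (
    INSTANCE_ID,
    T_NOW,
    TARGET_CLASS,
    build_instances,
    impute_missing,
)
from .predictors import (
    HEURISTICS,
    HeuristicSpec,
    ModelSpec,
    Prediction,
    fit_predict_model,
    heuristic_predict,
    history_from_instances,
)
from .splitting import (
    APPROACH_AVERAGE_USER,
    APPROACH_TIME_CUT,
    APPROACH_USER_CUT,
    APPROACH_USER_WISE,
    ORDER_RANDOM,
    ORDER_SIGNUP,
    FoldPlan,
    OuterSplit,
    average_user_transform,
    outer_split,
    time_cut_folds,
    user_cut_folds,
    user_wise_split,
)

__all__ = [
    "ALL_APPROACHES",
    "MODEL_APPROACHES",
    "HEURISTIC_APPROACHES",
    "ApproachResult",
    "RankTable",
    "EvalConfig",
    "Evaluator",
    "OrderingComparison",
    "weighted_f1",
    "final_score",
    "performance_drop",
    "in_range",
    "run_approach",
    "rank_approaches",
    "aggregate_ranks",
    "compare_orderings",
    "derive_seed",
]

log = logging.getLogger("emabench.evaluation")


def _log_plan(plan: FoldPlan) -> FoldPlan:
    if plan.assignment is not None:
        payload = repr(sorted(plan.assignment.items()))
    else:
        payload = repr(sorted((plan.per_user_splits or {}).items()))
    log.debug("fold plan %s checksum %08x", plan.approach, zlib.crc32(payload.encode()))
    return plan


MODEL_APPROACHES = (
    APPROACH_TIME_CUT,
    APPROACH_USER_CUT,
    APPROACH_AVERAGE_USER,
    APPROACH_USER_WISE,
)
HEURISTIC_APPROACHES = tuple(HEURISTICS)
ALL_APPROACHES = MODEL_APPROACHES + HEURISTIC_APPROACHES


def derive_seed(master: int, *tags) -> int:
    """Deterministic sub-seed from a master seed and string/int tags (< 2^31)."""
    text = ":".join([str(master), *map(str, tags)])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# -- elementary scores -----------------------------------------------------


def weighted_f1(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Per-class F1 averaged with weights proportional to true-class support."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValidationError("cannot score empty label sequences")
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))


def _fold_sd(fold_f1: Sequence[float]) -> float:
    scores = np.asarray(fold_f1, dtype=float)
    if scores.size == 0:
        raise ValidationError("fold_f1 must be non-empty")
    return float(np.std(scores, ddof=1)) if scores.size > 1 else 0.0


def final_score(f1_test: float, fold_f1: Sequence[float], alpha: float) -> float:
    """f1_test − alpha · sample-sd(fold F1); a single fold has sd 0."""
    if alpha < 0:
        raise SchemaError("alpha must be non-negative")
    return f1_test - alpha * _fold_sd(fold_f1)


def performance_drop(f1_train: float, f1_test: float) -> float:
    """Signed test-minus-validation difference (negative = overestimation)."""
    return f1_test - f1_train


def in_range(sigma_train: float, drop: float) -> bool:
    """Does the fold sd cover the observed validation-to-test degradation?

    True iff (f1_train − f1_test) <= sigma_train; positive drops are always
    in range.
    """
    if sigma_train < 0:
        raise ValidationError("sigma_train must be non-negative")
    return bool(-drop <= sigma_train)


@dataclass(frozen=True)
class ApproachResult:
    """Complete evaluation record of one approach on one dataset."""

    approach: str
    fold_f1: tuple[float, ...]
    f1_test: float
    alpha: float
    source: str = "model"

    @property
    def f1_train(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def sigma_train(self) -> float:
        return _fold_sd(self.fold_f1)

    @property
    def f1_final(self) -> float:
        return self.f1_test - self.alpha * self.sigma_train

    @property
    def performance_drop(self) -> float:
        return performance_drop(self.f1_train, self.f1_test)

    @property
    def in_range(self) -> bool:
        return in_range(self.sigma_train, self.performance_drop)

    def to_row(self) -> dict:
        return {
            "approach": self.approach,
            "source": self.source,
            "k": len(self.fold_f1),
            "f1_train": self.f1_train,
            "sigma_train": self.sigma_train,
            "f1_test": self.f1_test,
            "alpha": self.alpha,
            "f1_final": self.f1_final,
            "performance_drop": self.performance_drop,
            "in_range": self.in_range,
        }


# -- configuration / engine ------------------------------------------------


@dataclass(frozen=True)
class EvalConfig:
    """Experiment-wide evaluation settings."""

    k: int = 5
    alpha: float = 0.5
    test_fraction: float = 0.2
    min_assessments: int = 10
    fold_seed: int = 0
    model: ModelSpec = field(default_factory=ModelSpec)
    approaches: tuple[str, ...] = ALL_APPROACHES
    same_time: bool = False
    strictly_before: bool = False
    # user_wise test score: pooled weighted F1 (default) or per-user macro mean
    user_wise_macro: bool = False

    def validate(self) -> None:
        if self.alpha < 0:
            raise SchemaError("alpha must be non-negative")
        if self.k < 2:
            raise SchemaError("k must be >= 2")
        unknown = set(self.approaches) - set(ALL_APPROACHES)
        if unknown:
            raise SchemaError(f"unknown approaches: {sorted(unknown)}")
        if not self.approaches:
            raise SchemaError("need at least one approach")


def _score_fold_model(
    train_inst: pd.DataFrame,
    plan: FoldPlan,
    model: ModelSpec,
    schema,
) -> list[float]:
    fold_of = train_inst[INSTANCE_ID].map(plan.assignment)
    scores = []
    for f in range(plan.k):
        val = train_inst[fold_of == f]
        tr = train_inst[(fold_of != f) & fold_of.notna()]
        preds = fit_predict_model(tr, val, model, schema)
        scores.append(
            weighted_f1(val[TARGET_CLASS].to_numpy(), [p.predicted for p in preds])
        )
    return scores


def _heuristic_eval_grouped(
    base_records: pd.DataFrame,
    eval_inst: pd.DataFrame,
    own_records_all: pd.DataFrame,
    spec: HeuristicSpec,
    n_classes: int,
    prior: int,
    strictly_before: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Causal heuristic predictions; pool = base records + the user's own chain.

    Evaluation instances are grouped by user so that one eval user's records
    never enter another eval user's assessment-level pool.
    """
    y_true: list[np.ndarray] = []
    y_pred: list[int] = []
    own_by_user = dict(tuple(own_records_all.groupby(USER_COL, sort=False)))
    for user, grp in eval_inst.groupby(USER_COL, sort=True):
        own = own_by_user.get(user)
        history = (
            pd.concat([base_records, own], ignore_index=True)
            if own is not None
            else base_records
        )
        preds = heuristic_predict(
            history, grp, spec, n_classes, global_prior=prior,
            strictly_before=strictly_before,
        )
        y_true.append(grp[TARGET_CLASS].to_numpy())
        y_pred.extend(p.predicted for p in preds)
    return np.concatenate(y_true), np.asarray(y_pred)


class Evaluator:
    """Runs all approaches on one dataset; instance-level work is cached.

    Imputation, instance construction, the average-user transform and the
    (outer-split independent) user-wise per-user evaluation are computed
    once; each call to :meth:`run` then evaluates the requested approaches
    under one user ordering.
    """

    def __init__(self, dataset: EMADataset, config: EvalConfig | None = None) -> None:
        self.config = config or EvalConfig()
        self.config.validate()
        self.dataset = impute_missing(dataset)
        self.schema = dataset.schema
        self.n_classes = dataset.target_spec.n_classes
        self.instances = build_instances(self.dataset, same_time=self.config.same_time)
        self._transformed: pd.DataFrame | None = None
        self._user_wise: ApproachResult | None = None

    @property
    def transformed_instances(self) -> pd.DataFrame:
        if self._transformed is None:
            self._transformed = average_user_transform(self.instances, self.schema)
        return self._transformed

    # -- single-approach pieces -------------------------------------------

    def _instances_of(self, users: Sequence[str], transformed: bool) -> pd.DataFrame:
        inst = self.transformed_instances if transformed else self.instances
        return inst[inst[USER_COL].isin(set(users))]

    def _model_result(
        self, approach: str, outer: OuterSplit, shared_test_f1: dict
    ) -> ApproachResult:
        cfg = self.config
        transformed = approach == APPROACH_AVERAGE_USER
        train_inst = self._instances_of(outer.train_users, transformed)
        test_inst = self._instances_of(outer.test_users, transformed)
        if approach == APPROACH_TIME_CUT:
            plan = time_cut_folds(train_inst, cfg.k)
        else:
            plan = user_cut_folds(outer.train_users, train_inst, cfg.k, cfg.fold_seed)
            plan = replace(plan, approach=approach)
        _log_plan(plan)
        fold_scores = _score_fold_model(train_inst, plan, cfg.model, self.schema)
        # one final model per feature representation, shared across approaches
        key = "transformed" if transformed else "identity"
        if key not in shared_test_f1:
            preds = fit_predict_model(train_inst, test_inst, cfg.model, self.schema)
            shared_test_f1[key] = weighted_f1(
                test_inst[TARGET_CLASS].to_numpy(), [p.predicted for p in preds]
            )
        return ApproachResult(
            approach=approach,
            fold_f1=tuple(fold_scores),
            f1_test=shared_test_f1[key],
            alpha=cfg.alpha,
            source="model",
        )

    def _user_wise_result(self) -> ApproachResult:
        """One model per retained user; outer-split independent, cached."""
        if self._user_wise is not None:
            return self._user_wise
        cfg = self.config
        plan = _log_plan(user_wise_split(self.instances, cfg.min_assessments))
        inst = self.instances.set_index(
            self.instances[INSTANCE_ID].rename(None), drop=False
        )
        per_user_scores: list[float] = []
        per_user_test: list[float] = []
        y_true_all: list[np.ndarray] = []
        y_pred_all: list[int] = []
        for user in sorted(plan.per_user_splits):
            train_ids, test_ids = plan.per_user_splits[user]
            tr = inst.loc[list(train_ids)]
            te = inst.loc[list(test_ids)]
            if len(te):
                preds = fit_predict_model(tr, te, cfg.model, self.schema)
                y_true_all.append(te[TARGET_CLASS].to_numpy())
                y_pred_all.extend(p.predicted for p in preds)
                per_user_test.append(
                    weighted_f1(
                        te[TARGET_CLASS].to_numpy(), [p.predicted for p in preds]
                    )
                )
            # per-user CV on the training part: contiguous time blocks
            m = len(tr)
            k_u = min(cfg.k, m)
            if k_u >= 2:
                blocks = np.repeat(np.arange(k_u), np.diff(np.linspace(0, m, k_u + 1).astype(int)))
                scores = []
                for f in range(k_u):
                    val = tr[blocks == f]
                    sub = tr[blocks != f]
                    preds = fit_predict_model(sub, val, cfg.model, self.schema)
                    scores.append(
                        weighted_f1(val[TARGET_CLASS].to_numpy(), [p.predicted for p in preds])
                    )
                per_user_scores.append(float(np.mean(scores)))
        if not y_true_all:
            raise ValidationError("user_wise produced no test predictions")
        if cfg.user_wise_macro:
            f1_test = float(np.mean(per_user_test))
        else:
            f1_test = weighted_f1(np.concatenate(y_true_all), np.asarray(y_pred_all))
        self._user_wise = ApproachResult(
            approach=APPROACH_USER_WISE,
            fold_f1=tuple(per_user_scores) if per_user_scores else (f1_test,),
            f1_test=f1_test,
            alpha=cfg.alpha,
            source="model",
        )
        return self._user_wise

    def _heuristic_result(self, name: str, outer: OuterSplit) -> ApproachResult:
        cfg = self.config
        spec = HEURISTICS[name]
        train_inst = self._instances_of(outer.train_users, transformed=False)
        test_inst = self._instances_of(outer.test_users, transformed=False)
        prior = int(train_inst[TARGET_CLASS].mode().sort_values().iloc[0])
        # user-level heuristics share the user-cut plan, assessment-level the
        # time-cut plan (the fold layout matching their own level)
        if spec.level == "user":
            plan = user_cut_folds(outer.train_users, train_inst, cfg.k, cfg.fold_seed)
        else:
            plan = time_cut_folds(train_inst, cfg.k)
        _log_plan(plan)
        fold_of = train_inst[INSTANCE_ID].map(plan.assignment)
        all_train_records = history_from_instances(train_inst)
        fold_scores = []
        for f in range(plan.k):
            val = train_inst[fold_of == f]
            tr = train_inst[(fold_of != f) & fold_of.notna()]
            own_records = history_from_instances(
                train_inst[train_inst[USER_COL].isin(set(val[USER_COL]))]
            )
            y_t, y_p = _heuristic_eval_grouped(
                history_from_instances(tr), val, own_records,
                spec, self.n_classes, prior, cfg.strictly_before,
            )
            fold_scores.append(weighted_f1(y_t, y_p))
        own_test = history_from_instances(test_inst)
        y_t, y_p = _heuristic_eval_grouped(
            all_train_records, test_inst, own_test,
            spec, self.n_classes, prior, cfg.strictly_before,
        )
        return ApproachResult(
            approach=name,
            fold_f1=tuple(fold_scores),
            f1_test=weighted_f1(y_t, y_p),
            alpha=cfg.alpha,
            source="heuristic",
        )

    # -- public API --------------------------------------------------------

    def run(
        self, ordering: str = ORDER_SIGNUP, ordering_seed: int | None = None
    ) -> dict[str, ApproachResult]:
        """Evaluate every configured approach under one user ordering."""
        outer = outer_split(
            self.dataset, self.config.test_fraction, ordering, ordering_seed
        )
        shared_test_f1: dict = {}
        results: dict[str, ApproachResult] = {}
        for approach in self.config.approaches:
            if approach == APPROACH_USER_WISE:
                results[approach] = self._user_wise_result()
            elif approach in MODEL_APPROACHES:
                results[approach] = self._model_result(approach, outer, shared_test_f1)
            else:
                results[approach] = self._heuristic_result(approach, outer)
        return results


def run_approach(
    dataset: EMADataset,
    approach: str,
    config: EvalConfig | None = None,
    ordering: str = ORDER_SIGNUP,
    ordering_seed: int | None = None,
) -> ApproachResult:
    """Evaluate a single approach end-to-end on a dataset."""
    config = config or EvalConfig()
    config = replace(config, approaches=(approach,))
    return Evaluator(dataset, config).run(ordering, ordering_seed)[approach]


# -- ranking ---------------------------------------------------------------


def rank_approaches(
    results: Mapping[str, ApproachResult] | Sequence[ApproachResult],
) -> dict[str, float]:
    """Rank approaches by final score (1 = best); ties get average ranks."""
    if isinstance(results, Mapping):
        results = list(results.values())
    names = [r.approach for r in results]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate approach names in ranking")
    if not names:
        raise ValidationError("nothing to rank")
    scores = np.array([r.f1_final for r in results])
    ranks = rankdata(-scores, method="average")
    return dict(zip(names, ranks.tolist()))


@dataclass(frozen=True)
class RankTable:
    """Cross-dataset rank aggregate: mean and sd of ranks per approach."""

    approaches: tuple[str, ...]
    mean_rank: dict[str, float]
    sd_rank: dict[str, float]
    per_dataset: tuple[dict[str, float], ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "approach": a,
                "mean_rank": self.mean_rank[a],
                "sd_rank": self.sd_rank[a],
            }
            for a in self.approaches
        ]
        return pd.DataFrame(rows).sort_values("mean_rank", kind="mergesort").reset_index(drop=True)


def aggregate_ranks(per_dataset_ranks: Sequence[Mapping[str, float]]) -> RankTable:
    """Aggregate per-dataset ranks into mean rank and rank sd per approach."""
    if not per_dataset_ranks:
        raise ValidationError("no rankings to aggregate")
    approaches = tuple(sorted(per_dataset_ranks[0]))
    for r in per_dataset_ranks:
        if tuple(sorted(r)) != approaches:
            raise ValidationError("inconsistent approach sets across datasets")
    mean, sd = {}, {}
    for a in approaches:
        vals = np.array([r[a] for r in per_dataset_ranks], dtype=float)
        mean[a] = float(vals.mean())
        sd[a] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RankTable(
        approaches=approaches,
        mean_rank=mean,
        sd_rank=sd,
        per_dataset=tuple(dict(r) for r in per_dataset_ranks),
    )


# -- ordering comparison (concept-drift diagnostic) ------------------------


@dataclass(frozen=True)
class OrderingComparison:
    """Sorted-vs-shuffled pipeline comparison."""

    sorted_results: dict[str, ApproachResult]
    draw_results: tuple[dict[str, ApproachResult], ...]
    sorted_ranks: dict[str, float]
    draw_ranks: tuple[dict[str, float], ...]
    rank_change_per_approach: dict[str, float]
    rank_change_overall: float


def compare_orderings(
    dataset: EMADataset,
    n_draws: int = 5,
    seed: int = 0,
    config: EvalConfig | None = None,
) -> OrderingComparison:
    """Run the pipeline sorted by sign-up and under n_draws random orderings.

    Reports, per approach, the mean absolute rank difference between each
    random draw and the sorted run, and the overall mean over approaches —
    the "how much does the ranking move" statistic.
    """
    if n_draws < 1:
        raise SchemaError("n_draws must be >= 1")
    engine = Evaluator(dataset, config)
    sorted_results = engine.run(ORDER_SIGNUP)
    sorted_ranks = rank_approaches(sorted_results)
    draw_results = []
    draw_ranks = []
    for d in range(n_draws):
        res = engine.run(ORDER_RANDOM, derive_seed(seed, "draw", d))
        draw_results.append(res)
        draw_ranks.append(rank_approaches(res))
    per_approach = {
        a: float(np.mean([abs(r[a] - sorted_ranks[a]) for r in draw_ranks]))
        for a in sorted_ranks
    }
    overall = float(np.mean(list(per_approach.values())))
    return OrderingComparison(
        sorted_results=sorted_results,
        draw_results=tuple(draw_results),
        sorted_ranks=sorted_ranks,
        draw_ranks=tuple(draw_ranks),
        rank_change_per_approach=per_approach,
        rank_change_overall=overall,
    )
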