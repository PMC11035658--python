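import numpy as np
import pandas as pd
import pytest

from emabench.data_model import FeatureSchema, FeatureSpec, SchemaError, ValidationError
from emabench.evaluation import weighted_f1
from emabench.preprocess import (
    INSTANCE_ID,
    T_NOW,
    TARGET_AT_T_NOW,
    TARGET_CLASS,
    build_instances,
    impute_missing,
)
from emabench.predictors import (
    HEURISTICS,
    HeuristicSpec,
    ModelSpec,
    fit_predict_model,
    heuristic_predict,
    history_from_instances,
)
from emabench.synthetic_ema import GeneratorConfig, generate

SCHEMA = FeatureSchema((FeatureSpec("x1", "numeric"), FeatureSpec("cat", "categorical")))


def _inst(rows):
    """Instance frame from (iid, user, t_now_iso, x1, cat, y, y_at_now) tuples."""
    return pd.DataFrame(
        rows,
        columns=[INSTANCE_ID, "user_id", T_NOW, "x1", "cat", TARGET_CLASS, TARGET_AT_T_NOW],
    ).assign(**{T_NOW: lambda d: pd.to_datetime(d[T_NOW], utc=True)})


class TestModel:
    def test_single_class_training_predicts_that_class(self):
        train = _inst([(f"i{j}", "u1", f"2021-01-0{j+1}T00:00:00Z", float(j), "a", 2, 2) for j in range(4)])
        ev = _inst([("e0", "u9", "2021-02-01T00:00:00Z", 9.0, "b", 0, 0)])
        preds = fit_predict_model(train, ev, ModelSpec(seed=0), SCHEMA)
        assert [p.predicted for p in preds] == [2]

    def test_empty_training_set_rejected(self):
        ev = _inst([("e0", "u9", "2021-02-01T00:00:00Z", 9.0, "b", 0, 0)])
        with pytest.raises(ValidationError):
            fit_predict_model(ev.iloc[:0], ev, ModelSpec(seed=0), SCHEMA)

    def test_deterministic_and_row_order_invariant(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"i{j}", f"u{j%5}", f"2021-01-{j%27+1:02d}T00:00:00Z",
             float(rng.normal()), "ab"[j % 2], int(j % 3), int(j % 3))
            for j in range(40)
        ]
        train = _inst(rows)
        ev = _inst(rows[:10])
        a = fit_predict_model(train, ev, ModelSpec(seed=3), SCHEMA)
        b = fit_predict_model(train.sample(frac=1.0, random_state=8), ev, ModelSpec(seed=3), SCHEMA)
        assert [p.predicted for p in a] == [p.predicted for p in b]

    def test_unseen_category_goes_to_unknown_bucket(self):
        train = _inst([(f"i{j}", "u1", f"2021-01-0{j+1}T00:00:00Z", float(j), "a", j % 2, j % 2) for j in range(6)])
        ev = _inst([("e0", "u9", "2021-02-01T00:00:00Z", 1.0, "NEVER-SEEN", 0, 0)])
        preds = fit_predict_model(train, ev, ModelSpec(seed=0), SCHEMA)
        assert preds[0].predicted in (0, 1)

    def test_near_separable_regime_reaches_high_f1(self):
        """Noise-free features + near-unit persistence → next class is
        almost determined by the current latent, so held-out weighted F1
        must be near-perfect."""
        cfg = GeneratorConfig(
            n_users=100, count_dist=(15.0, 0.3), icc=0.97, rho=0.995,
            ar_share=1.0, feature_snr=np.inf, feature_user_sd=0.0,
            n_informative=3, n_noise=0, n_categorical=0, missing_rate=0.0, seed=5,
        )
        ds = generate(cfg)
        inst = build_instances(impute_missing(ds))
        users = sorted(set(inst["user_id"]))
        train = inst[inst["user_id"].isin(users[:80])]
        ev = inst[inst["user_id"].isin(users[80:])]
        preds = fit_predict_model(train, ev, ModelSpec(seed=0), ds.schema)
        f1 = weighted_f1(ev[TARGET_CLASS].to_numpy(), [p.predicted for p in preds])
        assert f1 > 0.95


def _history(rows):
    return pd.DataFrame(rows, columns=["user_id", "time", "target"]).assign(
        time=lambda d: pd.to_datetime(d["time"], utc=True)
    )


U_LAST = HEURISTICS["bl_user_last"]
U_AVG = HEURISTICS["bl_user_average"]
A_LAST = HEURISTICS["bl_assessment_last"]
A_AVG = HEURISTICS["bl_assessment_average"]


class TestHeuristics:
    def test_user_level_last_takes_latest_record(self):
        hist = _history([("u1", "2021-01-01", 2), ("u1", "2021-01-02", 3)])
        ev = _inst([("e0", "u1", "2021-01-03T00:00:00Z", 0.0, "a", 0, 0)])
        preds = heuristic_predict(hist, ev, U_LAST, n_classes=5)
        assert preds[0].predicted == 3

    def test_user_level_average_is_mode(self):
        hist = _history(
            [("u1", "2021-01-01", 2), ("u1", "2021-01-02", 3), ("u1", "2021-01-03", 3)]
        )
        ev = _inst([("e0", "u1", "2021-01-04T00:00:00Z", 0.0, "a", 0, 0)])
        preds = heuristic_predict(hist, ev, U_AVG, n_classes=5)
        assert preds[0].predicted == 3

    def test_cold_start_falls_back_to_assessment_pool(self):
        hist = _history([("other", "2021-01-01", 1)])
        ev = _inst([("e0", "brandnew", "2021-01-02T00:00:00Z", 0.0, "a", 0, 0)])
        preds = heuristic_predict(hist, ev, U_LAST, n_classes=5)
        assert preds[0].predicted == 1
        assert preds[0].source == "cold_start_fallback"

    def test_double_cold_start_uses_global_prior(self):
        hist = _history([("other", "2021-06-01", 1)])  # strictly in the future
        ev = _inst([("e0", "brandnew", "2021-01-02T00:00:00Z", 0.0, "a", 0, 0)])
        preds = heuristic_predict(hist, ev, U_LAST, n_classes=5, global_prior=4)
        assert preds[0].predicted == 4

    def test_own_current_record_counts_at_user_level_only(self):
        # the user's own record at exactly t_now is usable at user level
        # ("last completed questionnaire") but not yet in the shared pool
        hist = _history([("u1", "2021-01-05", 3), ("other", "2021-01-01", 1)])
        ev = _inst([("e0", "u1", "2021-01-05T00:00:00Z", 0.0, "a", 0, 3)])
        assert heuristic_predict(hist, ev, U_LAST, 5)[0].predicted == 3
        assert heuristic_predict(hist, ev, A_LAST, 5)[0].predicted == 1

    def test_label_outside_label_set_rejected(self):
        hist = _history([("u1", "2021-01-01", 7)])
        ev = _inst([("e0", "u1", "2021-01-02T00:00:00Z", 0.0, "a", 0, 0)])
        with pytest.raises(ValidationError):
            heuristic_predict(hist, ev, U_LAST, n_classes=5)

    @pytest.mark.parametrize("name", list(HEURISTICS))
    def test_causality_future_records_never_matter(self, name):
        """Dropping all records later than t_now leaves predictions unchanged."""
        rng = np.random.default_rng(2)
        hist = _history(
            [
                (f"u{j%4}", pd.Timestamp("2021-01-01") + pd.Timedelta(hours=float(h)), int(c))
                for j, (h, c) in enumerate(
                    zip(rng.uniform(0, 1000, 60), rng.integers(0, 5, 60))
                )
            ]
        )
        t_eval = pd.Timestamp("2021-01-15T00:00:00Z")
        ev = _inst([("e0", "u0", t_eval.isoformat(), 0.0, "a", 0, 2)])
        spec = HEURISTICS[name]
        full = heuristic_predict(hist, ev, spec, 5)
        trimmed = heuristic_predict(hist[hist["time"] <= t_eval], ev, spec, 5)
        assert full[0].predicted == trimmed[0].predicted

    def test_assessment_average_converges_to_modal_class(self):
        """With stable class proportions the all-users average heuristic
        collapses onto the majority class (high bias, minimum variance)."""
        rng = np.random.default_rng(3)
        classes = rng.choice(5, p=[0.1, 0.15, 0.4, 0.2, 0.15], size=2000)
        hist = _history(
            [
                (f"u{j%50}", pd.Timestamp("2021-01-01") + pd.Timedelta(minutes=j), int(c))
                for j, c in enumerate(classes)
            ]
        )
        ev = _inst([("e0", "u0", "2021-02-15T00:00:00Z", 0.0, "a", 0, 0)])
        preds = heuristic_predict(hist, ev, A_AVG, n_classes=5)
        assert preds[0].predicted == 2

    def test_persistent_process_user_last_beats_assessment_last(self):
        """High within-user persistence makes the user's own last answer a
        better predictor than the globally latest answer."""
        cfg = GeneratorConfig(
            n_users=200, count_dist=(10.0, 0.8), icc=0.6, rho=0.95, seed=11
        )
        ds = generate(cfg)
        inst = build_instances(impute_missing(ds))
        hist = history_from_instances(inst)
        scores = {}
        for name in ("bl_user_last", "bl_assessment_last"):
            preds = heuristic_predict(hist, inst, HEURISTICS[name], ds.target_spec.n_classes)
            scores[name] = weighted_f1(
                inst[TARGET_CLASS].to_numpy(), [p.predicted for p in preds]
            )
        assert scores["bl_user_last"] >= scores["bl_assessment_last"]

    def test_invalid_spec_combinations_rejected(self):
        with pytest.raises(SchemaError):
            HeuristicSpec("nation", "last")
        with pytest.raises(SchemaError):
            HeuristicSpec("user", "median-ish")
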