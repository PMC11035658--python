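import numpy as np
import pandas as pd
import pytest

from emabench.data_model import SchemaError, ValidationError
from emabench.preprocess import INSTANCE_ID, T_NEXT, T_NOW, build_instances, impute_missing
from emabench.splitting import (
    average_user_transform,
    outer_split,
    time_cut_folds,
    user_cut_folds,
    user_wise_split,
)
from emabench.data_model import FeatureSchema, FeatureSpec

from conftest import make_dataset


def _instance_frame(spec):
    """Instances from {user: [(t_now_iso, feature_value), ...]} shorthand."""
    rows = []
    for user, seq in spec.items():
        for i, (t, v) in enumerate(seq):
            rows.append(
                {
                    INSTANCE_ID: f"{user}-{i}",
                    "user_id": user,
                    T_NOW: pd.Timestamp(t),
                    T_NEXT: pd.Timestamp(t) + pd.Timedelta(hours=1),
                    "mood": v,
                    "target_class": 0,
                    "target_at_t_now": 0,
                }
            )
    return pd.DataFrame(rows)


def _daily_users(n):
    rows = []
    for d in range(1, n + 1):
        for j in range(2):
            rows.append(
                (f"u{d}a{j}", f"u{d:02d}", f"2021-01-{d:02d}T{j:02d}:00:00Z", 0.5, 1.0)
            )
    return make_dataset(rows, {"mood": "numeric"})


class TestOuterSplit:
    def test_sorted_split_takes_latest_signups(self):
        ds = _daily_users(10)
        split = outer_split(ds, 0.2, "signup_sorted")
        assert split.test_users == ("u09", "u10")
        assert len(split.train_users) == 8

    def test_ceil_rounding(self):
        ds = _daily_users(5)
        split = outer_split(ds, 0.2, "signup_sorted")
        assert len(split.test_users) == 1

    def test_random_ordering_deterministic_given_seed(self):
        ds = _daily_users(10)
        a = outer_split(ds, 0.2, "random", seed=5)
        b = outer_split(ds, 0.2, "random", seed=5)
        assert a == b

    def test_signup_invariant(self):
        ds = _daily_users(10)
        split = outer_split(ds, 0.3, "signup_sorted")
        signup = ds.signup_times()
        assert max(signup[u] for u in split.train_users) <= min(
            signup[u] for u in split.test_users
        )

    def test_degenerate_test_set_rejected(self):
        ds = _daily_users(2)
        with pytest.raises(SchemaError):
            outer_split(ds, 0.9, "signup_sorted")


class TestTimeCut:
    def test_contiguous_blocks_of_near_equal_size(self):
        inst = _instance_frame(
            {"u1": [(f"2021-01-{d:02d}", 0.0) for d in range(1, 11)]}
        )
        plan = time_cut_folds(inst, k=5)
        sizes = pd.Series(plan.assignment).value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_fold_time_ordering_invariant(self):
        rng = np.random.default_rng(0)
        inst = _instance_frame(
            {
                f"u{j}": [
                    (pd.Timestamp("2021-01-01") + pd.Timedelta(hours=float(h)), 0.0)
                    for h in rng.uniform(0, 500, 7)
                ]
                for j in range(4)
            }
        )
        plan = time_cut_folds(inst, k=5)
        t_next = inst.set_index(INSTANCE_ID)[T_NEXT]
        for i in range(4):
            hi = max(t_next[x] for x, f in plan.assignment.items() if f == i)
            lo = min(t_next[x] for x, f in plan.assignment.items() if f == i + 1)
            assert hi <= lo

    def test_fewer_instances_than_folds_rejected(self):
        inst = _instance_frame({"u1": [("2021-01-01", 0.0), ("2021-01-02", 0.0)]})
        with pytest.raises(ValidationError):
            time_cut_folds(inst, k=5)


class TestUserCut:
    def test_round_robin_user_groups_disjoint(self):
        users = [f"u{j}" for j in range(10)]
        inst = _instance_frame(
            {u: [("2021-01-01", 0.0), ("2021-01-02", 0.0)] for u in users}
        )
        plan = user_cut_folds(users, inst, k=5, seed=1)
        # brute-force scan: no user id appears in two folds
        fold_users = {}
        for iid, f in plan.assignment.items():
            u = iid.rsplit("-", 1)[0]
            fold_users.setdefault(f, set()).add(u)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not (fold_users[i] & fold_users[j])
        assert sorted(len(v) for v in fold_users.values()) == [2, 2, 2, 2, 2]

    def test_fewer_users_than_folds_rejected(self):
        inst = _instance_frame({"u1": [("2021-01-01", 0.0)]})
        with pytest.raises(ValidationError):
            user_cut_folds(["u1", "u2", "u3", "u4"], inst, k=5, seed=0)

    def test_deterministic_given_seed(self):
        users = [f"u{j}" for j in range(7)]
        inst = _instance_frame({u: [("2021-01-01", 0.0)] for u in users})
        a = user_cut_folds(users, inst, k=3, seed=9)
        b = user_cut_folds(users, inst, k=3, seed=9)
        assert a.assignment == b.assignment


NUMERIC_SCHEMA = FeatureSchema((FeatureSpec("mood", "numeric"),))
CATEGORICAL_SCHEMA = FeatureSchema((FeatureSpec("mood", "categorical"),))


class TestAverageUserTransform:
    def test_expanding_median(self):
        inst = _instance_frame(
            {"u1": [("2021-01-01", 1.0), ("2021-01-02", 3.0), ("2021-01-03", 5.0)]}
        )
        out = average_user_transform(inst, NUMERIC_SCHEMA)
        assert list(out.sort_values(T_NOW)["mood"]) == [1.0, 2.0, 3.0]

    def test_expanding_mode_ties_toward_earlier_value(self):
        inst = _instance_frame(
            {"u1": [("2021-01-01", "a"), ("2021-01-02", "b"), ("2021-01-03", "b")]}
        )
        out = average_user_transform(inst, CATEGORICAL_SCHEMA)
        assert list(out.sort_values(T_NOW)["mood"]) == ["a", "a", "b"]

    def test_single_element_identity(self):
        inst = _instance_frame({"u1": [("2021-01-01", 7.0)]})
        out = average_user_transform(inst, NUMERIC_SCHEMA)
        assert list(out["mood"]) == [7.0]

    def test_targets_and_ids_unchanged(self, small_synthetic):
        inst = build_instances(impute_missing(small_synthetic))
        out = average_user_transform(inst, small_synthetic.schema)
        assert list(out[INSTANCE_ID]) == list(inst[INSTANCE_ID])
        assert list(out["target_class"]) == list(inst["target_class"])

    def test_causal_prefix_property(self):
        """Transforming a time-prefix equals the prefix of the transform."""
        rng = np.random.default_rng(4)
        inst = _instance_frame(
            {
                "u1": [
                    (pd.Timestamp("2021-01-01") + pd.Timedelta(days=i), v)
                    for i, v in enumerate(rng.normal(size=9))
                ]
            }
        )
        full = average_user_transform(inst, NUMERIC_SCHEMA)
        for cut in (1, 4, 7):
            prefix = average_user_transform(inst.iloc[:cut], NUMERIC_SCHEMA)
            assert list(prefix["mood"]) == list(full["mood"][:cut])


class TestUserWise:
    def _inst_with_assessments(self, n_assess):
        return _instance_frame(
            {
                "u1": [
                    (pd.Timestamp("2021-01-01") + pd.Timedelta(days=i), 0.0)
                    for i in range(n_assess - 1)  # m assessments → m-1 instances
                ]
            }
        )

    @pytest.mark.parametrize("n_assess,n_train,n_test", [(10, 7, 2), (15, 11, 3)])
    def test_temporal_80_20_split(self, n_assess, n_train, n_test):
        inst = self._inst_with_assessments(n_assess)
        plan = user_wise_split(inst, 10)
        tr, te = plan.per_user_splits["u1"]
        assert (len(tr), len(te)) == (n_train, n_test)
        # training part strictly precedes the test part in time
        t_now = inst.set_index(INSTANCE_ID)[T_NOW]
        assert max(t_now[i] for i in tr) < min(t_now[i] for i in te)

    def test_user_below_threshold_excluded(self):
        inst = pd.concat(
            [
                self._inst_with_assessments(9),
                _instance_frame(
                    {
                        "u2": [
                            (pd.Timestamp("2021-02-01") + pd.Timedelta(days=i), 0.0)
                            for i in range(11)
                        ]
                    }
                ),
            ]
        )
        plan = user_wise_split(inst, 10)
        assert set(plan.per_user_splits) == {"u2"}

    def test_no_user_meets_threshold_is_error(self):
        with pytest.raises(ValidationError):
            user_wise_split(self._inst_with_assessments(5), 10)
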