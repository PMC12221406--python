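"""Replicate-count rule, penalized fits vs closed form, threshold, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcnet.preprocessing import FeatureTable
from sarcnet.selection import (
    BootstrapResult,
    ModelSpec,
    SelectionSummary,
    bootstrap_select,
    fit_penalized,
    replicate_count,
    selection_threshold,
    summarize_selected,
)

SPEC_REG = ModelSpec(variant="all_data", outcome="BATT", outcome_horizon="d7",
                     predictor_timepoint="h48")
SPEC_CLS = ModelSpec(variant="all_data", outcome="SarcAny", outcome_horizon="d7",
                     predictor_timepoint="h48")


def table_from_arrays(X, y, task="regression", forced=()):
    cols = [f"x{i}" for i in range(X.shape[1])]
    Xdf = pd.DataFrame(X, columns=cols)
    for i in forced:
        Xdf = Xdf.rename(columns={f"x{i}": "forced"})
    return FeatureTable(X=Xdf, y=pd.Series(y), task=task,
                        forced=["forced"] if forced else [],
                        kinds={c: "numeric" for c in Xdf.columns})


class TestReplicateCount:
    @pytest.mark.parametrize("n,b", [(1, 20), (10, 20), (5, 20), (79, 70),
                                     (45, 45), (200, 70)])
    def test_anchors_and_clamps(self, n, b):
        assert replicate_count(n) == b

    def test_monotone_nondecreasing(self):
        values = [replicate_count(n) for n in range(1, 200)]
        assert values == sorted(values)
        assert min(values) == 20 and max(values) == 70


def orthonormal_design(n=5, p=3, seed=4):
    """Columns orthonormal and orthogonal to the intercept."""
    rng = np.random.default_rng(seed)
    M = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    Q, _ = np.linalg.qr(M)
    return Q[:, 1:]


class TestPenalizedFit:
    def test_matches_soft_threshold_on_orthonormal_design(self):
        """With a fixed penalty and X'X = I the lasso solution is the
        soft-thresholded least-squares estimate."""
        n, p = 5, 3
        X = orthonormal_design(n, p)
        rng = np.random.default_rng(7)
        y = rng.normal(size=n)
        z = X.T @ (y - y.mean())
        for lam in (0.01, 0.05, 0.2):
            coefs, _ = fit_penalized(X, y, task="regression", lambda_=lam)
            expected = np.sign(z) * np.maximum(np.abs(z) - n * lam, 0.0)
            assert np.allclose(coefs, expected, atol=1e-8)

    def test_infinite_penalty_zeroes_all_penalized(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6))
        y_reg = rng.normal(size=30)
        coefs, _ = fit_penalized(X, y_reg, task="regression", lambda_=1e6)
        assert np.all(coefs == 0.0)
        y_cls = (rng.random(30) < 0.5).astype(float)
        coefs, _ = fit_penalized(X, y_cls, task="classification", lambda_=1e6)
        assert np.all(coefs == 0.0)

    def test_forced_covariate_survives_large_penalty_regression(self):
        rng = np.random.default_rng(2)
        n = 120
        X = rng.normal(size=(n, 5))
        y = 2.0 * X[:, 0] + 0.05 * rng.normal(size=n)  # signal only in forced
        coefs, _ = fit_penalized(X, y, task="regression", forced_idx=[0],
                                 lambda_=10.0)
        assert coefs[0] == pytest.approx(2.0, abs=0.05)
        assert np.all(coefs[1:] == 0.0)

    def test_forced_covariate_survives_large_penalty_classification(self):
        rng = np.random.default_rng(3)
        n = 300
        X = rng.normal(size=(n, 5))
        X[:, 0] = (rng.random(n) < 0.5).astype(float)
        p = 1.0 / (1.0 + np.exp(-(-1.0 + 2.5 * X[:, 0])))
        y = (rng.random(n) < p).astype(float)
        coefs, _ = fit_penalized(X, y, task="classification", forced_idx=[0],
                                 lambda_=1.0)
        assert coefs[0] > 0.5
        assert np.all(coefs[1:] == 0.0)

    def test_cv_fit_is_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 8))
        y = X[:, 1] - X[:, 2] + rng.normal(scale=0.5, size=40)
        a, _ = fit_penalized(X, y, task="regression", seed=9)
        b, _ = fit_penalized(X, y, task="regression", seed=9)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("task", ["regression", "classification"])
    def test_one_se_rule_is_sparser_than_min(self, task):
        rng = np.random.default_rng(15)
        n, p = 80, 20
        X = rng.normal(size=(n, p))
        lin = 0.9 * X[:, 0] + rng.normal(size=n)
        if task == "regression":
            y = (lin - lin.mean()) / lin.std()
        else:
            y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        c_min, _ = fit_penalized(X, y, task=task, seed=3, lambda_rule="min")
        c_1se, _ = fit_penalized(X, y, task=task, seed=3, lambda_rule="1se")
        assert (c_1se != 0).sum() <= (c_min != 0).sum()

    def test_unknown_lambda_rule_rejected(self):
        X = np.eye(4)
        with pytest.raises(ValueError, match="lambda_rule"):
            fit_penalized(X, np.ones(4), task="regression", lambda_rule="2se")

    def test_single_class_outcome_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="single-class"):
            fit_penalized(X, np.ones(10), task="classification")


class TestBootstrap:
    def test_determinism_and_count_invariants(self):
        rng = np.random.default_rng(8)
        n = 60
        X = rng.normal(size=(n, 6))
        X[:, 0] = (rng.random(n) < 0.4).astype(float)
        y = 0.8 * X[:, 1] + rng.normal(scale=0.8, size=n)
        table = table_from_arrays(
            (X - X.mean(0)) / X.std(0), (y - y.mean()) / y.std(), forced=[0])
        a = bootstrap_select(table, SPEC_REG, master_seed=77)
        b = bootstrap_select(table, SPEC_REG, master_seed=77)
        assert a.selection_counts == b.selection_counts
        assert a.coefficient_draws == b.coefficient_draws
        assert a.n_replicates == replicate_count(n)
        for f, c in a.selection_counts.items():
            assert c == len(a.coefficient_draws[f])
            assert 0 <= c <= a.n_replicates
        assert "forced" not in a.selection_counts
        assert len(a.forced_coefficients["forced"]) == a.n_replicates - a.n_discarded

    def test_stratified_bootstrap_avoids_single_class_replicates(self):
        rng = np.random.default_rng(9)
        n = 30
        X = rng.normal(size=(n, 4))
        y = np.r_[np.ones(4), np.zeros(n - 4)]  # rare positive class
        table = table_from_arrays(X, y, task="classification")
        res = bootstrap_select(table, SPEC_CLS, master_seed=5, stratify=True)
        assert res.n_discarded == 0

    def test_strong_planted_feature_beats_nulls(self):
        rng = np.random.default_rng(10)
        n = 150
        X = rng.normal(size=(n, 10))
        y = 1.0 * X[:, 3] + rng.normal(size=n)
        table = table_from_arrays((X - X.mean(0)) / X.std(0),
                                  (y - y.mean()) / y.std())
        res = bootstrap_select(table, SPEC_REG, master_seed=6)
        target = res.selection_counts["x3"]
        others = [c for f, c in res.selection_counts.items() if f != "x3"]
        assert target > max(others)


class TestThreshold:
    @pytest.mark.parametrize("counts,expected", [
        ([10, 30, 35, 40, 70], 55.0),
        ([0, 0, 0, 60], 37.5),
        ([7, 7, 7, 7], 7.0),
    ])
    def test_hand_computed(self, counts, expected):
        assert selection_threshold(counts) == pytest.approx(expected)

    def test_accepts_mapping(self):
        assert selection_threshold({"a": 10, "b": 30, "c": 35, "d": 40,
                                    "e": 70}) == 55.0

    @given(st.lists(st.integers(0, 70), min_size=1, max_size=40))
    @settings(max_examples=200)
    def test_threshold_between_q3_and_max(self, counts):
        thr = selection_threshold(counts)
        q3 = float(np.percentile(counts, 75))
        assert q3 - 1e-12 <= thr <= max(counts) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            selection_threshold([])


def make_result(counts, draws):
    return BootstrapResult(
        spec=SPEC_REG, n_rows=40, n_replicates=70, selection_counts=counts,
        coefficient_draws=draws, forced_coefficients={}, seeds=[])


class TestSummaries:
    def test_mean_and_small_sample_ci(self):
        counts = {"a": 60, "b": 15, "c": 0, "d": 0}
        draws = {"a": [0.5, 0.7, 0.9], "b": [0.1] * 15, "c": [], "d": []}
        out = summarize_selected(make_result(counts, draws))
        # threshold = (60 + Q3([0,0,15,60]))/2 = (60 + 26.25)/2 = 43.125
        assert [s.feature for s in out] == ["a"]
        s = out[0]
        assert s.mean_coefficient == pytest.approx(0.7)
        assert (s.ci_low, s.ci_high) == (0.5, 0.9)  # <4 draws: [min, max]
        assert s.selected_count == 60

    def test_count_equal_to_threshold_excluded(self):
        counts = {"a": 50, "b": 50, "c": 50}  # threshold = 50 exactly
        draws = {k: [0.4] * 50 for k in counts}
        assert summarize_selected(make_result(counts, draws)) == []

    def test_constant_draws_degenerate_ci(self):
        counts = {"a": 60, "b": 0, "c": 0, "d": 0, "e": 0}
        draws = {"a": [0.4] * 60, "b": [], "c": [], "d": [], "e": []}
        (s,) = summarize_selected(make_result(counts, draws))
        assert s.mean_coefficient == pytest.approx(0.4)
        assert (s.ci_low, s.ci_high) == (0.4, 0.4)

    def test_percentile_ci_with_enough_draws(self):
        draws_a = list(np.linspace(-1.0, 1.0, 41))
        counts = {"a": 41, "b": 0, "c": 0, "d": 0}
        draws = {"a": draws_a, "b": [], "c": [], "d": []}
        (s,) = summarize_selected(make_result(counts, draws))
        lo, hi = np.percentile(draws_a, [2.5, 97.5])
        assert s.ci_low == pytest.approx(lo)
        assert s.ci_high == pytest.approx(hi)
        assert s.ci_low <= s.mean_coefficient <= s.ci_high

    def test_sorted_by_magnitude(self):
        counts = {"a": 60, "b": 65, "c": 0, "d": 0, "e": 0, "f": 0, "g": 0}
        draws = {"a": [-0.9] * 60, "b": [0.2] * 65, "c": [], "d": [], "e": [],
                 "f": [], "g": []}
        out = summarize_selected(make_result(counts, draws))
        assert [s.feature for s in out] == ["a", "b"]


class TestModelSpec:
    def test_task_follows_outcome(self):
        assert SPEC_CLS.task == "classification"
        assert SPEC_REG.task == "regression"

    def test_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(variant="all_data", outcome="SarcAny",
                      outcome_horizon="d7", predictor_timepoint="h48",
                      penalty="lasso", mixing=0.5)
        with pytest.raises(ValueError):
            ModelSpec(variant="bogus", outcome="SarcAny",
                      outcome_horizon="d7", predictor_timepoint="h48")

    def test_retrodictive_flag(self):
        late = ModelSpec(variant="all_data", outcome="SarcAny",
                         outcome_horizon="d7", predictor_timepoint="w13")
        assert late.retrodictive and not SPEC_CLS.retrodictive
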