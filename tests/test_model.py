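"""Splitting, Bayesian optimization, model fitting, evaluation, export."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ictsib.errors import (
    DomainError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from ictsib.model import (
    BOConfig,
    ConditionModel,
    Param,
    TrainingRow,
    TrainingTable,
    bayesian_optimize,
    evaluate_model,
    export_linear_formula,
    fit_condition_model,
    load_linear_formula,
    predict_si,
    split_dataset,
)
from ictsib.types import FEATURE_NAMES, Condition, SwayFeatures


def make_table(n_subjects, link, seed=0, condition=Condition.EO_FIRM, noise_sd=0.0):
    """Training table with randomized complete feature vectors and y = link(features)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        vals = dict(zip(FEATURE_NAMES, rng.uniform(0.5, 2.0, len(FEATURE_NAMES))))
        feats = SwayFeatures(**vals)
        y = link(feats) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        rows.append(TrainingRow(f"S{i:03d}", condition, feats, max(y, 0.0)))
    return TrainingTable(rows=rows, source="test")


class TestSplitDataset:
    def _table(self, n):
        return make_table(n, lambda f: 1.0)

    def test_103_subjects_split_72_31(self):
        train, test = split_dataset(self._table(103), 0.7, seed=0)
        assert len(train.subjects()) == 72
        assert len(test.subjects()) == 31

    def test_two_subjects_half(self):
        train, test = split_dataset(self._table(2), 0.5, seed=0)
        assert len(train.subjects()) == 1
        assert len(test.subjects()) == 1

    def test_deterministic(self):
        t = self._table(20)
        a = split_dataset(t, 0.7, seed=5)
        b = split_dataset(t, 0.7, seed=5)
        assert a[0].subjects() == b[0].subjects()

    def test_bad_fraction(self):
        with pytest.raises(DomainError):
            split_dataset(self._table(5), 1.2, seed=0)

    @given(st.integers(0, 50))
    def test_subjects_disjoint_and_complete(self, seed):
        t = self._table(17)
        train, test = split_dataset(t, 0.7, seed=seed)
        a, b = set(train.subjects()), set(test.subjects())
        assert a.isdisjoint(b)
        assert a | b == set(t.subjects())


class TestBayesianOptimize:
    def test_degenerate_space_single_eval(self):
        calls = []

        def obj(p):
            calls.append(p)
            return p["h"] ** 2

        space = (Param("h", "uniform", 0.5, 0.5),)
        res = bayesian_optimize(obj, space, BOConfig(seed=1))
        assert res.best_params["h"] == 0.5
        assert len(calls) == 1

    def test_quadratic_optimum_found(self):
        space = (Param("h", "uniform", 0.0, 1.0),)
        res = bayesian_optimize(
            lambda p: (p["h"] - 0.3) ** 2, space, BOConfig(n_iterations=30, seed=3)
        )
        assert abs(res.best_params["h"] - 0.3) < 0.05

    def test_deterministic_trace(self):
        space = (Param("h", "log_uniform", 1e-3, 1e3),)
        f = lambda p: (math.log10(p["h"]) - 1.0) ** 2
        r1 = bayesian_optimize(f, space, BOConfig(n_iterations=10, seed=9))
        r2 = bayesian_optimize(f, space, BOConfig(n_iterations=10, seed=9))
        assert r1.best_params == r2.best_params
        assert r1.trace == r2.trace

    def test_integer_param(self):
        space = (Param("k", "integer", 2, 12),)
        res = bayesian_optimize(
            lambda p: (p["k"] - 7) ** 2, space, BOConfig(n_iterations=15, seed=2)
        )
        assert isinstance(res.best_params["k"], (int, np.integer))
        assert abs(res.best_params["k"] - 7) <= 1


def linear_link(f: SwayFeatures) -> float:
    # weights on identifiable (non-duplicated) coordinates only
    return 2.0 * f.mean_cm - 1.0 * f.mean_distance_cm + 3.0


class TestFitConditionModel:
    def test_noiseless_linear_recovery(self):
        table = make_table(40, linear_link, seed=1)
        m = fit_condition_model(table, "linear")
        beta = dict(zip(FEATURE_NAMES, m.beta))
        assert beta["mean_cm"] == pytest.approx(2.0, abs=1e-3)
        assert beta["mean_distance_cm"] == pytest.approx(-1.0, abs=1e-3)
        others = [v for k, v in beta.items() if k not in ("mean_cm", "mean_distance_cm")]
        assert np.max(np.abs(others)) < 1e-3
        assert m.bias == pytest.approx(3.0, abs=5e-3)

    def test_constant_target_intercept_only(self):
        table = make_table(15, lambda f: 5.0)
        with pytest.warns(UserWarning):
            m = fit_condition_model(table, "linear")
        np.testing.assert_allclose(m.beta, 0.0, atol=1e-12)
        assert m.bias == pytest.approx(5.0, abs=1e-12)

    def test_tree_step_function_leaf_means(self):
        # y depends on mean_cm via a two-level step; a depth-limited tree
        # predicts the two leaf means exactly
        def step(f):
            return 1.0 if f.mean_cm < 1.25 else 4.0

        table = make_table(60, step, seed=4)
        m = fit_condition_model(
            table, "tree", bo=BOConfig(n_iterations=8, n_initial=5, seed=0)
        )
        X, y = table.to_arrays()
        pred = m.predict_array(X)
        for lo in (1.0, 4.0):
            sel = y == lo
            np.testing.assert_allclose(pred[sel], lo, atol=1e-9)

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            fit_condition_model(make_table(5, linear_link), "linear")

    def test_unknown_model_type(self):
        with pytest.raises(DomainError):
            fit_condition_model(make_table(12, linear_link), "boosted")

    def test_svm_and_gam_fit(self):
        table = make_table(30, linear_link, seed=6, noise_sd=0.05)
        for mt in ("svm", "gam"):
            m = fit_condition_model(
                table, mt, bo=BOConfig(n_iterations=4, n_initial=4, seed=0)
            )
            ev = evaluate_model(m, table)
            assert ev.r > 0.8


class TestPredict:
    def test_training_mean_gives_mean_prediction(self):
        table = make_table(25, linear_link, seed=2)
        m = fit_condition_model(table, "linear")
        X, y = table.to_arrays()
        mean_feats = SwayFeatures.from_dict(dict(zip(FEATURE_NAMES, X.mean(axis=0))))
        assert predict_si(m, mean_feats) == pytest.approx(float(y.mean()), abs=1e-3)

    def test_missing_feature_rejected(self):
        table = make_table(12, linear_link)
        m = fit_condition_model(table, "linear")
        with pytest.raises(Exception):
            predict_si(m, SwayFeatures())  # all-NaN features

    def test_new_point_exact_linear_value(self):
        table = make_table(30, linear_link, seed=8)
        m = fit_condition_model(table, "linear")
        f = SwayFeatures(**dict(zip(FEATURE_NAMES, np.linspace(0.6, 1.9, 10))))
        assert predict_si(m, f) == pytest.approx(linear_link(f), abs=1e-3)


class TestEvaluate:
    def _table_from_vectors(self, y):
        rng = np.random.default_rng(0)
        rows = []
        for i, yi in enumerate(y):
            feats = SwayFeatures(
                **dict(zip(FEATURE_NAMES, rng.uniform(0.5, 2.0, 10)))
            )
            rows.append(TrainingRow(f"S{i}", Condition.EO_FIRM, feats, float(yi)))
        return TrainingTable(rows=rows, source="test")

    def test_pearson_oracle(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 7.0])
        # brute-force formula oracle
        oracle = float(
            np.sum((a - a.mean()) * (b - b.mean()))
            / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
        r, _ = stats.pearsonr(a, b)
        assert r == pytest.approx(oracle, abs=1e-12)
        assert oracle == pytest.approx(0.9934, abs=1e-4)

    def test_identity_predictions_r1(self):
        table = make_table(12, linear_link, seed=3)
        m = fit_condition_model(table, "linear")
        ev = evaluate_model(m, table)
        assert ev.r == pytest.approx(1.0, abs=1e-9)
        assert ev.rmse == pytest.approx(0.0, abs=1e-6)

    def test_anti_predictions_r_minus1(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred = -y + 10.0
        r, _ = stats.pearsonr(y, pred)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_constant_vector_undefined(self):
        table = self._table_from_vectors([2.0, 2.0, 2.0, 2.0])
        m = ConditionModel(
            condition=Condition.EO_FIRM, model_type="linear", hyperparams={},
            feature_mean=np.zeros(10), feature_sd=np.ones(10),
            beta=np.zeros(10), bias=2.0,
        )
        with pytest.raises(UndefinedCorrelationError):
            evaluate_model(m, table)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_pearson_affine_invariance(self, a, b):
        x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 7.0, 11.0])
        r0, _ = stats.pearsonr(x, y)
        r1, _ = stats.pearsonr(x, a * y + b)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestExport:
    def test_seven_condition_export_round_trip(self, tmp_path):
        models = {}
        for cond in Condition:
            table = make_table(20, linear_link, seed=hash(cond.value) % 1000,
                               condition=cond)
            models[cond] = fit_condition_model(table, "linear")
        p = tmp_path / "formula.json"
        export_linear_formula(models, p)
        back = load_linear_formula(p)
        assert len(back) == 7
        f = SwayFeatures(**dict(zip(FEATURE_NAMES, np.linspace(0.7, 1.8, 10))))
        for cond in Condition:
            assert predict_si(back[cond], f) == pytest.approx(
                predict_si(models[cond], f), abs=1e-9
            )

    def test_non_linear_rejected(self, tmp_path):
        table = make_table(20, linear_link, seed=5)
        m = fit_condition_model(
            table, "tree", bo=BOConfig(n_iterations=3, n_initial=3, seed=0)
        )
        with pytest.raises(TypeError):
            export_linear_formula({Condition.EO_FIRM: m}, tmp_path / "f.json")

    def test_intercept_only_export(self, tmp_path):
        table = make_table(15, lambda f: 5.0)
        with pytest.warns(UserWarning):
            m = fit_condition_model(table, "linear")
        p = tmp_path / "f.json"
        export_linear_formula({Condition.EO_FIRM: m}, p)
        back = load_linear_formula(p)[Condition.EO_FIRM]
        np.testing.assert_allclose(back.beta, 0.0, atol=1e-12)
        assert back.bias == pytest.approx(5.0, abs=1e-12)


class TestRidgePath:
    def test_beta_norm_monotone_in_penalty(self):
        from sklearn.linear_model import Ridge

        table = make_table(40, linear_link, seed=9, noise_sd=0.1)
        X, y = table.to_arrays()
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        norms = []
        for alpha in [1e-3, 1e-1, 1e1, 1e3, 1e5]:
            r = Ridge(alpha=alpha).fit(Xs, y)
            norms.append(float(np.linalg.norm(r.coef_)))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0] + 1e-9
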