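"""Correlation pruning, standardized OLS, LOO q2, refinement, splits and
the published fixed-coefficient predictors."""

import json

import numpy as np
import pandas as pd
import pytest

from permqspr.qspr import (
    LinearQSPRModel,
    PUBLISHED_MODELS,
    cross_correlation_filter,
    drop_rank_deficient,
    fit_linear,
    loo_q2,
    predict_published,
    r2_test,
    refine,
    representative_split,
)
from permqspr.synth import StudyDesign, sparse_linear_dataset


class TestCrossCorrelationFilter:
    def test_duplicated_column_tie_removes_lexicographically_later(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(25)
        X = pd.DataFrame({"copyB": base, "copyA": base, "other": rng.standard_normal(25)})
        y = 0.9 * base + 0.1 * rng.standard_normal(25)
        retained, log = cross_correlation_filter(X, y)
        assert retained == ["copyA", "other"]
        assert len(log) == 1 and log[0]["removed"] == "copyB"

    def test_member_less_correlated_with_response_is_removed(self):
        rng = np.random.default_rng(1)
        n = 200
        x1 = rng.standard_normal(n)
        x2 = 0.95 * x1 + np.sqrt(1 - 0.95**2) * rng.standard_normal(n)
        y = 0.8 * x1 + 0.6 * rng.standard_normal(n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        assert abs(np.corrcoef(x1, x2)[0, 1]) > 0.9
        retained, log = cross_correlation_filter(X, y)
        assert retained == ["x1"]
        assert log[0]["removed"] == "x2"

    def test_uncorrelated_matrix_is_identity(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((100, 4)), columns=list("abcd"))
        y = rng.standard_normal(100)
        retained, log = cross_correlation_filter(X, y)
        assert retained == list("abcd")
        assert log == []

    def test_no_surviving_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((50, 3))
        mix = rng.uniform(-1, 1, size=(3, 8))
        X = pd.DataFrame(z @ mix + 0.3 * rng.standard_normal((50, 8)),
                         columns=[f"d{i}" for i in range(8)])
        y = rng.standard_normal(50)
        retained, _ = cross_correlation_filter(X, y, threshold=0.70)
        corr = X[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.70 + 1e-12

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="constant"):
            cross_correlation_filter(X, [1.0, 2, 3, 4])


class TestFitLinear:
    def test_exact_linear_data(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["x1", "x2"])
        y = 2 * X["x1"] - X["x2"]
        model = fit_linear(X, y)
        assert model.r2_train == pytest.approx(1.0, abs=1e-12)
        # standardized coefficients keep the planted 2:-1 ratio
        b1, b2 = model.coefficients
        ratio = (b1 / X["x1"].std(ddof=1)) / (b2 / X["x2"].std(ddof=1))
        assert ratio == pytest.approx(-2.0, rel=1e-9)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        y = rng.standard_normal(40)
        model = fit_linear(X, y)
        z = (X - X.mean()) / X.std(ddof=1)
        ref = sm.OLS(y, sm.add_constant(z)).fit()
        assert model.intercept == pytest.approx(ref.params["const"], rel=1e-9)
        assert np.allclose(model.coefficients, ref.params[list("abc")], rtol=1e-9)
        assert model.r2_train == pytest.approx(ref.rsquared, rel=1e-9)

    def test_single_predictor_coefficient_is_correlation(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        model = fit_linear(pd.DataFrame({"x": x}), y)
        r = np.corrcoef(x, y)[0, 1]
        # standardized slope = r * sd(y)
        assert model.coefficients[0] == pytest.approx(r * np.std(y, ddof=1), rel=1e-9)

    def test_orthogonal_response_r2_near_zero_and_q2_below(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        y = rng.standard_normal(30)
        model = fit_linear(X, y)
        assert model.r2_train < 0.4
        assert loo_q2(X, y) <= model.r2_train

    def test_rank_deficient_design_names_collinear_terms(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(20)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(20)})
        with pytest.raises(ValueError, match="a.*b|collinear"):
            fit_linear(X, rng.standard_normal(20))

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="training rows"):
            fit_linear(X, [1.0, 2.0, 3.0])


class TestLooQ2:
    def test_noiseless_data_q2_is_one(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((15, 2)), columns=["u", "v"])
        y = 3 * X["u"] + X["v"] + 1.0
        assert loo_q2(X, y) == pytest.approx(1.0, abs=1e-10)

    def test_random_response_mean_q2_negative(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
            vals.append(loo_q2(X, rng.standard_normal(20)))
        assert np.mean(vals) < 0

    def test_equals_independent_refit_oracle(self):
        sk_lm = pytest.importorskip("sklearn.linear_model")
        sk_pp = pytest.importorskip("sklearn.preprocessing")
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 12
            X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
            y = X["a"].to_numpy() + 0.5 * rng.standard_normal(n)
            press = 0.0
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                scaler = sk_pp.StandardScaler().fit(X[mask])
                lm = sk_lm.LinearRegression().fit(scaler.transform(X[mask]), y[mask])
                pred = lm.predict(scaler.transform(X.iloc[[i]]))[0]
                press += (y[i] - pred) ** 2
            expected = 1 - press / np.sum((y - y.mean()) ** 2)
            assert loo_q2(X, y) == pytest.approx(expected, abs=1e-10)


class TestRefine:
    def test_noiseless_planted_model_stops_at_true_support(self):
        X, y, truth = sparse_linear_dataset(n=30, n_true=3, n_decoy=7, sigma=0.0, seed=0)
        model = refine(fit_linear(X, y), X, y)
        assert set(model.terms) == set(truth["betas"])
        assert model.r2_train == pytest.approx(1.0, abs=1e-10)
        assert model.q2_loo == pytest.approx(1.0, abs=1e-8)

    def test_unbounded_tolerances_reduce_to_single_term(self):
        X, y, _ = sparse_linear_dataset(n=25, n_true=2, n_decoy=4, sigma=0.3, seed=1)
        model = refine(fit_linear(X, y), X, y, prox_tol=np.inf, max_r2_drop=np.inf)
        assert len(model.terms) == 1
        # p - 1 removals plus the initial state are on the trace
        assert len(model.refinement_trace) == X.shape[1]

    def test_term_names_stable_under_removal(self):
        X, y, _ = sparse_linear_dataset(n=30, n_true=3, n_decoy=5, sigma=0.1, seed=2)
        model = refine(fit_linear(X, y), X, y)
        for step in model.refinement_trace:
            assert [t for t in X.columns if t in step["terms"]] == step["terms"]

    def test_trace_records_r2_and_q2_per_step(self):
        X, y, _ = sparse_linear_dataset(n=30, n_true=2, n_decoy=4, sigma=0.2, seed=3)
        model = refine(fit_linear(X, y), X, y)
        for step in model.refinement_trace:
            assert -5 < step["q2"] <= step["r2"] <= 1


class TestRepresentativeSplit:
    def test_full_factorial_coverage(self):
        data = StudyDesign().rows()
        labels = representative_split(data, test_size=6, seed=17)
        test = data[labels == "test"]
        assert len(test) == 6
        assert set(test["permeant"]) == set(data["permeant"])
        assert set(test["membrane"]) == set(data["membrane"])
        assert len(set(test["vehicle"])) >= 3
        train = data[labels == "train"]
        for f in ("permeant", "vehicle", "membrane"):
            assert set(train[f]) == set(data[f])

    def test_deterministic_for_seed(self):
        data = StudyDesign().rows()
        a = representative_split(data, test_size=6, seed=5)
        b = representative_split(data, test_size=6, seed=5)
        assert a.equals(b)

    def test_zero_test_size_rejected(self):
        with pytest.raises(ValueError, match="test_size"):
            representative_split(StudyDesign().rows(), test_size=0)

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError, match="metadata"):
            representative_split(pd.DataFrame({"x": [1, 2, 3]}), test_size=1)


class TestPublishedModels:
    def test_kp_model_intercept_at_zero_input(self):
        inputs = {k: 0.0 for k in PUBLISHED_MODELS["eq2"]["coefficients"]}
        assert predict_published("eq2", inputs) == pytest.approx(0.6976, abs=1e-12)

    def test_flux_model_intercept_at_zero_input(self):
        inputs = {k: 0.0 for k in PUBLISHED_MODELS["eq3"]["coefficients"]}
        assert predict_published("eq3", inputs) == pytest.approx(1.08083, abs=1e-12)

    def test_affine_in_inputs(self):
        rng = np.random.default_rng(10)
        names = list(PUBLISHED_MODELS["eq2"]["coefficients"])
        a = {k: rng.normal() for k in names}
        b = {k: rng.normal() for k in names}
        ab = {k: a[k] + b[k] for k in names}
        intercept = PUBLISHED_MODELS["eq2"]["intercept"]
        lhs = predict_published("eq2", ab) - predict_published("eq2", a) \
            - predict_published("eq2", b) + intercept
        assert lhs == pytest.approx(0.0, abs=1e-9)

    def test_missing_input_and_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            predict_published("eq2", {"solubility": 1.0})
        with pytest.raises(KeyError, match="unknown"):
            predict_published("eq9", {})

    def test_coefficients_survive_json_round_trip_bitwise(self):
        blob = json.dumps(PUBLISHED_MODELS)
        assert json.loads(blob) == PUBLISHED_MODELS


class TestModelSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        X, y, _ = sparse_linear_dataset(n=20, n_true=2, n_decoy=2, sigma=0.1, seed=4)
        model = fit_linear(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        with open(path) as fh:
            clone = LinearQSPRModel.from_dict(json.load(fh))
        assert np.allclose(clone.predict(X), model.predict(X), atol=1e-12)


class TestDropRankDeficient:
    def test_level_based_columns_pruned_to_full_rank(self):
        # 12 rows over 4 levels: any >3 centered level-based columns are
        # linearly dependent
        rng = np.random.default_rng(6)
        levels = np.repeat(np.arange(4), 3)
        X = pd.DataFrame(
            {f"lv{i}": rng.permutation([10, 20, 30, 40])[levels] for i in range(6)}
        )
        kept = drop_rank_deficient(X)
        assert len(kept) == 3
        z = (X[kept] - X[kept].mean()) / X[kept].std(ddof=1)
        assert np.linalg.matrix_rank(np.column_stack([np.ones(12), z])) == 4

    def test_full_rank_input_unchanged(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((20, 5)), columns=list("abcde"))
        assert drop_rank_deficient(X) == list("abcde")


def test_r2_test_variants():
    X, y, _ = sparse_linear_dataset(n=40, n_true=2, n_decoy=2, sigma=0.2, seed=5)
    model = fit_linear(X.iloc[:30], y[:30])
    pearson = r2_test(model, X.iloc[30:], y[30:])
    predictive = r2_test(model, X.iloc[30:], y[30:], predictive=True)
    assert 0 <= pearson <= 1
    assert predictive <= pearson + 1e-9
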