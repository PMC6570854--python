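"""Tests for the all-subsets AICc multimodel-inference engine."""

import numpy as np
import pandas as pd
import pytest

from leafspectra import (
    PredictorSchema,
    aicc,
    akaike_weights,
    average_coefficients,
    confidence_set,
    enumerate_models,
    fit_subset,
    relative_contributions,
    run_mmi,
    standardize_predictors,
    variable_importance,
)
from leafspectra.mmi import DegenerateInputError, ModelSet, SmallSampleError

from _oracles import brute_force_chain, ols_pinv


def random_instance(rng, n=40, p=4, betas=None):
    X = rng.normal(size=(n, p))
    betas = np.zeros(p) if betas is None else np.asarray(betas, float)
    y = 1.0 + X @ betas + rng.normal(size=n)
    return X, y


class TestStandardize:
    def test_zero_mean_unit_sd(self, default_bundle):
        z, transform = standardize_predictors(
            default_bundle.environment_table,
            columns=["mat", "map", "nutrients"],
        )
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)
        assert set(transform.columns) == {"mean", "sd"}

    def test_idempotent(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        z1, _ = standardize_predictors(frame)
        z2, _ = standardize_predictors(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_constant_column_named_in_error(self):
        frame = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(DegenerateInputError, match="flat"):
            standardize_predictors(frame)


class TestFitSubset:
    def test_empty_mask_is_null_model(self, rng):
        X, y = random_instance(rng)
        rss, coef = fit_subset(X, y, [False] * 4)
        assert rss == pytest.approx(float(((y - y.mean()) ** 2).sum()))
        assert coef[0] == pytest.approx(y.mean())

    def test_exact_linear_response_has_zero_rss(self, rng):
        X = rng.normal(size=(20, 3))
        y = 2.0 + X @ [1.0, -2.0, 0.5]
        rss, _ = fit_subset(X, y, [True, True, True])
        assert rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_pseudoinverse_oracle(self, rng):
        X, y = random_instance(rng, n=30, p=3, betas=[1.0, 0.0, -0.5])
        rss, coef = fit_subset(X, y, [True, False, True])
        rss_o, coef_o, _ = ols_pinv(X, y, (0, 2))
        assert rss == pytest.approx(rss_o, rel=1e-8)
        np.testing.assert_allclose(coef, coef_o, atol=1e-8)


class TestAicc:
    def test_direct_evaluation(self):
        # n ln(1) + 2*3 + 2*3*4/16
        assert aicc(20, 3, 20.0) == pytest.approx(7.5)

    def test_doubling_rss_adds_n_log2(self):
        assert aicc(50, 4, 2.0) - aicc(50, 4, 1.0) == pytest.approx(50 * np.log(2))

    def test_small_sample_guard(self):
        with pytest.raises(SmallSampleError):
            aicc(4, 3, 1.0)

    def test_zero_rss_guard(self):
        with pytest.raises(DegenerateInputError):
            aicc(20, 3, 0.0)


class TestEnumeration:
    def test_two_predictors_give_four_models(self, rng):
        X, y = random_instance(rng, p=2)
        assert len(enumerate_models(X, y)) == 4

    def test_ranking_matches_brute_force(self, rng):
        X, y = random_instance(rng, n=40, p=4, betas=[1.5, 0, 0, -1])
        model_set = enumerate_models(X, y)
        oracle = brute_force_chain(X, y)
        np.testing.assert_allclose(model_set.aicc, oracle["aicc_sorted"], rtol=1e-10)
        np.testing.assert_array_equal(model_set.masks, oracle["masks_sorted"])
        np.testing.assert_allclose(model_set.weight, oracle["weights_sorted"], atol=1e-12)

    def test_zero_variance_response_rejected(self, rng):
        X, _ = random_instance(rng)
        with pytest.raises(DegenerateInputError):
            enumerate_models(X, np.ones(40))


class TestWeights:
    def _toy_set(self, aicc_values):
        m = len(aicc_values)
        return ModelSet(
            names=("x0",), masks=np.zeros(m, dtype=np.int64), k=np.full(m, 2),
            rss=np.ones(m), aicc=np.asarray(aicc_values, float),
            coef=np.zeros((m, 2)), coef_var=np.zeros((m, 2)), n=10,
        )

    def test_equal_aicc_split_evenly(self):
        ms = akaike_weights(self._toy_set([5.0, 5.0]))
        np.testing.assert_allclose(ms.weight, [0.5, 0.5])

    def test_delta_two_closed_form(self):
        ms = akaike_weights(self._toy_set([0.0, 2.0]))
        expected = np.array([1.0, np.exp(-1.0)])
        np.testing.assert_allclose(ms.weight, expected / expected.sum(), rtol=1e-12)

    def test_weights_sum_to_one(self, rng):
        X, y = random_instance(rng, p=5)
        ms = enumerate_models(X, y)
        assert ms.weight.sum() == pytest.approx(1.0, abs=1e-12)


class TestConfidenceSet:
    def _weighted_set(self, weights):
        m = len(weights)
        ms = ModelSet(
            names=("x0",), masks=np.arange(m, dtype=np.int64), k=np.full(m, 2),
            rss=np.ones(m), aicc=np.arange(m, dtype=float),
            coef=np.zeros((m, 2)), coef_var=np.zeros((m, 2)), n=10,
        )
        ms.delta_aicc = ms.aicc - ms.aicc.min()
        ms.weight = np.asarray(weights, float)
        return ms

    def test_point_mass(self):
        assert len(confidence_set(self._weighted_set([1.0]))) == 1

    def test_prefix_includes_crossing_model(self):
        idx = confidence_set(self._weighted_set([0.6, 0.3, 0.08, 0.02]), level=0.95)
        assert list(idx) == [0, 1, 2]

    def test_level_one_takes_all(self):
        assert len(confidence_set(self._weighted_set([0.6, 0.3, 0.08, 0.02]), level=1.0)) == 4

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            confidence_set(self._weighted_set([1.0]), level=1.5)


class TestAveraging:
    def test_matches_direct_summation_oracle(self, rng):
        X, y = random_instance(rng, n=50, p=3, betas=[2.0, 0, 0])
        ms = enumerate_models(X, y)
        avg = average_coefficients(ms)
        oracle = brute_force_chain(X, y)
        assert avg.attrs["confidence_set_size"] == oracle["cset_size"]
        np.testing.assert_allclose(avg["estimate"], oracle["averaged"], atol=1e-10)
        np.testing.assert_allclose(avg["se"], oracle["unconditional_se"], atol=1e-10)

    def test_absent_predictor_is_zero(self, rng):
        """A predictor outside every confidence-set model averages to exactly 0."""
        X, y = random_instance(rng, n=50, p=3, betas=[2.0, 0, 0])
        ms = enumerate_models(X, y)
        member = ms.membership()
        # restrict the set to models that exclude predictor 2
        idx = np.flatnonzero(~member[:, 2])[:5]
        avg = average_coefficients(ms, set_indices=idx)
        assert avg.loc["x2", "estimate"] == 0.0
        assert avg.loc["x2", "sign"] == 0

    def test_sign_matches_estimate(self, rng):
        X, y = random_instance(rng, n=60, p=3, betas=[3.0, -3.0, 0.0])
        avg = average_coefficients(enumerate_models(X, y))
        assert avg.loc["x0", "sign"] == 1
        assert avg.loc["x1", "sign"] == -1


class TestImportanceAndContributions:
    def test_single_predictor_importance_equals_model_weight(self, rng):
        X, y = random_instance(rng, n=30, p=1, betas=[1.0])
        ms = enumerate_models(X, y)
        imp = variable_importance(ms)
        with_x = ms.membership()[:, 0]
        assert imp["x0"] == pytest.approx(float(ms.weight[with_x].sum()))

    def test_strong_driver_dominates(self, rng):
        X = rng.normal(size=(60, 2))
        y = 5.0 * X[:, 0] + rng.normal(0, 0.1, 60)
        imp = variable_importance(enumerate_models(X, y))
        assert imp["x0"] > 0.99 > imp["x1"]

    def test_null_response_importances_exchangeable(self):
        """With a pure-noise response all predictors are interchangeable."""
        rng = np.random.default_rng(7)
        sums = np.zeros(4)
        reps = 200
        for _ in range(reps):
            X = rng.normal(size=(30, 4))
            y = rng.normal(size=30)
            sums += variable_importance(enumerate_models(X, y)).to_numpy()
        means = sums / reps
        assert np.ptp(means) < 0.05

    def test_contribution_normalization_examples(self):
        schema = PredictorSchema.uniform(["a", "b", "c"])
        table = relative_contributions(
            pd.Series({"a": 0.5, "b": 0.3, "c": 0.2}), schema
        )
        np.testing.assert_allclose(
            table.predictors["contribution_pct"], [50.0, 30.0, 20.0]
        )
        assert table.predictors["contribution_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_category_totals_and_per_capita(self):
        schema = PredictorSchema(
            names=("a", "b", "c"),
            category={"a": "g1", "b": "g1", "c": "g2"},
            biotic=frozenset({"c"}),
        )
        imp = pd.Series({"a": 0.08, "b": 0.06, "c": 0.86})
        table = relative_contributions(imp, schema)
        assert table.categories.loc["g1", "total_pct"] == pytest.approx(14.0)
        assert table.categories.loc["g1", "per_capita_pct"] == pytest.approx(7.0)
        assert table.biotic_total_pct == pytest.approx(86.0)
        assert table.abiotic_total_pct == pytest.approx(14.0)

    def test_sixteen_equal_importances(self):
        schema = PredictorSchema.survey_default()
        imp = pd.Series(0.5, index=list(schema.names))
        table = relative_contributions(imp, schema)
        np.testing.assert_allclose(table.predictors["contribution_pct"], 6.25)
        np.testing.assert_allclose(table.categories["per_capita_pct"], 6.25)

    def test_permutation_invariance(self, rng):
        X, y = random_instance(rng, n=40, p=4, betas=[1, 0, -1, 0])
        names = ["a", "b", "c", "d"]
        schema = PredictorSchema.uniform(names)
        frame = pd.DataFrame(X, columns=names)
        res = run_mmi(frame, y, schema=schema)
        perm = ["c", "a", "d", "b"]
        schema_p = PredictorSchema.uniform(perm)
        res_p = run_mmi(frame[perm], y, schema=schema_p)
        for name in names:
            assert res.contributions.predictors.loc[name, "contribution_pct"] == pytest.approx(
                res_p.contributions.predictors.loc[name, "contribution_pct"], rel=1e-10
            )

    def test_all_zero_importance_rejected(self):
        schema = PredictorSchema.uniform(["a", "b"])
        with pytest.raises(DegenerateInputError):
            relative_contributions(pd.Series({"a": 0.0, "b": 0.0}), schema)

    def test_noise_predictors_do_not_displace_strong_driver(self):
        """Adding pure-noise predictors keeps a strong driver ranked first."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            X = rng.normal(size=(50, 5))
            y = 2.0 * X[:, 0] + rng.normal(0, 0.2, 50)
            imp = variable_importance(enumerate_models(X, y))
            assert imp.idxmax() == "x0"
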