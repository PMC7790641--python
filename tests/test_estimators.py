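"""The four transfer-function estimators against independent oracles."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_calibration
from ecometric.errors import ValidationError
from ecometric.estimators import (
    fit_all,
    fit_knn,
    fit_linear,
    fit_mlgrid,
    fit_polynomial,
    model_from_dict,
    model_to_dict,
    modelset_from_dict,
    modelset_to_dict,
    predict_knn,
    predict_linear,
    predict_mlgrid,
    predict_polynomial,
)

RNG = np.random.default_rng(42)


def random_calibration(n=300, seed=0):
    rng = np.random.default_rng(seed)
    means = rng.uniform(1.0, 3.0, n)
    sds = rng.uniform(0.0, 1.0, n)
    env = 12.25 - 3.34 * means + rng.normal(0, 0.4, n)
    return make_calibration(means, sds, env)


class TestLinear:
    def test_recovers_noiseless_generating_line(self, noiseless_calibration):
        model = fit_linear(noiseless_calibration)
        assert model.intercept == pytest.approx(12.25, abs=1e-8)
        assert model.slope == pytest.approx(-3.34, abs=1e-8)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_three_collinear_points_interpolated_exactly(self):
        cal = make_calibration([1.0, 2.0, 3.0], [0.1, 0.2, 0.3], [5.0, 4.0, 3.0])
        model = fit_linear(cal)
        assert model.slope == pytest.approx(-1.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_mean_residual_is_zero(self, noisy_calibration):
        model = fit_linear(noisy_calibration)
        resid = noisy_calibration.env_log - model.predict(noisy_calibration.means)
        assert abs(resid.mean()) < 1e-10

    def test_prediction_evaluates_fitted_line(self):
        from ecometric.estimators import LinearModel

        model = LinearModel(12.25, -3.34, 0.408, 100, 0.01, (1.0, 3.0))
        assert predict_linear(model, 2.0) == pytest.approx(5.57)
        assert predict_linear(model, 0.0) == 12.25
        assert predict_linear(model, 3.0) == pytest.approx(2.23)

    def test_constant_predictor_is_error(self):
        cal = make_calibration([2.0] * 10, [0.1] * 10, RNG.normal(5, 1, 10))
        with pytest.raises(ValidationError, match="constant"):
            fit_linear(cal)

    def test_non_finite_query_rejected(self, noisy_calibration):
        model = fit_linear(noisy_calibration)
        with pytest.raises(ValidationError):
            predict_linear(model, float("nan"))


class TestPolynomial:
    def test_exact_recovery_of_known_cubic(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 3, 80)
        truth = np.array([5.64, -73.31, 15.22, 11.95])  # ascending powers
        y = np.polynomial.polynomial.polyval(x, truth)
        model = fit_polynomial(make_calibration(x, x * 0.1, y))
        assert np.allclose(model.coefficients, truth, atol=1e-6)
        assert model.r_squared == pytest.approx(1.0)

    def test_nests_linear_fit(self, noisy_calibration):
        lin = fit_linear(noisy_calibration)
        poly = fit_polynomial(noisy_calibration)
        assert poly.r_squared >= lin.r_squared
        # on linear-truth data the cubic's predictions track the line
        grid = np.linspace(*poly.fitted_range, 50)
        assert np.allclose(
            predict_polynomial(poly, grid), predict_linear(lin, grid), atol=0.2
        )

    def test_mean_residual_is_zero(self, noisy_calibration):
        model = fit_polynomial(noisy_calibration)
        resid = noisy_calibration.env_log - model.predict(noisy_calibration.means)
        assert abs(resid.mean()) < 1e-8

    def test_minimum_matches_grid_search_oracle(self):
        cal = random_calibration(n=400, seed=5)
        model = fit_polynomial(cal)
        lo, hi = model.fitted_range
        grid = np.linspace(lo, hi, 10_000)
        brute = predict_polynomial(model, grid).min()
        assert model.min_prediction == pytest.approx(brute, abs=1e-6)
        assert model.min_prediction <= predict_polynomial(model, grid).min() + 1e-12

    def test_constant_predictor_is_error(self):
        cal = make_calibration([2.0] * 10, [0.1] * 10, RNG.normal(5, 1, 10))
        with pytest.raises(ValidationError, match="constant"):
            fit_polynomial(cal)


class TestKNN:
    def test_training_subset_size_follows_fraction(self):
        cal = random_calibration(n=1000, seed=1)
        model = fit_knn(cal, k=15, training_fraction=0.2, seed=9)
        assert model.n_train == 200

    def test_fraction_one_uses_full_calibration(self):
        cal = random_calibration(n=120, seed=2)
        model = fit_knn(cal, k=15, training_fraction=1.0, seed=9)
        assert model.n_train == 120
        assert sorted(model.train_point_ids) == sorted(cal.point_ids)

    def test_same_seed_reproduces_training_subset(self):
        cal = random_calibration(n=500, seed=3)
        a = fit_knn(cal, seed=77)
        b = fit_knn(cal, seed=77)
        assert a.train_point_ids == b.train_point_ids
        assert fit_knn(cal, seed=78).train_point_ids != a.train_point_ids

    def test_k_exceeding_training_size_reports_both_numbers(self):
        cal = random_calibration(n=50, seed=4)
        with pytest.raises(ValidationError, match="k=15.*10"):
            fit_knn(cal, k=15, training_fraction=0.2)

    def test_matches_brute_force_full_sort_oracle(self):
        cal = random_calibration(n=800, seed=6)
        model = fit_knn(cal, k=15, training_fraction=0.5, seed=5)
        rng = np.random.default_rng(8)
        queries = rng.uniform(0.5, 3.5, 500)
        for q in queries:
            # oracle: full stable sort over all training records
            order = np.argsort(np.abs(model.train_means - q), kind="stable")
            expected = model.train_env[order[:15]].mean()
            assert predict_knn(model, q) == pytest.approx(expected, abs=1e-12)

    def test_k_equals_training_size_gives_global_mean(self):
        cal = random_calibration(n=60, seed=7)
        model = fit_knn(cal, k=60, training_fraction=1.0)
        expected = model.train_env.mean()
        for q in (0.0, 2.0, 10.0):
            assert predict_knn(model, q) == pytest.approx(expected)

    def test_exact_match_k1_returns_that_record(self):
        cal = make_calibration([1.0, 2.0, 3.0], [0, 0, 0], [9.0, 6.0, 3.0])
        model = fit_knn(cal, k=1, training_fraction=1.0)
        i = int(np.flatnonzero(model.train_means == 2.0)[0])
        assert predict_knn(model, 2.0) == model.train_env[i]

    def test_tie_at_kth_distance_broken_by_training_index(self):
        cal = make_calibration([1.0, 3.0, 2.0], [0, 0, 0], [10.0, 20.0, 30.0])
        model = fit_knn(cal, k=1, training_fraction=1.0)
        # query 2.0 is equidistant from means 1.0 and 3.0 but exactly on 2.0;
        # move to 1.5: tie between records with means 1.0 and 2.0
        order = np.argsort(np.abs(model.train_means - 1.5), kind="stable")
        assert predict_knn(model, 1.5) == model.train_env[order[0]]

    def test_mean_sd_space_requires_sd(self):
        cal = random_calibration(n=100, seed=9)
        model = fit_knn(cal, k=5, training_fraction=1.0, distance_space="mean_sd")
        with pytest.raises(ValidationError, match="sd"):
            predict_knn(model, 2.0)
        assert np.isfinite(predict_knn(model, 2.0, 0.5))

    def test_matches_sklearn_uniform_knn(self):
        sklearn = pytest.importorskip("sklearn.neighbors")
        cal = random_calibration(n=400, seed=10)
        model = fit_knn(cal, k=15, training_fraction=1.0)
        ref = sklearn.KNeighborsRegressor(n_neighbors=15).fit(
            model.train_means[:, None], model.train_env
        )
        queries = np.random.default_rng(11).uniform(1, 3, 50)
        ours = np.array([predict_knn(model, q) for q in queries])
        assert np.allclose(ours, ref.predict(queries[:, None]), atol=1e-9)


class TestMLGrid:
    def test_single_bin_estimate_is_member_mean(self):
        cal = make_calibration(
            [2.0, 2.0, 2.0, 2.01], [0.5, 0.5, 0.5, 0.51], [5.0, 6.0, 7.0, 6.0]
        )
        model = fit_mlgrid(cal, n_bins=2)
        assert model.bin_estimates[0, 0] == pytest.approx(6.0)

    def test_matches_floor_index_regrouping_oracle(self):
        cal = random_calibration(n=600, seed=12)
        model = fit_mlgrid(cal, n_bins=25)
        means, sds, env = cal.means, cal.sds, cal.env_log
        lo_m, hi_m = means.min(), means.max()
        lo_s, hi_s = sds.min(), sds.max()
        groups: dict[tuple[int, int], list[float]] = {}
        for m, s, y in zip(means, sds, env):
            i = min(int((m - lo_m) / (hi_m - lo_m) * 25), 24)
            j = min(int((s - lo_s) / (hi_s - lo_s) * 25), 24)
            groups.setdefault((i, j), []).append(y)
        for (i, j), values in groups.items():
            assert model.bin_counts[i, j] == len(values)
            assert model.bin_estimates[i, j] == pytest.approx(np.mean(values))
        assert model.bin_counts.sum() == cal.n

    def test_record_at_global_max_lands_in_last_bin(self):
        cal = random_calibration(n=200, seed=13)
        model = fit_mlgrid(cal, n_bins=25)
        m_max = cal.means.max()
        s_max = cal.sds[np.argmax(cal.means)]
        assert np.isfinite(predict_mlgrid(model, m_max, s_max))

    def test_estimates_stay_within_calibration_env_range(self):
        cal = random_calibration(n=600, seed=14)
        model = fit_mlgrid(cal)
        occupied = model.bin_estimates[~np.isnan(model.bin_estimates)]
        assert occupied.min() >= cal.env_log.min() - 1e-12
        assert occupied.max() <= cal.env_log.max() + 1e-12

    def test_query_outside_envelope_is_missing_not_error(self):
        cal = random_calibration(n=200, seed=15)
        model = fit_mlgrid(cal)
        assert np.isnan(predict_mlgrid(model, 2.0, cal.sds.max() + 0.5))
        assert np.isnan(predict_mlgrid(model, cal.means.min() - 0.5, 0.5))

    def test_calibration_records_always_receive_estimates(self):
        cal = random_calibration(n=300, seed=16)
        model = fit_mlgrid(cal)
        preds = predict_mlgrid(model, cal.means, cal.sds)
        assert np.isfinite(preds).all()

    def test_hist_mode_alternative_is_within_member_range(self):
        cal = random_calibration(n=300, seed=17)
        model = fit_mlgrid(cal, bin_estimate="hist_mode")
        occupied = model.bin_estimates[~np.isnan(model.bin_estimates)]
        assert occupied.min() >= cal.env_log.min() - 1e-9
        assert occupied.max() <= cal.env_log.max() + 1e-9

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValidationError, match="n_bins"):
            fit_mlgrid(random_calibration(50, seed=18), n_bins=1)


class TestSerialization:
    def test_round_trip_reproduces_predictions_bit_identically(self):
        cal = random_calibration(n=400, seed=20)
        models = fit_all(cal, seed=21)
        restored = modelset_from_dict(
            json.loads(json.dumps(modelset_to_dict(models)))
        )
        queries_m = np.random.default_rng(22).uniform(0.8, 3.2, 100)
        queries_s = np.random.default_rng(23).uniform(0.0, 1.2, 100)
        for m, s in zip(queries_m, queries_s):
            assert predict_linear(restored.linear, m) == predict_linear(models.linear, m)
            assert predict_polynomial(restored.polynomial, m) == predict_polynomial(
                models.polynomial, m
            )
            assert predict_knn(restored.knn, m) == predict_knn(models.knn, m)
            ours, theirs = (
                predict_mlgrid(models.mlgrid, m, s),
                predict_mlgrid(restored.mlgrid, m, s),
            )
            assert (np.isnan(ours) and np.isnan(theirs)) or ours == theirs

    def test_single_model_round_trip(self, noisy_calibration):
        model = fit_linear(noisy_calibration)
        back = model_from_dict(json.loads(json.dumps(model_to_dict(model))))
        assert back == model


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_knn_training_permutation_invariance(seed):
    """Predictions depend on the training set only through the tie rule."""
    cal = random_calibration(n=200, seed=30)
    model = fit_knn(cal, k=7, training_fraction=0.5, seed=seed % 100)
    q = 1.0 + (seed % 17) / 8.0
    d = np.abs(model.train_means - q)
    kth = np.sort(d, kind="stable")[6]
    if (d == kth).sum() == 1:  # no tie at the k-th distance: order irrelevant
        perm = np.random.default_rng(seed).permutation(model.n_train)
        shuffled = fit_knn(cal, k=7, training_fraction=0.5, seed=seed % 100)
        shuffled.train_means = model.train_means[perm]
        shuffled.train_sds = model.train_sds[perm]
        shuffled.train_env = model.train_env[perm]
        assert predict_knn(shuffled, q) == pytest.approx(predict_knn(model, q), abs=1e-12)


def test_all_methods_track_the_generating_gradient(noisy_calibration):
    """With a nonzero generating slope every estimator's predictions
    correlate positively with observed log precipitation."""
    cal = noisy_calibration
    models = fit_all(cal, seed=1)
    obs = cal.env_log
    for name, pred in [
        ("linear", predict_linear(models.linear, cal.means)),
        ("polynomial", predict_polynomial(models.polynomial, cal.means)),
        ("knn", predict_knn(models.knn, cal.means)),
        ("mlgrid", predict_mlgrid(models.mlgrid, cal.means, cal.sds)),
    ]:
        ok = np.isfinite(pred)
        r = np.corrcoef(pred[ok], obs[ok])[0, 1]
        assert r > 0, name
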