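"""Splitting, internal/external statistics, Y-scrambling and the
applicability domain."""

import numpy as np
import pandas as pd
import pytest

from argqsar.model import fit_ols
from argqsar.validation import (
    external_stats,
    internal_stats,
    leverage_analysis,
    lin_ccc,
    lmo_cv,
    random_split,
    warning_leverage,
    y_scramble,
)


def _dataset(seed=0, n=60, p=3, sigma=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.linspace(1.0, -1.0, p)
    y = 2.0 + X @ beta + rng.normal(scale=sigma, size=n)
    return X, y


class TestRandomSplit:
    def test_149_compounds_80_20(self):
        ids = [f"m{i}" for i in range(149)]
        split = random_split(ids, 0.8, seed=1)
        assert len(split.training_ids) == 119
        assert len(split.prediction_ids) == 30
        assert sorted(split.training_ids + split.prediction_ids) == sorted(ids)

    def test_reproducible_given_seed(self):
        ids = [f"m{i}" for i in range(50)]
        assert random_split(ids, 0.8, seed=3).training_ids == random_split(
            ids, 0.8, seed=3
        ).training_ids

    def test_fraction_one_warns_and_empties_prediction(self):
        ids = [f"m{i}" for i in range(10)]
        with pytest.warns(UserWarning):
            split = random_split(ids, 1.0, seed=0)
        assert split.prediction_ids == []


class TestInternalStats:
    def test_adjusted_r2_arithmetic_printed_inputs(self):
        # R2 = 0.8926, n = 119, p = 6
        r2_adj = 1 - (1 - 0.8926) * 118 / 112
        assert r2_adj == pytest.approx(0.8868, abs=2e-4)

    def test_perfect_fit_statistics(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 3))
        y = 1.0 + X @ np.array([1.0, 2.0, 3.0])
        model = fit_ols(X, y)
        rep = internal_stats(model, X, y, compute_lmo=False)
        assert rep.r2 == pytest.approx(1.0, abs=1e-10)
        assert rep.r2_adj == pytest.approx(1.0, abs=1e-10)
        assert rep.ccc_tr == pytest.approx(1.0, abs=1e-10)
        assert rep.rmse_tr == pytest.approx(0.0, abs=1e-8)
        assert rep.q2_loo == pytest.approx(1.0, abs=1e-8)

    def test_every_statistic_matches_direct_formulas(self):
        X, y = _dataset(seed=2, n=25, p=3)
        model = fit_ols(X, y)
        rep = internal_stats(model, X, y, compute_lmo=False, lof_d=0.5)
        n, p = 25, 3
        yhat = model.predict(X)
        resid = y - yhat
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1 - rss / tss
        assert rep.rss_tr == pytest.approx(rss, abs=1e-10)
        assert rep.r2 == pytest.approx(r2, abs=1e-10)
        assert rep.r2_adj == pytest.approx(
            1 - (1 - r2) * (n - 1) / (n - p - 1), abs=1e-10
        )
        assert rep.rmse_tr == pytest.approx(np.sqrt(rss / n), abs=1e-10)
        assert rep.mae_tr == pytest.approx(np.mean(np.abs(resid)), abs=1e-10)
        assert rep.s == pytest.approx(np.sqrt(rss / (n - p - 1)), abs=1e-10)
        assert rep.f_stat == pytest.approx(
            (r2 / p) / ((1 - r2) / (n - p - 1)), abs=1e-8
        )
        assert rep.lof == pytest.approx(
            (rss / n) / (1 - (p + 1 + 0.5 * p) / n) ** 2, abs=1e-10
        )
        # LOO block against explicit refits
        press = 0.0
        abs_press = []
        loo_pred = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            D = np.column_stack([np.ones(n - 1), X[mask]])
            beta, *_ = np.linalg.lstsq(D, y[mask], rcond=None)
            loo_pred[i] = np.r_[1.0, X[i]] @ beta
            press += (y[i] - loo_pred[i]) ** 2
            abs_press.append(abs(y[i] - loo_pred[i]))
        assert rep.press_cv == pytest.approx(press, abs=1e-8)
        assert rep.q2_loo == pytest.approx(1 - press / tss, abs=1e-10)
        assert rep.rmse_cv == pytest.approx(np.sqrt(press / n), abs=1e-10)
        assert rep.mae_cv == pytest.approx(np.mean(abs_press), abs=1e-10)
        assert rep.ccc_cv == pytest.approx(lin_ccc(y, loo_pred), abs=1e-10)
        assert rep.q2_loo <= rep.r2

    def test_rss_equals_n_rmse_squared(self):
        X, y = _dataset(seed=3)
        model = fit_ols(X, y)
        rep = internal_stats(model, X, y, compute_lmo=False)
        assert rep.rss_tr == pytest.approx(rep.n * rep.rmse_tr**2, abs=1e-8)

    def test_too_small_training_set_rejected(self):
        X, y = _dataset(seed=4, n=4, p=3)
        rng = np.random.default_rng(0)
        model = fit_ols(*_dataset(seed=5, n=30, p=3))
        with pytest.raises(ValueError):
            internal_stats(model, X, y)


class TestLmoCv:
    def test_noiseless_planted_data(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        y = 1.0 + X @ np.array([1.0, -2.0, 0.5])
        assert lmo_cv(X, y, leave_fraction=0.3, repeats=50, seed=0) > 0.99

    def test_close_to_loo_on_planted_benchmark(self):
        X, y = _dataset(seed=6, n=100, p=3)
        model = fit_ols(X, y)
        rep = internal_stats(
            model, X, y, lmo_fraction=0.3, lmo_repeats=500, lmo_seed=1
        )
        assert rep.q2_lmo <= rep.q2_loo + 0.05

    def test_single_left_out_point_reduction(self):
        X, y = _dataset(seed=7, n=20, p=2)
        # leave_fraction small enough that one point is left out
        got = lmo_cv(X, y, leave_fraction=0.05, repeats=1, seed=11)
        rng = np.random.default_rng(11)
        out = rng.choice(20, size=1, replace=False)
        mask = np.ones(20, dtype=bool)
        mask[out] = False
        D = np.column_stack([np.ones(19), X[mask]])
        beta, *_ = np.linalg.lstsq(D, y[mask], rcond=None)
        pred = np.r_[1.0, X[out[0]]] @ beta
        expected = 1 - (y[out[0]] - pred) ** 2 / (y[out[0]] - y[mask].mean()) ** 2
        assert got == pytest.approx(expected, abs=1e-10)

    def test_group_too_small_rejected(self):
        X, y = _dataset(seed=8, n=8, p=3)
        with pytest.raises(ValueError):
            lmo_cv(X, y, leave_fraction=0.5, repeats=5, seed=0)


class TestYScramble:
    def test_planted_signal_destroyed(self):
        X, y = _dataset(seed=9, n=150, p=3, sigma=0.4)
        rep = y_scramble(X, y, iterations=500, seed=0)
        assert rep.r2_mean < 0.1
        assert rep.q2_mean < 0

    def test_identity_permutation_reproduces_fit(self):
        X, y = _dataset(seed=10, n=40, p=3)
        model = fit_ols(X, y)
        from argqsar.validation import internal_stats as istats

        base = istats(model, X, y, compute_lmo=False)
        rep = y_scramble(X, y, iterations=1, seed=0, permute=False)
        assert rep.r2_mean == pytest.approx(base.r2, abs=1e-10)
        assert rep.q2_mean == pytest.approx(base.q2_loo, abs=1e-10)

    def test_same_seed_identical_report(self):
        X, y = _dataset(seed=11)
        r1 = y_scramble(X, y, iterations=100, seed=5)
        r2 = y_scramble(X, y, iterations=100, seed=5)
        assert np.array_equal(r1.r2_values, r2.r2_values)
        assert np.array_equal(r1.q2_values, r2.q2_values)


class TestExternalStats:
    def test_perfect_prediction_all_ones(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 3))
        beta = np.array([1.0, -1.0, 0.5])
        y = 1.0 + X @ beta
        model = fit_ols(X, y)
        X_ext = rng.normal(size=(10, 3))
        y_ext = 1.0 + X_ext @ beta
        rep = external_stats(model, X_ext, y_ext, y)
        for value in (rep.q2_f1, rep.q2_f2, rep.q2_f3, rep.ccc_ext, rep.r2_ext,
                      rep.k, rep.k_prime):
            assert value == pytest.approx(1.0, abs=1e-8)
        assert rep.r2m_delta == pytest.approx(0.0, abs=1e-8)
        assert rep.regression_angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_constant_prediction_q2f2_nonpositive(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 2))
        y = X @ np.array([1.0, 1.0]) + rng.normal(size=30)
        model = fit_ols(X, y)
        # external X at the training mean -> near-constant predictions
        X_ext = np.tile(X.mean(axis=0), (5, 1))
        y_ext = rng.normal(size=5) + y.mean()
        rep = external_stats(model, X_ext, y_ext, y)
        assert rep.q2_f2 <= 1e-6

    def test_q2f2_never_exceeds_q2f1(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 3))
            y = 1 + X @ np.array([1.0, 0.5, -0.5]) + rng.normal(scale=0.5, size=40)
            model = fit_ols(X[:30], y[:30])
            rep = external_stats(model, X[30:], y[30:], y[:30])
            assert rep.q2_f2 <= rep.q2_f1 + 1e-12

    def test_all_fields_match_direct_formulas(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 2))
        beta = np.array([1.0, -0.7])
        y = 0.5 + X @ beta + rng.normal(scale=0.4, size=30)
        model = fit_ols(X, y)
        X_ext = rng.normal(size=(10, 2))
        y_ext = 0.5 + X_ext @ beta + rng.normal(scale=0.4, size=10)
        rep = external_stats(model, X_ext, y_ext, y)
        yhat = model.predict(X_ext)
        resid = y_ext - yhat
        press = float(resid @ resid)
        assert rep.press_ext == pytest.approx(press, abs=1e-10)
        assert rep.rmse_ext == pytest.approx(np.sqrt(press / 10), abs=1e-10)
        assert rep.mae_ext == pytest.approx(np.mean(np.abs(resid)), abs=1e-10)
        assert rep.q2_f1 == pytest.approx(
            1 - press / np.sum((y_ext - y.mean()) ** 2), abs=1e-10
        )
        assert rep.q2_f2 == pytest.approx(
            1 - press / np.sum((y_ext - y_ext.mean()) ** 2), abs=1e-10
        )
        assert rep.q2_f3 == pytest.approx(
            1 - (press / 10) / (np.sum((y - y.mean()) ** 2) / 30), abs=1e-10
        )
        assert rep.r2_ext == pytest.approx(
            np.corrcoef(y_ext, yhat)[0, 1] ** 2, abs=1e-10
        )
        k = np.sum(y_ext * yhat) / np.sum(yhat**2)
        k_prime = np.sum(y_ext * yhat) / np.sum(y_ext**2)
        assert rep.k == pytest.approx(k, abs=1e-10)
        assert rep.k_prime == pytest.approx(k_prime, abs=1e-10)
        r2o = 1 - np.sum((y_ext - k * yhat) ** 2) / np.sum((y_ext - y_ext.mean()) ** 2)
        r2o_p = 1 - np.sum((yhat - k_prime * y_ext) ** 2) / np.sum(
            (yhat - yhat.mean()) ** 2
        )
        assert rep.r2o == pytest.approx(r2o, abs=1e-10)
        assert rep.r2o_prime == pytest.approx(r2o_p, abs=1e-10)
        r2 = rep.r2_ext
        r2m = r2 * (1 - np.sqrt(max(r2 - r2o, 0)))
        r2m_p = r2 * (1 - np.sqrt(max(r2 - r2o_p, 0)))
        assert rep.r2m_average == pytest.approx((r2m + r2m_p) / 2, abs=1e-10)
        assert rep.r2m_delta == pytest.approx(abs(r2m - r2m_p), abs=1e-10)
        slope = np.sum((y_ext - y_ext.mean()) * (yhat - yhat.mean())) / np.sum(
            (y_ext - y_ext.mean()) ** 2
        )
        assert rep.regression_angle_deg == pytest.approx(
            np.degrees(np.arctan(slope)) - 45, abs=1e-10
        )

    def test_ccc_symmetric_in_arguments(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(size=(2, 20))
        assert lin_ccc(a, b) == pytest.approx(lin_ccc(b, a), abs=1e-12)

    def test_too_small_external_set(self):
        X, y = _dataset(seed=16)
        model = fit_ols(X, y)
        with pytest.raises(ValueError):
            external_stats(model, X[:2], y[:2], y)


class TestLeverage:
    def test_warning_leverage_values(self):
        assert round(warning_leverage(149, 6), 3) == 0.141
        assert warning_leverage(149, 6) == pytest.approx(21 / 149, abs=1e-12)
        assert warning_leverage(119, 6) == pytest.approx(21 / 119, abs=1e-12)

    def test_training_leverages_sum_to_p_plus_one(self):
        X, y = _dataset(seed=17, n=40, p=6)
        model = fit_ols(X, y)
        rep = leverage_analysis(model, X)
        assert rep.leverages.sum() == pytest.approx(7.0, abs=1e-8)
        assert (rep.leverages >= 1 / 40 - 1e-12).all()
        assert (rep.leverages <= 1.0 + 1e-12).all()

    def test_query_at_training_mean_has_minimal_leverage(self):
        X, y = _dataset(seed=18, n=50, p=4)
        model = fit_ols(X, y)
        rep = leverage_analysis(model, X, X.mean(axis=0))
        assert rep.leverages[0] == pytest.approx(1 / 50, abs=1e-10)
        assert rep.in_domain[0]

    def test_far_query_out_of_domain(self):
        X, y = _dataset(seed=19, n=50, p=4)
        model = fit_ols(X, y)
        far = X.max(axis=0) * 10
        rep = leverage_analysis(model, X, far)
        assert not rep.in_domain[0]

    def test_standardized_residual_criterion(self):
        X, y = _dataset(seed=20, n=40, p=3)
        model = fit_ols(X, y)
        resid = y - model.predict(X)
        rep = leverage_analysis(model, X, X, residuals=resid)
        s = np.sqrt(np.sum(resid**2) / (40 - 3 - 1))
        assert np.allclose(rep.std_residuals, resid / s)
        inlier = (np.abs(rep.std_residuals) <= 3) & (rep.leverages <= rep.h_star)
        assert np.array_equal(rep.in_domain, inlier)
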