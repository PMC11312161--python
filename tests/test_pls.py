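import numpy as np
import pytest

from oleonir.pls import (
    CVResult,
    cross_validate_press,
    explained_x_variance,
    load_model,
    nipals_pls1_fit,
    pls_predict,
    regression_coefficients,
    save_model,
    select_components_haaland_thomas,
)


@pytest.fixture
def random_problem(rng):
    X = rng.standard_normal((30, 20))
    y = rng.standard_normal(30)
    return X, y


class TestNipalsFit:
    def test_rank_one_truth_recovered_with_one_factor(self, rng):
        direction = rng.standard_normal(15)
        t = rng.standard_normal(40)
        X = np.outer(t, direction)
        y = 3.0 * t + 1.0
        model = nipals_pls1_fit(X, y, 1)
        residuals = y - pls_predict(model, X)
        assert np.linalg.norm(residuals) < 1e-10

    def test_full_rank_fit_equals_least_squares(self, rng):
        """With h = rank(X centered), PLS reaches the OLS solution."""
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        model = nipals_pls1_fit(X, y, 6)
        Xc = np.column_stack([np.ones(25), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        np.testing.assert_allclose(pls_predict(model, X), Xc @ beta, atol=1e-8)

    def test_sample_permutation_leaves_coefficients_unchanged(self, random_problem, rng):
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 4)
        perm = rng.permutation(len(y))
        permuted = nipals_pls1_fit(X[perm], y[perm], 4)
        np.testing.assert_allclose(permuted.coef, model.coef, atol=1e-10)
        assert permuted.intercept == pytest.approx(model.intercept, abs=1e-10)

    def test_weights_unit_norm_scores_orthogonal(self, random_problem):
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 5)
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-8)
        gram = model.T.T @ model.T
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_zero_variance_y_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError, match="zero variance"):
            nipals_pls1_fit(X, np.ones(10), 2)

    def test_matches_reference_pls_fitted_values(self, rng):
        """NIPALS PLS1 agrees with the scikit-learn PLS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((40, 30))
        y = rng.standard_normal(40)
        for h in (1, 3, 5):
            ours = pls_predict(nipals_pls1_fit(X, y, h), X)
            theirs = PLSRegression(n_components=h, scale=False).fit(X, y).predict(X).ravel()
            np.testing.assert_allclose(ours, theirs, rtol=1e-6)


class TestPredict:
    def test_calibration_rows_reproduce_fitted_values(self, random_problem):
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 3)
        np.testing.assert_allclose(
            pls_predict(model, X), model.intercept + X @ model.coef, atol=1e-12
        )

    def test_mean_spectrum_predicts_mean_concentration(self, random_problem):
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 3)
        assert pls_predict(model, model.x_mean)[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_coefficient_path_equals_score_space_path(self, random_problem, rng):
        """yhat via coef equals projecting through W, P, q factor by factor."""
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 4)
        X_new = rng.standard_normal((7, X.shape[1]))
        E = X_new - model.x_mean
        yhat = np.full(7, model.y_mean)
        for j in range(model.h):
            t = E @ model.W[:, j]
            E = E - np.outer(t, model.P[:, j])
            yhat = yhat + model.q[j] * t
        np.testing.assert_allclose(pls_predict(model, X_new), yhat, atol=1e-10)


class TestCrossValidation:
    def test_noiseless_rank_one_press_vanishes(self, rng):
        direction = rng.standard_normal(10)
        t = rng.standard_normal(20)
        X = np.outer(t, direction)
        y = 2.0 * t
        cv = cross_validate_press(X, y, h_max=1)
        assert cv.press[0] < 1e-18

    def test_press_matches_exhaustive_refit_oracle(self, rng):
        """Accumulated PRESS equals per-(h, fold) refits from scratch."""
        X = rng.standard_normal((15, 8))
        y = X @ rng.standard_normal(8) + 0.3 * rng.standard_normal(15)
        h_max = 4
        cv = cross_validate_press(X, y, h_max=h_max)
        oracle = np.zeros(h_max)
        for h in range(1, h_max + 1):
            for i in range(15):
                train = np.delete(np.arange(15), i)
                model = nipals_pls1_fit(X[train], y[train], h)
                oracle[h - 1] += (y[i] - pls_predict(model, X[i : i + 1])[0]) ** 2
        np.testing.assert_allclose(cv.press, oracle, rtol=1e-10)

    def test_duplicated_samples_match_refit_oracle(self, rng):
        """LOO on a duplicated dataset still agrees with exhaustive refits
        (each held-out copy is predicted from a set containing its twin)."""
        X = rng.standard_normal((12, 6))
        y = X @ rng.standard_normal(6) + 0.2 * rng.standard_normal(12)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        cv2 = cross_validate_press(X2, y2, h_max=3)
        oracle = np.zeros(3)
        for h in range(1, 4):
            for i in range(24):
                train = np.delete(np.arange(24), i)
                model = nipals_pls1_fit(X2[train], y2[train], h)
                oracle[h - 1] += (y2[i] - pls_predict(model, X2[i : i + 1])[0]) ** 2
        np.testing.assert_allclose(cv2.press, oracle, rtol=1e-10)

    def test_kfold_scheme(self, rng):
        X = rng.standard_normal((21, 6))
        y = rng.standard_normal(21)
        cv = cross_validate_press(X, y, h_max=3, scheme="kfold", n_folds=7)
        assert cv.press.shape == (3,)
        assert np.all(cv.press > 0)


class TestHaalandThomasSelection:
    def test_worked_press_example_selects_two(self):
        """PRESS [10, 4, 3.9, 4.4] at n=20: F(1)=2.56 rejected, F(2)=1.03 accepted."""
        from scipy import stats

        cv = CVResult(press=np.array([10.0, 4.0, 3.9, 4.4]), h_star=3, selected_h=3)
        f_crit = stats.f.ppf(0.75, 20, 20)
        assert 10.0 / 3.9 > f_crit and 4.0 / 3.9 < f_crit  # oracle
        assert select_components_haaland_thomas(cv, n=20, alpha=0.25) == 2

    def test_monotone_press_with_large_gaps_keeps_minimum(self):
        cv = CVResult(press=np.array([5.0, 4.0, 3.0, 2.0, 1.0]), h_star=5, selected_h=5)
        assert select_components_haaland_thomas(cv, n=20, alpha=0.25) == 5

    def test_single_candidate(self):
        cv = CVResult(press=np.array([1.0]), h_star=1, selected_h=1)
        assert select_components_haaland_thomas(cv, n=10) == 1

    def test_selected_never_exceeds_press_minimiser(self, rng):
        for _ in range(20):
            press = rng.uniform(0.5, 5.0, size=8)
            cv = CVResult(press=press, h_star=int(np.argmin(press)) + 1, selected_h=1)
            selected = select_components_haaland_thomas(cv, n=30)
            assert selected <= cv.h_star

    def test_selection_grows_with_alpha(self, rng):
        """A larger alpha shrinks the F acceptance region, so fewer small-h
        models pass and the selected count can only grow."""
        for _ in range(10):
            press = rng.uniform(0.5, 5.0, size=8)
            cv = CVResult(press=press, h_star=int(np.argmin(press)) + 1, selected_h=1)
            hs = [
                select_components_haaland_thomas(cv, n=30, alpha=a)
                for a in (0.05, 0.25, 0.5)
            ]
            assert hs[0] <= hs[1] <= hs[2]


class TestInterpretation:
    def test_single_factor_coefficients_parallel_to_weight(self, random_problem):
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 1)
        cosine = model.coef @ model.W[:, 0] / np.linalg.norm(model.coef)
        assert abs(cosine) == pytest.approx(1.0, abs=1e-10)

    def test_coefficients_equal_prediction_gradient(self, random_problem):
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 3)
        x0 = X.mean(axis=0)
        eps = 1e-6
        for j in (0, 7, 19):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += eps
            xm[j] -= eps
            grad = (pls_predict(model, xp)[0] - pls_predict(model, xm)[0]) / (2 * eps)
            assert grad == pytest.approx(model.coef[j], abs=1e-8)

    def test_shifting_y_changes_only_intercept(self, random_problem):
        X, y = random_problem
        m1 = nipals_pls1_fit(X, y, 3)
        m2 = nipals_pls1_fit(X, y + 10.0, 3)
        np.testing.assert_allclose(m2.coef, m1.coef, atol=1e-10)
        assert m2.intercept == pytest.approx(m1.intercept + 10.0, abs=1e-10)

    def test_rank_one_x_explains_everything(self, rng):
        direction = rng.standard_normal(12)
        t = rng.standard_normal(25)
        X = np.outer(t, direction)
        y = t + 0.01 * rng.standard_normal(25)
        model = nipals_pls1_fit(X, y, 1)
        assert explained_x_variance(model)[0] == pytest.approx(1.0, abs=1e-10)

    @staticmethod
    def _orthogonal_block_design(rng, block2_width):
        n = 40
        t1 = rng.standard_normal(n)
        t2 = rng.standard_normal(n)
        t1 = (t1 - t1.mean()) / np.linalg.norm(t1 - t1.mean())
        t2 = t2 - t2.mean()
        t2 -= (t2 @ t1) * t1
        t2 /= np.linalg.norm(t2)
        X = np.zeros((n, 5 + block2_width))
        X[:, :5] = np.outer(t1, np.full(5, 1.0))
        X[:, 5:] = np.outer(t2, np.full(block2_width, 1.0))
        return X, t1, t2

    def test_equal_energy_blocks_single_factor_explains_half(self, rng):
        """With equal-energy orthogonal blocks the first weight is exactly the
        y direction, the fit converges in one factor, and that factor carries
        exactly half the X energy."""
        X, t1, t2 = self._orthogonal_block_design(rng, block2_width=5)
        y = t1 + 2.0 * t2
        with pytest.warns(UserWarning, match="stopped early"):
            model = nipals_pls1_fit(X, y, 2)
        assert model.h == 1
        assert explained_x_variance(model)[0] == pytest.approx(0.5, abs=1e-10)

    def test_rank_two_design_explained_fully_by_two_factors(self, rng):
        X, t1, t2 = self._orthogonal_block_design(rng, block2_width=20)
        y = t1 + 2.0 * t2
        model = nipals_pls1_fit(X, y, 2)
        fractions = explained_x_variance(model)
        assert fractions.shape == (2,)
        assert fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_explained_fractions_match_energy_oracle(self, random_problem):
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 5)
        Xc = X - X.mean(axis=0)
        total = np.sum(Xc**2)
        oracle = [
            np.sum(np.outer(model.T[:, j], model.P[:, j]) ** 2) / total
            for j in range(5)
        ]
        np.testing.assert_allclose(model.explained_x_variance, oracle, atol=1e-12)
        assert model.explained_x_variance.sum() <= 1.0 + 1e-9

    def test_regression_coefficients_labelled_by_wavelength(self, random_problem):
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 2)
        wl = 600.0 + 2.0 * np.arange(X.shape[1])
        wavelengths, coef = regression_coefficients(model, wl)
        np.testing.assert_array_equal(wavelengths, wl)
        np.testing.assert_array_equal(coef, model.coef)


class TestSerialisation:
    def test_save_load_predicts_bit_identically(self, tmp_path, random_problem, rng):
        X, y = random_problem
        model = nipals_pls1_fit(X, y, 4)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        X_new = rng.standard_normal((5, X.shape[1]))
        np.testing.assert_array_equal(pls_predict(loaded, X_new), pls_predict(model, X_new))
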