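import numpy as np
import pytest

import ftirq
from ftirq.chemometrics import (
    CalibrationModel,
    beta_coefficients,
    calibrate,
    fit_hla_go,
    fit_pcr,
    fit_plsr,
    load_model,
    predict,
    save_model,
    select_lv,
    top_bands,
)
from ftirq.preprocess import PreprocessConfig

from conftest import make_two_component_mixtures


def ols_oracle(X, y, X_new):
    """Mean-centered least squares via pseudo-inverse."""
    xm, ym = X.mean(axis=0), y.mean()
    b = np.linalg.pinv(X - xm) @ (y - ym)
    return ym + (X_new - xm) @ b


@pytest.fixture(scope="module")
def tall_full_rank():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(40, 6))
    y = X @ rng.normal(size=6) + rng.normal(0, 0.3, size=40) + 2.0
    return X, y


class TestPlsr:
    def test_exact_recovery_on_noiseless_two_component_data(self):
        X, y, _, _ = make_two_component_mixtures()
        model = fit_plsr(X, y, n_lv=2)
        assert np.sqrt(np.mean((predict(model, X) - y) ** 2)) < 1e-8

    def test_full_rank_matches_ols_pseudo_inverse(self, tall_full_rank):
        X, y = tall_full_rank
        model = fit_plsr(X, y, n_lv=6)
        assert np.allclose(predict(model, X), ols_oracle(X, y, X), atol=1e-8)

    def test_matches_sklearn_pls_regression(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        X, y, _, _ = make_two_component_mixtures(n=30, p=40, noise_sd=1e-4)
        for a in (1, 2, 3):
            ours = fit_plsr(X, y, n_lv=a)
            ref = sklearn_pls(n_components=a, scale=False).fit(X, y)
            assert np.allclose(
                predict(ours, X), ref.predict(X).ravel(), atol=1e-8
            ), f"disagreement at {a} latent variables"

    def test_scores_mutually_orthogonal(self):
        X, y, _, _ = make_two_component_mixtures(n=30, p=50, noise_sd=1e-3)
        model = fit_plsr(X, y, n_lv=5)
        T = model.internals["scores"]
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-10 * np.max(np.diag(gram))

    def test_zero_variance_y_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError, match="zero-variance"):
            fit_plsr(X, np.full(10, 2.0), n_lv=1)

    def test_n_lv_beyond_rank_rejected(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(20, 1))
        v = rng.normal(size=(1, 8))
        X = u @ v  # rank 1 after centering
        y = X[:, 0] + rng.normal(0, 0.01, 20)
        with pytest.raises(ValueError, match="rank"):
            fit_plsr(X, y, n_lv=5)


class TestPcr:
    def test_full_rank_matches_ols_pseudo_inverse(self, tall_full_rank):
        X, y = tall_full_rank
        model = fit_pcr(X, y, n_lv=6)
        assert np.allclose(predict(model, X), ols_oracle(X, y, X), atol=1e-8)

    def test_rank_one_noiseless_exact(self):
        rng = np.random.default_rng(2)
        direction = rng.normal(size=12)
        t = rng.normal(size=25)
        X = np.outer(t, direction)
        y = 3.0 * t + 1.0
        model = fit_pcr(X, y, n_lv=1)
        assert np.allclose(predict(model, X), y, atol=1e-10)

    def test_pcr_not_better_than_plsr_in_fit_at_same_rank(self):
        # PLS maximizes covariance with y, so its calibration RMSE at k
        # factors should not exceed PCR's on the same data (empirical check)
        X, y, _, _ = make_two_component_mixtures(n=40, p=60, noise_sd=1e-3)
        for k in (1, 2):
            rm_pls = np.sqrt(np.mean((predict(fit_plsr(X, y, k), X) - y) ** 2))
            rm_pcr = np.sqrt(np.mean((predict(fit_pcr(X, y, k), X) - y) ** 2))
            assert rm_pls <= rm_pcr + 1e-12


class TestHlaGo:
    def test_two_component_noiseless_exact(self):
        X, y, _, _ = make_two_component_mixtures()
        model = fit_hla_go(X, y, n_factors=1)
        assert np.allclose(predict(model, X), y, atol=1e-8)

    def test_background_orthogonal_to_analyte_keeps_full_signal(self):
        # construct y-signal along e1, background along e2: s* == s_hat
        n = 16
        rng = np.random.default_rng(4)
        y = rng.uniform(1, 3, n)
        g = rng.normal(size=n)
        yc = y - y.mean()
        g = g - (g @ yc) / (yc @ yc) * yc  # decorrelate from y in-sample
        X = np.zeros((n, 6))
        X[:, 0] = y
        X[:, 1] = g
        model = fit_hla_go(X, y, n_factors=1)
        s_hat = model.internals["pure_signal_estimate"]
        s_star = model.internals["nas_vector"]
        assert np.allclose(s_star, s_hat, atol=1e-10)

    def test_zero_factors_is_projection_on_pure_signal_estimate(self):
        X, y, _, _ = make_two_component_mixtures(n=20, p=30, noise_sd=1e-3)
        model = fit_hla_go(X, y, n_factors=0)
        s_hat = model.internals["pure_signal_estimate"]
        xm, ym = X.mean(axis=0), y.mean()
        manual = ym + (X - xm) @ s_hat / (s_hat @ s_hat)
        assert np.allclose(predict(model, X), manual, atol=1e-12)

    def test_nas_scalar_linear_in_concentration(self):
        X, y, _, _ = make_two_component_mixtures(n=30, p=50)
        model = fit_hla_go(X, y, n_factors=1)
        s_star = model.internals["nas_vector"]
        nas = (X - X.mean(axis=0)) @ s_star
        r = np.corrcoef(nas, y)[0, 1]
        assert 1 - r**2 < 1e-10

    def test_analyte_inside_background_rejected(self):
        # y-correlated signal fully removable by a rank-1 background
        rng = np.random.default_rng(5)
        y = rng.uniform(1, 3, 15)
        X = np.outer(y - y.mean(), np.ones(8))  # rank-1, collinear with s_hat
        with pytest.raises(ValueError, match="not distinguishable"):
            fit_hla_go(X, y, n_factors=1)


class TestSelectLv:
    def test_noiseless_rank_two_data_selects_two(self):
        X, y, _, _ = make_two_component_mixtures(n=60, p=40)
        cv = select_lv(X, y, method="plsr", max_lv=6, n_folds=5, seed=0)
        assert cv.chosen_lv == 2

    def test_tie_takes_smallest(self):
        cv_rms = np.array([0.5, 0.5, 0.5])
        assert int(np.argmin(cv_rms)) + 1 == 1  # documents the argmin tie rule

    def test_seed_reproducibility(self):
        X, y, _, _ = make_two_component_mixtures(n=50, p=30, noise_sd=1e-3)
        a = select_lv(X, y, max_lv=5, n_folds=5, seed=7)
        b = select_lv(X, y, max_lv=5, n_folds=5, seed=7)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert a.chosen_lv == b.chosen_lv
        assert np.array_equal(a.per_lv_rms, b.per_lv_rms)

    def test_chosen_lv_is_first_minimum(self):
        X, y, _, _ = make_two_component_mixtures(n=50, p=30, noise_sd=0.01, seed=8)
        cv = select_lv(X, y, max_lv=6, n_folds=5, seed=1)
        assert cv.chosen_lv == int(np.argmin(cv.per_lv_rms)) + 1


class TestPredictAndProvenance:
    def test_calibration_mean_predicts_y_mean(self):
        X, y, _, _ = make_two_component_mixtures(noise_sd=0.01)
        for fit in (fit_plsr, fit_pcr):
            model = fit(X, y, 2)
            assert predict(model, X.mean(axis=0)) == pytest.approx(y.mean(), abs=1e-10)

    def test_grid_mismatch_rejected(self):
        X, y, _, _ = make_two_component_mixtures()
        model = fit_plsr(X, y, 2)
        with pytest.raises(ValueError, match="mismatch"):
            predict(model, X[:, :-3])

    def test_calibrate_applies_and_freezes_preprocessing(self, chemometric_split):
        cal, val = chemometric_split
        model, cv = calibrate(cal, method="plsr",
                              preprocess=PreprocessConfig(method="msc"),
                              max_lv=6, n_folds=5, seed=3)
        assert model.msc_reference is not None
        y_hat = ftirq.predict_spectra(model, val)
        assert ftirq.r_squared(val.concentration, y_hat) > 0.95

    def test_model_json_round_trip(self, tmp_path):
        X, y, _, _ = make_two_component_mixtures()
        model = fit_plsr(X, y, 2, preprocess=PreprocessConfig(method="snv"))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.coefficients, model.coefficients)
        assert back.preprocess == model.preprocess
        assert np.array_equal(predict(back, X), predict(model, X))


class TestBetaCoefficients:
    def test_length_matches_axis(self, chemometric_split):
        cal, _ = chemometric_split
        model, _ = calibrate(cal, method="plsr", n_lv=5,
                             preprocess=PreprocessConfig(method="snv"))
        wn, b = beta_coefficients(model)
        assert len(wn) == len(b) == cal.n_points

    def test_all_zero_coefficients_give_no_bands(self):
        model = CalibrationModel(
            method="plsr", n_lv=1, x_mean=np.zeros(10), y_mean=0.0,
            coefficients=np.zeros(10), wavenumbers=np.linspace(2000, 1000, 10),
        )
        assert top_bands(model, 5) == []

    def test_top_bands_sorted_by_magnitude(self):
        wn = np.linspace(2000, 1000, 101)
        b = np.zeros(101)
        b[20], b[50], b[80] = 0.5, -2.0, 1.0
        model = CalibrationModel(
            method="plsr", n_lv=1, x_mean=np.zeros(101), y_mean=0.0,
            coefficients=b, wavenumbers=wn,
        )
        bands = top_bands(model, 2)
        assert bands == [pytest.approx(wn[50]), pytest.approx(wn[80])]
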