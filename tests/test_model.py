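import numpy as np
import pandas as pd
import pytest

import tissueclock as tc
from tissueclock.datamodel import ValidationError
from tissueclock.model import MissingGeneError, objective, predict_ages_matrix


def _instance(seed=3, n=20, p=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.normal(50.0, 10.0, n)
    return X, y


class TestFitElasticNet:
    def test_huge_lasso_penalty_gives_intercept_only_model(self):
        X, y = _instance()
        model = tc.fit_elastic_net(X, y, alpha=1.0, lam=1e9)
        assert (model.coefficients["coefficient"] == 0).all()
        assert model.intercept == pytest.approx(y.mean())

    @pytest.mark.parametrize("seed", [3, 11, 42])
    def test_ridge_matches_closed_form(self, seed):
        """alpha=0 solves RSS + (lam/2)||w||^2 exactly (standardized fit,
        coefficients back-transformed)."""
        X, y = _instance(seed)
        lam = 2.0
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        w_std = np.linalg.solve(Xs.T @ Xs + (lam / 2) * np.eye(3),
                                Xs.T @ (y - y.mean()))
        w_expect = w_std / sd
        b0_expect = y.mean() - w_expect @ mu
        model = tc.fit_elastic_net(X, y, alpha=0.0, lam=lam)
        np.testing.assert_allclose(
            model.coefficients["coefficient"], w_expect, atol=1e-4
        )
        assert model.intercept == pytest.approx(b0_expect, abs=1e-4)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_vanishing_penalty_matches_ols(self, alpha):
        X, y = _instance(seed=11)
        X1 = np.hstack([np.ones((len(y), 1)), X])
        beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
        model = tc.fit_elastic_net(X, y, alpha=alpha, lam=1e-8)
        assert model.intercept == pytest.approx(beta[0], abs=1e-4)
        np.testing.assert_allclose(
            model.coefficients["coefficient"], beta[1:], atol=1e-4
        )

    def test_parameter_validation(self):
        X, y = _instance()
        with pytest.raises(ValueError, match="lambda"):
            tc.fit_elastic_net(X, y, alpha=0.5, lam=0.0)
        with pytest.raises(ValueError, match="alpha"):
            tc.fit_elastic_net(X, y, alpha=1.5, lam=1.0)
        with pytest.raises(ValidationError, match="align"):
            tc.fit_elastic_net(X, y[:-1], alpha=0.5, lam=1.0)

    def test_objective_at_solution_beats_zero_and_perturbations(self):
        X, y = _instance(seed=5)
        lam, alpha = 1.5, 0.4
        model = tc.fit_elastic_net(X, y, alpha=alpha, lam=lam, standardize=False,
                                   tol=1e-12, max_iter=200_000)
        obj = objective(model, X, y)
        zero = tc.AgeModel(
            intercept=float(y.mean()),
            coefficients=pd.DataFrame(
                {"gene": model.coefficients["gene"],
                 "coefficient": 0.0, "tissue": ""}),
            alpha=alpha, lam=lam,
        )
        assert obj <= objective(zero, X, y) + 1e-9
        rng = np.random.default_rng(0)
        w = model.coefficients["coefficient"].to_numpy()
        for _ in range(100):
            probe = model.coefficients.copy()
            probe["coefficient"] = w + rng.normal(0, 0.05, len(w))
            perturbed = tc.AgeModel(
                intercept=model.intercept + rng.normal(0, 0.05),
                coefficients=probe, alpha=alpha, lam=lam)
            assert obj <= objective(perturbed, X, y) + 1e-9

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_coefficient_shrinkage_along_lambda_path(self, alpha):
        X, y = _instance(seed=7)
        norms = []
        for lam in [2.0**e for e in range(-10, 11)]:
            m = tc.fit_elastic_net(X, y, alpha=alpha, lam=lam,
                                   tol=1e-12, max_iter=200_000)
            w = m.coefficients["coefficient"].to_numpy()
            norms.append(np.sqrt(w @ w))
        assert (np.diff(norms) <= 1e-8).all()

    def test_standardization_does_not_change_predictions(self):
        rng = np.random.default_rng(9)
        X = rng.normal(5, 3, size=(30, 4)) * np.array([1.0, 10.0, 0.1, 2.0])
        y = rng.normal(50, 10, 30)
        m_std = tc.fit_elastic_net(X, y, alpha=0.0, lam=1e-6, standardize=True)
        m_raw = tc.fit_elastic_net(X, y, alpha=0.0, lam=1e-6, standardize=False)
        np.testing.assert_allclose(
            predict_ages_matrix(m_std, X), predict_ages_matrix(m_raw, X),
            atol=1e-6,
        )


class TestPredictAge:
    def test_packaged_model_intercept_at_zero_expression(self):
        model = tc.load_packaged_model()
        assert tc.predict_age(model, {}, zero_missing=True) == pytest.approx(49.1)

    def test_packaged_model_single_gene_term(self):
        model = tc.load_packaged_model()
        expr = {g: 0.0 for g in model.coefficients["gene"]}
        expr["RASSF8"] = 1.0
        assert tc.predict_age(model, expr) == pytest.approx(49.1 + 0.43450456)

    def test_zero_coefficient_model_predicts_intercept(self):
        model = tc.AgeModel(
            intercept=42.0,
            coefficients=pd.DataFrame(
                {"gene": ["a", "b"], "coefficient": [0.0, 0.0], "tissue": ""}),
            alpha=0.0, lam=1.0,
        )
        assert tc.predict_age(model, {"a": 3.0, "b": -1.0}) == 42.0

    def test_missing_gene_is_an_error_listing_genes(self):
        model = tc.load_packaged_model()
        with pytest.raises(MissingGeneError, match="RF00019"):
            tc.predict_age(model, {"RASSF8": 1.0})

    def test_prediction_is_linear_in_expression(self):
        model = tc.load_packaged_model()
        genes = list(model.coefficients["gene"])
        rng = np.random.default_rng(1)
        x1 = dict(zip(genes, rng.normal(size=len(genes))))
        x2 = dict(zip(genes, rng.normal(size=len(genes))))
        combo = {g: 0.3 * x1[g] + 0.7 * x2[g] for g in genes}
        expect = (0.3 * (tc.predict_age(model, x1) - model.intercept)
                  + 0.7 * (tc.predict_age(model, x2) - model.intercept)
                  + model.intercept)
        assert tc.predict_age(model, combo) == pytest.approx(expect)


class TestMetrics:
    def test_rmse_examples(self):
        assert tc.rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert tc.rmse([60, 50], [57, 54]) == pytest.approx(np.sqrt(25 / 2))
        assert tc.rmse([40.0], [43.5]) == pytest.approx(3.5)
        with pytest.raises(ValidationError):
            tc.rmse([1, 2], [1])

    def test_pcc_delegates_to_pearson(self):
        truth = np.array([1.0, 2, 3, 4])
        assert tc.pcc(truth, truth) == pytest.approx(1.0)
        assert tc.pcc(truth, -truth + 7) == pytest.approx(-1.0)
        assert tc.pcc(truth, [1, 3, 2, 4]) == pytest.approx(0.8)


class TestSerialization:
    def test_model_round_trip(self, tmp_path):
        X, y = _instance(seed=13)
        model = tc.fit_elastic_net(
            X, y, alpha=0.3, lam=2.0,
            gene_ids=["GA", "GB", "GC"], tissues=["liver"] * 3,
        )
        path = tmp_path / "model.tsv"
        tc.write_model(model, path)
        back = tc.read_model(path)
        assert back.intercept == pytest.approx(model.intercept, rel=1e-6)
        np.testing.assert_allclose(
            back.coefficients["coefficient"],
            model.coefficients["coefficient"], rtol=1e-6,
        )
        assert list(back.coefficients["tissue"]) == ["liver"] * 3

    def test_packaged_model_layout(self):
        model = tc.load_packaged_model()
        assert len(model.coefficients) == 50
        counts = model.coefficients["tissue"].value_counts()
        assert counts["Pituitary"] == 49
        assert counts["Muscle"] == 1
        assert model.alpha == 0.0
        assert model.lam == 0.5
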