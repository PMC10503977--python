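"""OLS fitting and the degrees-of-freedom-sensitive fit statistics."""

import numpy as np
import pytest

from qsarkit import (
    CompoundRecord,
    QSARDataset,
    fit,
    fit_statistics,
    predict,
)

# Published model equation for the chalcone training set:
# pIC50 = -3.754 + 8.469*BCUT_SMR_2 + 0.636*logP(o/w)
#         + 0.057*SlogP_VSA4 - 0.442*vsurf_IW3
PUBLISHED_COEFS = {
    "BCUT_SMR_2": 8.469,
    "logP(o/w)": 0.636,
    "SlogP_VSA4": 0.057,
    "vsurf_IW3": -0.442,
}
PUBLISHED_INTERCEPT = -3.754


def _toy(X, y, names=None, split="train"):
    names = names or [f"x{j}" for j in range(X.shape[1])]
    recs = [
        CompoundRecord(f"c{i}", dict(zip(names, X[i])), float(y[i]), split)
        for i in range(len(X))
    ]
    return QSARDataset(recs, names)


class TestFit:
    def test_recovers_published_equation(self, chalcone_model):
        assert chalcone_model.intercept == pytest.approx(PUBLISHED_INTERCEPT, abs=0.01)
        for name, val in PUBLISHED_COEFS.items():
            assert chalcone_model.coefficients[name] == pytest.approx(val, abs=0.01)
        assert chalcone_model.n_train == 20

    def test_constant_response_gives_zero_slopes(self, rng):
        X = rng.normal(size=(12, 3))
        ds = _toy(X, np.full(12, 5.5))
        m = fit(ds)
        assert m.intercept == pytest.approx(5.5, abs=1e-10)
        assert all(abs(c) < 1e-10 for c in m.coefficients.values())

    def test_noiseless_linear_recovered_exactly(self, rng):
        X = rng.normal(size=(15, 2))
        y = 2.0 + 3.0 * X[:, 0] - X[:, 1]
        m = fit(_toy(X, y))
        assert m.intercept == pytest.approx(2.0, abs=1e-9)
        assert m.coefficients["x0"] == pytest.approx(3.0, abs=1e-9)
        assert m.coefficients["x1"] == pytest.approx(-1.0, abs=1e-9)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=10)
        ds = _toy(np.column_stack([x, 2 * x]), rng.normal(size=10))
        with pytest.raises(ValueError, match="collinear"):
            fit(ds)

    def test_too_few_records_rejected(self, rng):
        X = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="records"):
            fit(_toy(X, rng.normal(size=4)))


class TestPredict:
    @pytest.mark.parametrize(
        "compound, expected",
        [("8b", 6.7780), ("10b", 7.5893), ("10d", 7.6778), ("12a", 5.2381)],
    )
    def test_matches_printed_predictions(self, chalcone_model, chalcones, compound, expected):
        preds = predict(chalcone_model, chalcones)
        assert preds[compound] == pytest.approx(expected, abs=0.01)

    def test_all_printed_predictions(self, chalcone_model, chalcones, chalcones_frame):
        preds = predict(chalcone_model, chalcones)
        for row in chalcones_frame.itertuples():
            assert preds[row.compound] == pytest.approx(row.pIC50_pred, abs=0.01)

    def test_zero_descriptors_predict_intercept(self, chalcone_model):
        zeros = {n: 0.0 for n in chalcone_model.descriptor_names}
        assert chalcone_model.predict_one(zeros) == pytest.approx(
            chalcone_model.intercept
        )

    def test_missing_descriptor_names_compound(self, chalcone_model):
        with pytest.raises(ValueError, match="'q1'"):
            chalcone_model.predict_one({"logP(o/w)": 1.0}, compound_id="q1")


class TestFitStatistics:
    def test_reproduces_published_statistics(self, chalcone_model, chalcones):
        s = fit_statistics(chalcone_model, chalcones)
        assert s.r2 == pytest.approx(0.88, abs=0.005)
        assert s.r2_adj == pytest.approx(0.84, abs=0.01)
        assert s.rmse == pytest.approx(0.28, abs=0.01)
        assert s.mae == pytest.approx(0.20, abs=0.01)
        assert s.f_stat == pytest.approx(27.76, abs=0.3)
        assert s.coef_p_values["SlogP_VSA4"] < 1e-4
        assert all(p < 0.05 for p in s.coef_p_values.values())

    def test_rmse_conventions(self, chalcone_model, chalcones):
        se = fit_statistics(chalcone_model, chalcones, rmse_convention="residual-se")
        plain = fit_statistics(chalcone_model, chalcones, rmse_convention="mean")
        n, p = se.n, se.p
        assert se.rmse**2 * (n - p - 1) == pytest.approx(se.sse, rel=1e-12)
        assert plain.rmse**2 * n == pytest.approx(plain.sse, rel=1e-12)

    def test_perfect_fit(self, rng):
        X = rng.normal(size=(10, 2))
        y = 1.0 + X[:, 0] - 2 * X[:, 1]
        ds = _toy(X, y)
        s = fit_statistics(fit(ds), ds)
        assert s.r2 == pytest.approx(1.0, abs=1e-12)
        assert s.rmse == pytest.approx(0.0, abs=1e-7)
        assert s.mae == pytest.approx(0.0, abs=1e-7)

    def test_f_identity(self, chalcone_model, chalcones):
        s = fit_statistics(chalcone_model, chalcones)
        expected = ((s.sst - s.sse) / s.p) / (s.sse / (s.n - s.p - 1))
        assert s.f_stat == pytest.approx(expected, rel=1e-12)

    def test_residuals_orthogonal_to_design(self, chalcone_model, chalcones):
        train = chalcones.train
        X = train.descriptor_matrix()
        y = train.activities()
        preds = predict(chalcone_model, train)
        e = y - np.array([preds[i] for i in train.ids])
        # standardize columns to make the tolerance scale-free
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert abs(e.sum()) < 1e-8
        assert np.all(np.abs(Z.T @ e) < 1e-8)

    def test_matches_sklearn_fit(self, chalcones):
        """Independent route: scikit-learn's LinearRegression on the same data."""
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        X = chalcones.train.descriptor_matrix()
        y = chalcones.train.activities()
        ref = sklearn_lm.LinearRegression().fit(X, y)
        m = fit(chalcones)
        assert m.intercept == pytest.approx(ref.intercept_, abs=1e-8)
        coefs = [m.coefficients[n] for n in chalcones.descriptor_names]
        assert np.allclose(coefs, ref.coef_, atol=1e-8)

    def test_coefficient_recovery_on_synthetic_noise(self):
        """Estimated coefficients stay within 4 standard errors of truth."""
        rng = np.random.default_rng(12345)
        truth = np.array([1.5, -2.0, 0.5])
        hits = 0
        n_trials = 200
        for _ in range(n_trials):
            X = rng.normal(size=(25, 3))
            y = 0.7 + X @ truth + rng.normal(scale=0.4, size=25)
            ds = _toy(X, y)
            m = fit(ds)
            s = fit_statistics(m, ds)
            A = np.column_stack([np.ones(25), X])
            se = np.sqrt(
                np.diag(np.linalg.inv(A.T @ A))[1:] * s.sse / (s.n - s.p - 1)
            )
            est = np.array([m.coefficients[f"x{j}"] for j in range(3)])
            if np.all(np.abs(est - truth) <= 4 * se):
                hits += 1
        assert hits / n_trials >= 0.95
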