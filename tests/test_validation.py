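"""The validation battery: LOO, r²m, Y-randomization, external checks."""

import numpy as np
import pytest

from qsarkit import (
    CompoundRecord,
    QSARDataset,
    external_validation,
    fit,
    fit_statistics,
    loo_cv,
    rm_metrics,
    validation_report,
    y_randomization,
)


def _toy(X, y, split="train"):
    names = [f"x{j}" for j in range(X.shape[1])]
    recs = [
        CompoundRecord(f"c{i}", dict(zip(names, X[i])), float(y[i]), split)
        for i in range(len(X))
    ]
    return QSARDataset(recs, names)


class TestLOO:
    def test_reproduces_published_loo_statistics(self, chalcones):
        res = loo_cv(chalcones)
        assert res.q2_loo == pytest.approx(0.81, abs=0.01)
        assert res.rmse_loo == pytest.approx(0.31, abs=0.015)
        assert res.mae_loo == pytest.approx(0.27, abs=0.01)

    def test_per_compound_loo_predictions_match_printed(self, chalcones, chalcones_frame):
        res = loo_cv(chalcones)
        train_rows = chalcones_frame[chalcones_frame.split == "train"]
        for row in train_rows.itertuples():
            assert res.loo_predictions[row.compound] == pytest.approx(
                row.pIC50_loo, abs=0.01
            )

    def test_noiseless_linear_data_gives_q2_of_one(self, rng):
        X = rng.normal(size=(12, 2))
        y = 1.0 + X[:, 0] - 0.5 * X[:, 1]
        res = loo_cv(_toy(X, y))
        assert res.q2_loo == pytest.approx(1.0, abs=1e-10)
        assert res.rmse_loo == pytest.approx(0.0, abs=1e-7)

    def test_refit_loop_equals_hat_matrix_shortcut(self, rng):
        """Oracle equivalence: explicit refits vs e_i/(1-h_ii)."""
        for _ in range(3):
            X = rng.normal(size=(15, 3))
            y = X @ [1.0, -1.0, 0.5] + rng.normal(size=15)
            ds = _toy(X, y)
            res = loo_cv(ds)
            A = np.column_stack([np.ones(15), X])
            H = A @ np.linalg.inv(A.T @ A) @ A.T
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            e = y - A @ beta
            shortcut = y - e / (1 - np.diag(H))
            got = np.array([res.loo_predictions[f"c{i}"] for i in range(15)])
            assert np.allclose(got, shortcut, atol=1e-8)

    def test_press_at_least_sse(self, chalcones, chalcone_model, rng):
        """PRESS >= SSE, hence Q² <= r², on the chalcones and random data."""
        stats = fit_statistics(chalcone_model, chalcones)
        assert loo_cv(chalcones).q2_loo <= stats.r2
        for _ in range(5):
            X = rng.normal(size=(12, 2))
            y = X[:, 0] + rng.normal(size=12)
            ds = _toy(X, y)
            s = fit_statistics(fit(ds), ds)
            assert loo_cv(ds).q2_loo <= s.r2 + 1e-12


class TestRmMetrics:
    def test_published_slopes_on_test_set(self, chalcones, chalcone_model):
        ext = external_validation(chalcone_model, chalcones)
        ids = list(ext.observed)
        m = rm_metrics(
            [ext.observed[i] for i in ids], [ext.predicted[i] for i in ids]
        )
        assert m.k == pytest.approx(0.96, abs=0.01)
        assert m.k_prime == pytest.approx(1.04, abs=0.01)

    def test_published_rm2_on_loo_predictions(self, chalcones):
        res = loo_cv(chalcones)
        y = chalcones.train.activities()
        loo = [res.loo_predictions[i] for i in chalcones.train.ids]
        m = rm_metrics(y, loo)
        assert m.rm2 == pytest.approx(0.57, abs=0.05)

    def test_identical_vectors(self, rng):
        y = rng.normal(size=10) + 5
        m = rm_metrics(y, y)
        assert m.k == pytest.approx(1.0) and m.k_prime == pytest.approx(1.0)
        assert m.rm2 == pytest.approx(1.0) and m.rm2_prime == pytest.approx(1.0)
        assert m.delta_rm2 == pytest.approx(0.0)

    def test_swap_exchanges_primed_and_unprimed(self, rng):
        yo = rng.normal(size=12) + 6
        yp = yo + rng.normal(scale=0.3, size=12)
        a = rm_metrics(yo, yp)
        b = rm_metrics(yp, yo)
        assert a.k == pytest.approx(b.k_prime) and a.k_prime == pytest.approx(b.k)
        assert a.rm2 == pytest.approx(b.rm2_prime, abs=1e-12)
        assert a.rm2_prime == pytest.approx(b.rm2, abs=1e-12)
        assert a.delta_rm2 == pytest.approx(b.delta_rm2)

    def test_mean_and_delta_identities(self, rng):
        yo = rng.normal(size=10) + 6
        yp = yo + rng.normal(scale=0.5, size=10)
        m = rm_metrics(yo, yp)
        assert m.rm2_mean == pytest.approx((m.rm2 + m.rm2_prime) / 2)
        assert m.delta_rm2 == pytest.approx(abs(m.rm2 - m.rm2_prime))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rm_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestYRandomization:
    def test_scrambled_models_collapse(self, chalcones):
        res = y_randomization(chalcones, n_runs=100, seed=0)
        assert res.avg_r2 < 0.35  # far below the true model's 0.88
        assert res.avg_q2 < 0
        assert res.crp2 > 0.5  # robustness criterion

    def test_determinism(self, chalcones):
        a = y_randomization(chalcones, n_runs=20, seed=5)
        b = y_randomization(chalcones, n_runs=20, seed=5)
        assert a.runs == b.runs and a.crp2 == b.crp2

    def test_identity_permutation_reproduces_original_fit(self, chalcones, chalcone_model):
        n = len(chalcones.train)
        res = y_randomization(chalcones, permutations=[np.arange(n)])
        r2_orig = fit_statistics(chalcone_model, chalcones).r2
        assert res.runs[0][1] == pytest.approx(r2_orig, abs=1e-12)
        # limit case: all "random" R² equal the original -> cRp² = NaN guard
        # does not trigger since R² == avg; value collapses to 0
        assert res.crp2 == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_random_r2_limit(self, chalcones, chalcone_model):
        """If random models had R²=0, cRp² reduces to the original R²."""
        r2 = fit_statistics(chalcone_model, chalcones).r2
        crp2_limit = np.sqrt(r2) * np.sqrt(r2 - 0.0)
        assert crp2_limit == pytest.approx(r2, abs=1e-12)

    def test_too_few_runs_rejected(self, chalcones):
        with pytest.raises(ValueError, match="n_runs"):
            y_randomization(chalcones, n_runs=5, seed=0)

    def test_permutation_preserves_activity_multiset(self, chalcones):
        y = np.sort(chalcones.train.activities())
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(y))
        assert np.allclose(np.sort(chalcones.train.activities()[perm]), y)


class TestExternalValidation:
    def test_reproduces_published_external_statistics(self, chalcones, chalcone_model):
        ext = external_validation(chalcone_model, chalcones)
        assert ext.r2_test == pytest.approx(0.71, abs=0.01)
        assert ext.q2_f2 == pytest.approx(0.52, abs=0.02)

    def test_golbraikh_tropsha_checklist_passes(self, chalcones, chalcone_model):
        ext = external_validation(chalcone_model, chalcones)
        assert len(ext.gt_checklist) == 4
        assert all(item["passed"] for item in ext.gt_checklist.values())

    def test_q2f2_hand_computed_from_printed_predictions(self, chalcones, chalcones_frame):
        """Direct sum over the five printed test residuals and train mean."""
        test_rows = chalcones_frame[chalcones_frame.split == "test"]
        train_mean = chalcones_frame[chalcones_frame.split == "train"].pIC50_obs.mean()
        sse = ((test_rows.pIC50_obs - test_rows.pIC50_pred) ** 2).sum()
        dev = ((test_rows.pIC50_obs - train_mean) ** 2).sum()
        assert 1 - sse / dev == pytest.approx(0.529, abs=0.002)

    def test_perfect_predictions(self, rng):
        X = rng.normal(size=(20, 2))
        y = 1 + X[:, 0] - X[:, 1]
        recs_train = _toy(X[:15], y[:15]).records
        recs_test = _toy(X[15:], y[15:], split="test").records
        for i, r in enumerate(recs_test):
            r.id = f"t{i}"
        ds = QSARDataset(recs_train + recs_test, ["x0", "x1"])
        model = fit(ds)
        ext = external_validation(model, ds)
        assert ext.r2_test == pytest.approx(1.0, abs=1e-9)
        assert ext.q2_f2 == pytest.approx(1.0, abs=1e-9)
        assert all(item["passed"] for item in ext.gt_checklist.values())

    def test_empty_test_set_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        ds = _toy(X, X[:, 0])
        with pytest.raises(ValueError, match="test"):
            external_validation(fit(ds), ds)


class TestValidationReport:
    def test_full_battery_is_consistent(self, chalcones):
        rep = validation_report(chalcones, n_runs=50, seed=0)
        assert rep.loo.q2_loo == pytest.approx(0.81, abs=0.01)
        assert rep.external.r2_test == pytest.approx(0.71, abs=0.01)
        assert rep.rm_test.delta_rm2 < 0.2  # external acceptability rule
        assert rep.y_randomization.avg_q2 < 0
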