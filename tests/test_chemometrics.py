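"""PLS-1 fitting, the calibration split, factor diagnostics and persistence."""

import numpy as np
import pytest

from irquant.chemometrics import (
    FactorScanRow,
    SplitPlan,
    calibrate,
    factor_scan,
    load_model,
    nipals_pls1,
    pearson_r,
    predict_r,
    rmse,
    save_model,
    select_factors,
    split_calibration_validation,
)
from irquant.exceptions import (
    EmptyWindowError,
    ModelSchemaError,
    ModelSelectionError,
    WindowMismatchError,
)
from irquant.spectra import Spectrum, make_grid
from irquant.synthetic import NOISELESS, realized_r, simulate_calibration_campaign

from .oracles import ols_coef, simpls_pls1


class TestElementaryStats:
    def test_rmse(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([1.0, 2.0], [0.0, 0.0]) == pytest.approx(np.sqrt(2.5))
        assert rmse([5.0], [2.0]) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    def test_pearson(self):
        x = [1.0, 2.0, 3.0, 5.0, 8.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v + 10 for v in x]) == pytest.approx(-1.0)
        # textbook covariance/(sd*sd) oracle on a fixed 5-point set
        y = [2.0, 1.0, 4.0, 4.0, 9.0]
        xa, ya = np.array(x), np.array(y)
        expected = np.cov(xa, ya, ddof=1)[0, 1] / (xa.std(ddof=1) * ya.std(ddof=1))
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSplit:
    def test_default_counts(self, default_campaign):
        scansets, _, r_true = default_campaign
        cal, val = split_calibration_validation(scansets, r_true, SplitPlan(seed=4))
        assert len(cal) == 80 and len(val) == 20
        # every mixture contributes to both sets
        assert {r for _, r in cal} == {r for _, r in val}

    def test_seed_reproducibility(self, default_campaign):
        scansets, _, r_true = default_campaign
        a = split_calibration_validation(scansets, r_true, SplitPlan(seed=11))
        b = split_calibration_validation(scansets, r_true, SplitPlan(seed=11))
        for (s1, r1), (s2, r2) in zip(a[0], b[0]):
            assert r1 == r2 and s1 is s2
        c = split_calibration_validation(scansets, r_true, SplitPlan(seed=12))
        assert any(s1 is not s2 for (s1, _), (s2, _) in zip(a[0], c[0]))

    def test_too_few_scans_rejected(self, default_campaign):
        scansets, _, r_true = default_campaign
        with pytest.raises(ValueError, match="scans"):
            split_calibration_validation(
                scansets, r_true, SplitPlan(seed=0, n_cal=9, n_val=2)
            )


class TestNIPALS:
    def test_single_channel_response_is_exact_at_one_factor(self, rng):
        X = np.zeros((8, 5))
        X[:, 2] = rng.uniform(1.0, 2.0, 8)
        y = 10.0 * X[:, 2]
        fit = nipals_pls1(X, y, 1)
        assert rmse(fit.predict(X), y) == pytest.approx(0.0, abs=1e-10)

    def test_full_rank_equals_least_squares(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        fit = nipals_pls1(X, y, 4)
        pred_ols = y.mean() + (X - X.mean(0)) @ ols_coef(X, y)
        np.testing.assert_allclose(fit.predict(X), pred_ols, atol=1e-8)

    def test_matches_independent_simpls(self, rng):
        for _ in range(5):
            X = rng.normal(size=(8, 6))
            y = rng.normal(size=8)
            for k in (1, 2, 3, 5):
                fit = nipals_pls1(X, y, k)
                pred = y.mean() + (X - X.mean(0)) @ simpls_pls1(X, y, k)
                np.testing.assert_allclose(fit.predict(X), pred, atol=1e-8)

    def test_matches_scikit_learn(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        for k in (1, 3, 5):
            fit = nipals_pls1(X, y, k)
            sk = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(
                fit.predict(X), sk.predict(X).ravel(), atol=1e-8
            )

    def test_guards(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError, match="zero-variance"):
            nipals_pls1(X, np.ones(6), 2)
        with pytest.raises(ValueError, match="k="):
            nipals_pls1(X, rng.normal(size=6), 6)

    def test_residual_collapse_warns_and_truncates(self):
        X = np.zeros((6, 4))
        X[:, 0] = np.arange(6.0)
        y = np.arange(6.0)
        with pytest.warns(UserWarning, match="collapsed"):
            fit = nipals_pls1(X, y, 3)
        assert fit.n_factors < 3


class TestFactorScan:
    def test_rmsec_non_increasing(self, default_campaign):
        scansets, _, r_true = default_campaign
        rows = factor_scan(scansets, r_true, SplitPlan(seed=0), k_max=10)
        rmsecs = [r.rmsec for r in rows]
        assert all(b <= a + 1e-12 for a, b in zip(rmsecs, rmsecs[1:]))
        assert all(np.isfinite([r.rmsev, r.r_c, r.r_v]).all() for r in rows)
        assert all(-1.0 <= r.r_c <= 1.0 and -1.0 <= r.r_v <= 1.0 for r in rows)

    def test_rel_err_missing_when_no_working_level(self, default_campaign):
        scansets, _, r_true = default_campaign
        rows = factor_scan(
            scansets, r_true, SplitPlan(seed=0), k_max=2, working_level=95.0
        )
        assert all(r.rel_err_at_working is None for r in rows)

    def test_overfitting_widens_generalization_gap(self, default_campaign):
        scansets, _, r_true = default_campaign
        rows = factor_scan(scansets, r_true, SplitPlan(seed=0), k_max=10)
        k_sel = select_factors(rows)
        gap = lambda r: r.rmsev - r.rmsec
        assert gap(rows[-1]) > gap(rows[k_sel - 1])


class TestSelectFactors:
    def _rows(self, rs):
        return [
            FactorScanRow(k=i + 1, rmsec=1.0 / (i + 1), rmsev=1.0, r_c=r, r_v=r,
                          rel_err_at_working=None)
            for i, r in enumerate(rs)
        ]

    def test_first_crossing(self):
        assert select_factors(self._rows([0.99, 0.997, 0.9985, 0.999])) == 3

    def test_no_qualifying_k_raises_with_best(self):
        with pytest.raises(ModelSelectionError, match="0.99700"):
            select_factors(self._rows([0.99, 0.995, 0.997]))

    def test_smaller_qualifying_k_preferred(self):
        rows = self._rows([0.999, 0.999])
        rows[1].rmsev = 5.0  # larger gap at the larger qualifying k
        assert select_factors(rows) == 1


class TestNoiselessRecovery:
    def test_noiseless_design_is_recovered_to_fixture_tolerance(self):
        # With noise off the spectra are an exact linear mixture, but the
        # peak normalization makes them a *ratio* of linear forms in the two
        # masses, so a linear model carries a small curvature error even at
        # full rank; the fixture's band balance keeps it below 0.15 R-points.
        scansets, records = simulate_calibration_campaign(
            noise=NOISELESS, seed=0, prep_sigma=0.0
        )
        # noiseless spectra are (near) rank-deficient, so the factor scan
        # legitimately truncates: that warning is part of the contract
        with pytest.warns(UserWarning, match="collapsed"):
            rows = factor_scan(
                scansets, realized_r(records), SplitPlan(seed=0), k_max=4
            )
        assert rows[-1].rmsec < 0.15
        assert rows[-1].r_c > 0.9999


class TestModelPersistence:
    def test_round_trip_predictions_bit_identical(self, default_model, tmp_path,
                                                  default_campaign):
        scansets, _, _ = default_campaign
        probe = scansets[0].spectra[0]
        path = tmp_path / "model.json"
        save_model(default_model, path)
        back = load_model(path)
        assert predict_r(back, probe) == predict_r(default_model, probe)
        assert back.n_factors == default_model.n_factors

    def test_truncated_file_rejected(self, default_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(default_model, path)
        path.write_text(path.read_text()[: 200])
        with pytest.raises(ModelSchemaError):
            load_model(path)

    def test_wrong_schema_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"schema": "something-else/9"}')
        with pytest.raises(ModelSchemaError):
            load_model(path)

    def test_incompatible_spectrum_rejected_at_predict(self, default_model):
        outside = Spectrum(make_grid(900.0, 500.0, 4.0), np.ones(101))
        with pytest.raises((EmptyWindowError, WindowMismatchError)):
            predict_r(default_model, outside)


class TestCalibrate:
    def test_stored_diagnostics_reproducible(self, default_model, default_campaign):
        """Re-predicting the calibration scans reproduces the stored RMSEC."""
        scansets, _, r_true = default_campaign
        cal, _ = split_calibration_validation(
            scansets, r_true, SplitPlan(seed=default_model.seed)
        )
        preds = [predict_r(default_model, s) for s, _ in cal]
        truth = [r for _, r in cal]
        assert rmse(preds, truth) == pytest.approx(default_model.rmsec, abs=1e-8)

    def test_forced_factor_count(self, default_campaign):
        scansets, _, r_true = default_campaign
        model = calibrate(scansets, r_true, SplitPlan(seed=0), n_factors=3, k_max=6)
        assert model.n_factors == 3
        assert model.diagnostics.k == 3

    def test_prediction_at_mean_spectrum_returns_mean_r(self, default_model):
        fit = default_model.pls
        assert fit.predict(fit.x_mean[None, :])[0] == pytest.approx(fit.y_mean)
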