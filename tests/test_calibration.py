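import json

import numpy as np
import pytest

from conftest import small_config
from haycal.calibration import (
    CalibrationError,
    CVSpec,
    acceptance_check,
    calibrate,
    cross_validate,
    grid_search,
    r_squared,
    rpd,
    sec_from_residuals,
)
from haycal.preprocess import MathTreatment
from haycal.simulate import ScatterParams, generate

T144 = MathTreatment.from_string("1,4,4")
CV5 = CVSpec(k=5, seed=0)


class TestStatistics:
    def test_r_squared_perfect_and_mean(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, y) == 1.0
        assert abs(r_squared(y, np.full(20, y.mean()))) < 1e-12

    def test_r_squared_closed_form_negative(self):
        y = np.array([0.0, 1.0, 2.0])
        pred = np.array([0.0, 1.0, 4.0])
        assert np.isclose(r_squared(y, pred), -1.0)

    def test_r_squared_zero_variance_rejected(self):
        with pytest.raises(CalibrationError):
            r_squared(np.ones(5), np.zeros(5))

    @pytest.mark.parametrize(
        "sd_gkg,secv_pct,expected",
        [
            (12.4, 0.34, 3.65),   # high-variation legume DM, ground scan
            (16.6, 0.34, 4.88),   # grass CP, ground scan
            (12.4, 0.51, 2.43),   # legume DM, unground scan
        ],
    )
    def test_rpd_worked_examples(self, sd_gkg, secv_pct, expected):
        assert round(rpd(sd_gkg / 10.0, secv_pct), 2) == expected

    def test_rpd_unity_and_errors(self):
        assert rpd(1.5, 1.5) == 1.0
        with pytest.raises(CalibrationError):
            rpd(0.0, 1.0)
        with pytest.raises(CalibrationError):
            rpd(1.0, -1.0)

    def test_sec_denominator_n_minus_k_minus_1(self):
        resid = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        assert np.isclose(sec_from_residuals(resid, 2), np.sqrt(6 / 3))


class TestCVSpec:
    def test_folds_partition(self):
        folds = CVSpec(k=4, seed=1).folds(22)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(22))
        assert len(folds) == 4

    def test_leave_one_out(self):
        folds = CVSpec(scheme="leave_one_out").folds(7)
        assert len(folds) == 7 and all(f.size == 1 for f in folds)

    def test_invalid_specs(self):
        with pytest.raises(CalibrationError):
            CVSpec(k=1)
        with pytest.raises(CalibrationError):
            CVSpec(scheme="monte_carlo")
        with pytest.raises(CalibrationError):
            CVSpec(k=10).folds(5)


class TestCrossValidate:
    def test_noise_free_linear_response_near_perfect(self, noise_free_dataset):
        res = cross_validate(noise_free_dataset, "CP", T144, cv=CV5)
        assert res.r2_cv > 0.999
        assert res.rpd > 20

    def test_permuted_response_near_zero_r2(self):
        r2s = []
        for seed in range(10):
            ds = generate(small_config(seed=seed, n_samples=60))
            rng = np.random.default_rng(seed + 1000)
            col = ds.reference.values[:, 0].copy()
            rng.shuffle(col)
            ds.reference.values[:, 0] = col
            res = cross_validate(ds, "CP", T144, cv=CVSpec(k=5, seed=seed), cap=4)
            r2s.append(res.r2_cv)
        assert np.mean(r2s) < 0.1

    def test_same_seed_same_result(self, small_dataset):
        r1 = cross_validate(small_dataset, "CP", T144, cv=CV5)
        r2 = cross_validate(small_dataset, "CP", T144, cv=CV5)
        assert r1.secv == r2.secv and r1.r2_cv == r2.r2_cv
        assert np.array_equal(r1.model.b, r2.model.b)

    def test_rpd_identity(self, small_dataset):
        res = cross_validate(small_dataset, "CP", T144, cv=CV5)
        sd = res.provenance["sd_reference"]
        assert abs(res.rpd * res.secv - sd) < 0.005 * sd

    def test_statistics_reported_in_percent(self, small_dataset):
        res = cross_validate(small_dataset, "CP", T144, cv=CV5)
        y_pct = small_dataset.reference.column("CP", unit="percent")
        assert abs(res.provenance["sd_reference"] - np.std(y_pct, ddof=1)) < 1e-9

    def test_secv_not_below_noise_floor(self):
        """Cross-validated error cannot beat the response noise injected."""
        ratios = []
        for seed in range(10):
            ds = generate(small_config(seed=seed, n_samples=80))
            sigma = 0.4  # percent units, added on top of the spectral encoding
            rng = np.random.default_rng(seed + 5000)
            ds.reference.values[:, 0] += 10.0 * sigma * rng.standard_normal(80)
            res = cross_validate(ds, "CP", T144, cv=CVSpec(k=5, seed=seed), cap=6)
            ratios.append(res.secv / sigma)
        assert all(r >= 0.8 for r in ratios)


class TestCalibrateWorkflow:
    def test_screening_reported_in_provenance(self):
        ds = generate(small_config(n_samples=80))
        res = calibrate(ds, "CP", T144, cv=CV5)
        prov = res.provenance
        assert prov["n_initial"] == 80
        assert res.n_selected == 80 - len(prov["removed_spectral"]) - len(prov["removed_lab"])
        assert prov["gh_cutoff"] == 3.0 and prov["t_cutoff"] == 2.5

    def test_infinite_cutoffs_keep_all_samples(self):
        ds = generate(small_config(n_samples=50))
        res = calibrate(ds, "CP", T144, cv=CV5, gh_cutoff=np.inf, t_cutoff=np.inf)
        assert res.n_selected == 50


class TestGridSearch:
    def test_single_treatment_returned(self, small_dataset):
        res = grid_search(small_dataset, "CP", treatments=[T144], cv=CV5, screen=False)
        assert res.treatment == T144

    def test_winner_member_of_grid_and_table_complete(self, small_dataset):
        grid = [MathTreatment.from_string(c) for c in ("1,4,4", "2,8,8", "3,16,16")]
        res = grid_search(small_dataset, "CP", treatments=grid, cv=CV5, screen=False)
        assert res.treatment in grid
        assert len(res.provenance["grid"]) == 3

    def test_first_derivative_wins_when_response_lives_in_narrow_bands(self):
        # white channel noise is amplified ~(2)^d by repeated differencing,
        # so low derivative orders should win on a noisy narrow-band response
        ds = generate(small_config(n_samples=80, noise_sd=0.01))
        grid = [MathTreatment.from_string(c) for c in ("1,4,4", "4,4,4")]
        res = grid_search(ds, "CP", treatments=grid, cv=CV5, screen=False)
        assert res.treatment.derivative_order == 1

    def test_empty_grid_rejected(self, small_dataset):
        with pytest.raises(CalibrationError):
            grid_search(small_dataset, "CP", treatments=[], cv=CV5)


class TestAcceptance:
    def _result(self, r2_cv, rpd_val, **kw):
        from haycal.calibration import CalibrationResult

        return CalibrationResult(
            analyte="CP", treatment=T144, n_selected=100, n_factors=5,
            r2_cal=0.95, sec=kw.get("sec", 0.3), r2_cv=r2_cv,
            secv=kw.get("secv", 0.35), rpd=rpd_val,
            accepted=(r2_cv > 0.80 and rpd_val > 2),
        )

    def test_good_model_accepted(self):
        assert acceptance_check(self._result(0.95, 4.88))

    def test_boundary_r2_rejected(self):
        assert not acceptance_check(self._result(0.80, 3.0))

    def test_low_rpd_rejected(self):
        assert not acceptance_check(self._result(0.90, 1.9))

    def test_secv_sec_ratio_warning_logged(self, caplog):
        with caplog.at_level("WARNING", logger="haycal.calibration"):
            acceptance_check(self._result(0.9, 3.0, sec=0.2, secv=0.5))
        assert any("SECV/SEC" in r.message for r in caplog.records)
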