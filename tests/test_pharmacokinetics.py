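"""Non-compartmental PK: trapezoid AUC, phase fits, clearance, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geldepot as gd
from geldepot.errors import ValidationError
from geldepot.synthetic_data import closed_form_auc


def series(t, c, t_admin=24.0):
    return gd.PlasmaSeries(t=np.asarray(t, float), C=np.asarray(c, float), t_admin=t_admin)


class TestTrapezoidAUC:
    def test_single_trapezoid(self):
        s = series([0, 24], [0, 2084])
        assert gd.auc_trapezoid(s) == pytest.approx(2084 / 2 * 24 / 60)

    def test_rectangle(self):
        s = series([0, 30, 60], [100, 100, 100], t_admin=30)
        assert gd.auc_trapezoid(s) == pytest.approx(100.0)

    def test_dense_biexponential_matches_analytic_integral(self, noiseless_truth):
        t = np.linspace(0, 264, 20_001)
        s = series(t, gd.plasma_concentration(noiseless_truth, t))
        assert gd.auc_trapezoid(s) == pytest.approx(
            closed_form_auc(noiseless_truth, 0, 264), rel=1e-3
        )

    def test_endpoints_must_be_sampled(self):
        s = series([0, 10, 20], [0, 5, 3], t_admin=10)
        with pytest.raises(ValidationError, match="sampled"):
            gd.auc_trapezoid(s, 0, 15)

    @given(st.integers(1, 14))
    @settings(deadline=None, derandomize=True)
    def test_additivity_at_any_interior_sample(self, k):
        rng = np.random.default_rng(99)
        t = np.sort(rng.uniform(0, 264, 16))
        c = rng.uniform(0, 3000, 16)
        s = series(t, c, t_admin=t[8])
        total = gd.auc_trapezoid(s, t[0], t[-1])
        split = gd.auc_trapezoid(s, t[0], t[k]) + gd.auc_trapezoid(s, t[k], t[-1])
        assert split == pytest.approx(total, rel=1e-12)

    def test_overestimates_convex_decay(self, noiseless_truth):
        t = np.array([24.0, 64.0, 104.0, 144.0, 184.0, 224.0, 264.0])
        s = series(t, gd.plasma_concentration(noiseless_truth, t))
        sparse = gd.auc_trapezoid(s)
        exact = closed_form_auc(noiseless_truth, 24, 264)
        assert sparse > exact  # chords lie above a convex decay


class TestPartitionAndClearance:
    def test_poldox_component_sum(self):
        # printed component AUCs behave additively through the partition contract
        assert 252.4 + 599.7 == pytest.approx(852.1)
        assert 1338.7 + 944.7 == pytest.approx(2283.4)

    def test_partition_sums_exactly(self, noiseless_truth):
        s = gd.simulate_plasma(noiseless_truth)
        a, p, tot = gd.partition_auc(s)
        assert tot == a + p  # exact, not approximate
        assert tot == pytest.approx(gd.auc_trapezoid(s), rel=1e-12)

    def test_partition_requires_sampled_t_admin(self):
        s = series([0, 10, 30], [0, 5, 1], t_admin=20)
        with pytest.raises(ValidationError, match="t_admin"):
            gd.partition_auc(s)

    def test_zero_series(self):
        s = series([0, 24, 264], [0, 0, 0])
        assert gd.partition_auc(s) == (0.0, 0.0, 0.0)

    def test_clearance_worked_examples(self):
        assert gd.clearance_over_f(40.0, 852.1) == pytest.approx(0.0469, abs=5e-4)
        assert round(gd.clearance_over_f(40.0, 852.1), 2) == 0.05
        assert round(gd.clearance_over_f(40.0, 2283.4), 2) == 0.02

    def test_clearance_linearity_and_errors(self):
        assert gd.clearance_over_f(80.0, 100.0) == 2 * gd.clearance_over_f(40.0, 100.0)
        with pytest.raises(ValidationError):
            gd.clearance_over_f(40.0, 0.0)


class TestCmaxTmax:
    def test_peak_extraction(self):
        s = series([0, 10, 25, 40], [0, 900, 2084, 700], t_admin=25)
        assert gd.cmax_tmax(s) == (2084.0, 25.0)

    def test_monotone_series_peaks_at_last_sample(self):
        s = series([0, 10, 20, 24], [0, 1, 2, 3])
        assert gd.cmax_tmax(s) == (3.0, 24.0)

    def test_tie_breaks_to_earlier_time(self):
        s = series([0, 10, 20, 24], [0, 5, 5, 1])
        assert gd.cmax_tmax(s) == (5.0, 10.0)


class TestPhaseRates:
    def test_exact_log_linear_decay(self):
        t = np.arange(30, 90, 10, dtype=float)
        c = 100.0 * 10 ** (-0.02 * t)
        s = series(np.concatenate([[0.0, 24.0], t]), np.concatenate([[0.0, 90.0], c]))
        with pytest.warns(UserWarning):  # equal rates look like mixed windows
            alpha, beta = gd.phase_rate_constants(s, alpha_window=(30, 50), beta_window=(60, 80))
        assert alpha == pytest.approx(0.02 * 2.303, rel=1e-9)
        assert beta == pytest.approx(0.02 * 2.303, rel=1e-9)
        assert gd.half_life(0.04606) == pytest.approx(15.05, abs=0.01)

    def test_beta_recovered_from_noiseless_truth(self, noiseless_truth):
        s = gd.simulate_plasma(noiseless_truth)
        alpha, beta = gd.phase_rate_constants(s)  # default windows
        assert beta == pytest.approx(noiseless_truth.beta, rel=0.05)
        # alpha from raw mixed curve is biased upward-bounded but positive
        assert alpha > beta

    def test_residual_stripping_recovers_both_phases(self, noiseless_truth):
        s = gd.simulate_plasma(noiseless_truth)
        alpha, beta = gd.phase_rate_constants(s, strip=True)
        assert alpha == pytest.approx(noiseless_truth.alpha, rel=0.10)
        assert beta == pytest.approx(noiseless_truth.beta, rel=0.10)

    def test_window_validation(self, noiseless_truth):
        s = gd.simulate_plasma(noiseless_truth)
        with pytest.raises(ValidationError, match="administration"):
            gd.phase_rate_constants(s, alpha_window=(10, 20), beta_window=(100, 264))
        with pytest.raises(ValidationError, match="3 points"):
            gd.phase_rate_constants(s, alpha_window=(26, 29), beta_window=(100, 264))
        zero = series([0, 24, 30, 40, 50, 60, 80], [0, 10, 5, 0, 2, 1, 1])
        with pytest.raises(ValidationError, match="nonpositive"):
            gd.phase_rate_constants(zero, alpha_window=(30, 50), beta_window=(50, 80))

    def test_mixed_windows_warn_not_error(self):
        # early window decays slower than late window: alpha < beta
        t = np.array([0, 24, 30, 40, 50, 60, 70, 80], dtype=float)
        c = np.array([0, 100, 90, 80, 70, 30, 10, 3], dtype=float)
        s = series(t, c)
        with pytest.warns(UserWarning, match="phase windows"):
            gd.phase_rate_constants(s, alpha_window=(30, 50), beta_window=(60, 80))

    def test_half_life_identities(self):
        assert gd.half_life(np.log(2)) == pytest.approx(1.0)
        with pytest.raises(ValidationError):
            gd.half_life(0.0)


class TestFullNCA:
    def test_noiseless_recovery(self, noiseless_truth):
        s = gd.simulate_plasma(noiseless_truth)
        p = gd.nca(s, dose_mg=noiseless_truth.dose, strip=True)
        assert p.t_half_beta == pytest.approx(np.log(2) / noiseless_truth.beta, rel=0.10)
        assert p.t_half_alpha == pytest.approx(np.log(2) / noiseless_truth.alpha, rel=0.10)
        cl_true = noiseless_truth.dose / closed_form_auc(noiseless_truth, s.t[0], s.t[-1])
        assert p.CL_F == pytest.approx(cl_true, rel=0.10)
        assert p.Cmax == pytest.approx(
            gd.plasma_concentration(noiseless_truth, np.array([24.0]))[0], rel=1e-9
        )
        assert p.Tmax == 24.0

    def test_invariants(self, noiseless_truth):
        s = gd.simulate_plasma(noiseless_truth)
        p = gd.nca(s, dose_mg=40.0, strip=True)
        assert p.AUC_total == p.AUC_admin + p.AUC_post
        assert p.t_half_alpha < p.t_half_beta
        assert min(p.AUC_admin, p.AUC_post) >= 0


class TestCalibration:
    def test_exact_least_squares_on_collinear_standards(self):
        conc = np.array([0.0, 10.0, 20.0, 40.0])
        ratios = 0.05 * conc + 0.002
        cal = gd.fit_calibration(conc, ratios)
        assert cal.slope == pytest.approx(0.05, rel=1e-12)
        assert cal.intercept == pytest.approx(0.002, rel=1e-9)

    def test_single_point_proportionality(self):
        cal = gd.single_point_calibration(standard_conc=10.0, standard_ratio=0.5)
        table = pd.DataFrame(
            {"sample": ["u"], "area_analyte": [1.0], "area_IS": [1.0]}
        )
        out = gd.quantify_from_peaks(table, cal)
        assert out["conc"][0] == pytest.approx(20.0)  # 2x the standard ratio

    def test_noisy_standards_recover_slope(self):
        """Monte-Carlo: 5% CV triplicate standards recover the generating
        slope within 10% in every one of 100 seeded assays (median well
        inside)."""
        conc = np.tile([5.0, 10.0, 20.0, 40.0], 3)
        slopes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ratios = 0.05 * conc * rng.lognormal(0, 0.05, size=conc.size)
            slopes.append(gd.fit_calibration(conc, ratios).slope)
        assert np.median(slopes) == pytest.approx(0.05, rel=0.10)

    def test_below_quantification_flagged_not_negative(self):
        cal = gd.CalibrationCurve(slope=0.05, intercept=0.01)
        table = pd.DataFrame(
            {"sample": ["low", "ok"], "area_analyte": [0.001, 1.0], "area_IS": [1.0, 1.0]}
        )
        out = gd.quantify_from_peaks(table, cal)
        assert out["bql"][0] and np.isnan(out["conc"][0])
        assert not out["bql"][1] and out["conc"][1] > 0

    def test_tissue_normalization_and_is_validation(self):
        cal = gd.CalibrationCurve(slope=0.05, intercept=0.0)
        table = pd.DataFrame(
            {"sample": ["t"], "area_analyte": [0.5], "area_IS": [1.0], "mg_tissue": [25.0]}
        )
        out = gd.quantify_from_peaks(table, cal)
        assert out["conc_per_mg"][0] == pytest.approx(10.0 / 25.0)
        bad = table.assign(area_IS=[0.0])
        with pytest.raises(ValidationError, match="internal-standard"):
            gd.quantify_from_peaks(bad, cal)
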