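"""Fixed-intercept fits, the exponential size model, and c-Ag estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sscquant.calibration import (
    AG_BPEI_A549_SIZE_MODEL,
    AG_BPEI_A549_SLOPES,
    CalibrationModel,
    CalibrationPoint,
    SizeCalibration,
    SlopeSizeModel,
    combined_slope,
    estimate_c_ag,
    fit_size_calibration,
    fit_slope_size_model,
    r_squared_forced,
    reference_model,
)
from sscquant.cytometry import ExposureCondition
from sscquant.errors import (
    CoverageError,
    DegenerateRegressorError,
    DomainError,
    IdentifiabilityError,
)


def _points(nssc, c_ag, diameter=60.0):
    cond = ExposureCondition(diameter, "upright", 6.0)
    return [
        CalibrationPoint(nssc=x, c_ag=y, condition=cond) for x, y in zip(nssc, c_ag)
    ]


def _cals(pairs):
    return [
        SizeCalibration(core_diameter=d, slope=s, r_squared=1.0, n_points=1)
        for d, s in pairs
    ]


PUBLISHED_PAIRS = sorted(AG_BPEI_A549_SLOPES.items())


class TestFitSizeCalibration:
    def test_single_point_slope(self):
        cal = fit_size_calibration(_points([2.0], [9423.0], 40.0), 40.0)
        assert cal.slope == pytest.approx(9423.0)

    def test_exact_line(self):
        nssc = [1.5, 2.0, 5.0, 10.0]
        cal = fit_size_calibration(
            _points(nssc, [500.0 * (x - 1) for x in nssc]), 60.0
        )
        assert cal.slope == pytest.approx(500.0, rel=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_matches_brute_force_closed_form(self, rng):
        """Σxy/Σx² computed by an explicit loop is the oracle."""
        for _ in range(20):
            n = int(rng.integers(2, 40))
            nssc = rng.uniform(1.01, 23, n)
            c_ag = rng.uniform(0, 1e5, n)
            cal = fit_size_calibration(_points(nssc, c_ag), 60.0)
            sxy = sum((x - 1) * y for x, y in zip(nssc, c_ag))
            sxx = sum((x - 1) ** 2 for x in nssc)
            assert cal.slope == pytest.approx(sxy / sxx, rel=1e-10)

    def test_all_points_at_unity_nssc_is_degenerate(self):
        with pytest.raises(DegenerateRegressorError):
            fit_size_calibration(_points([1.0, 1.0], [0.0, 10.0]), 60.0)

    def test_mixed_diameters_rejected(self):
        pts = _points([2.0], [100.0], 40.0) + _points([2.0], [100.0], 60.0)
        with pytest.raises(DomainError):
            fit_size_calibration(pts, 40.0)


class TestRSquaredForced:
    def test_perfect_fit(self):
        nssc = [2.0, 3.0, 4.0]
        pts = _points(nssc, [10.0 * (x - 1) for x in nssc])
        assert r_squared_forced(pts, 10.0) == 1.0

    def test_negative_when_forced_line_beats_nothing(self):
        # hand computation: x=(1,1), y=(0,10), slope 0 → SS_res=100, SS_tot=50
        # (about ȳ=5), so the centered convention gives 1 − 100/50 = −1
        pts = _points([2.0, 2.0], [0.0, 10.0])
        assert r_squared_forced(pts, 0.0) == pytest.approx(-1.0)

    def test_constant_y_returns_nan_sentinel(self):
        pts = _points([2.0, 3.0], [5.0, 5.0])
        assert math.isnan(r_squared_forced(pts, 1.0))

    def test_fitted_slope_maximizes_r_squared(self, rng):
        nssc = rng.uniform(1.1, 10, 30)
        c_ag = 800 * (nssc - 1) * (1 + 0.1 * rng.standard_normal(30))
        pts = _points(nssc, np.maximum(c_ag, 0))
        best = fit_size_calibration(pts, 60.0).slope
        r2_best = r_squared_forced(pts, best)
        for slope in np.linspace(0.2 * best, 3 * best, 25):
            assert r_squared_forced(pts, float(slope)) <= r2_best + 1e-12


class TestSlopeSizeModel:
    def test_published_pairs_recover_published_coefficients(self):
        model = fit_slope_size_model(_cals(PUBLISHED_PAIRS))
        assert model.a == pytest.approx(199.0, rel=0.10)
        assert model.b == pytest.approx(161933.0, rel=0.10)
        assert model.k == pytest.approx(0.072, rel=0.10)

    def test_noiseless_exponential_recovered_exactly(self):
        a, b, k = 100.0, 50_000.0, 0.05
        pairs = [(d, a + b * math.exp(-k * d)) for d in (30, 60, 90, 120, 150)]
        model = fit_slope_size_model(_cals(pairs))
        assert model.a == pytest.approx(a, rel=1e-6)
        assert model.b == pytest.approx(b, rel=1e-6)
        assert model.k == pytest.approx(k, rel=1e-6)
        assert model.rss == pytest.approx(0.0, abs=1e-6)

    def test_decay_rate_recovery_bias_under_noise(self, rng):
        """Median-free bias check: mean recovered k within 10% over replicates."""
        a, b, k = 199.0, 161933.0, 0.072
        diameters = np.array([40.0, 60.0, 80.0, 100.0, 200.0])
        ks = []
        for _ in range(100):
            slopes = (a + b * np.exp(-k * diameters)) * (
                1 + 0.05 * rng.standard_normal(5)
            )
            model = fit_slope_size_model(_cals(zip(diameters, slopes)))
            ks.append(model.k)
        assert np.mean(ks) == pytest.approx(k, rel=0.10)

    def test_too_few_diameters(self):
        with pytest.raises(IdentifiabilityError):
            fit_slope_size_model(_cals([(40, 9423), (60, 2301)]))

    def test_residual_no_worse_than_any_start(self):
        model = fit_slope_size_model(_cals(PUBLISHED_PAIRS))
        d = np.array([p[0] for p in PUBLISHED_PAIRS], dtype=float)
        s = np.array([p[1] for p in PUBLISHED_PAIRS], dtype=float)
        for k0 in np.linspace(0.01, 0.2, 20):
            b0 = s[0] / math.exp(-k0 * d[0])
            rss0 = float(np.sum((0.0 + b0 * np.exp(-k0 * d) - s) ** 2))
            assert model.rss <= rss0 + 1e-6


class TestCombinedSlope:
    def test_value_at_40nm_with_published_coefficients(self):
        # direct evaluation, independent of the fitter: 199 + 161933 e^(-2.88)
        assert combined_slope(AG_BPEI_A549_SIZE_MODEL, 40.0) == pytest.approx(
            9289.07, rel=1e-4
        )

    def test_large_diameter_asymptote(self):
        assert combined_slope(AG_BPEI_A549_SIZE_MODEL, 1e6) == pytest.approx(199.0)

    def test_zero_diameter_limit_is_a_plus_b(self):
        model = SlopeSizeModel(a=199.0, b=161933.0, k=0.072)
        assert combined_slope(model, 1e-12) == pytest.approx(199.0 + 161933.0)

    @given(d1=st.floats(1, 500), d2=st.floats(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_diameter(self, d1, d2):
        lo, hi = sorted((d1, d2))
        if lo == hi:
            return
        m = AG_BPEI_A549_SIZE_MODEL
        assert combined_slope(m, lo) > combined_slope(m, hi)

    def test_published_per_size_slopes_are_ordered(self):
        slopes = [s for _, s in PUBLISHED_PAIRS]
        assert slopes == sorted(slopes, reverse=True)
        assert slopes == [9423, 2301, 967, 204, 159]


class TestEstimateCAg:
    def test_control_identity(self):
        assert estimate_c_ag(1.0, 9423.0).c_ag_est == 0.0

    def test_published_40nm_line_at_nssc_2(self):
        res = estimate_c_ag(2.0, AG_BPEI_A549_SLOPES[40.0], core_diameter=40.0)
        assert res.c_ag_est == 9423.0

    def test_sub_control_returned_and_flagged(self):
        res = estimate_c_ag(0.9, 1000.0)
        assert res.c_ag_est == pytest.approx(-100.0)
        assert res.sub_control
        assert estimate_c_ag(0.9, 1000.0, clamp=True).c_ag_est == 0.0

    def test_out_of_domain_flag(self):
        assert estimate_c_ag(25.0, 100.0).out_of_domain
        assert not estimate_c_ag(20.0, 100.0).out_of_domain

    def test_non_positive_slope_rejected(self):
        with pytest.raises(DomainError):
            estimate_c_ag(2.0, 0.0)

    def test_round_trip_through_fit(self, rng):
        """Noise-free points regenerate their own c_ag through fit + estimate."""
        nssc = rng.uniform(1.1, 20, 15)
        slope_true = 777.0
        pts = _points(nssc, [slope_true * (x - 1) for x in nssc])
        slope = fit_size_calibration(pts, 60.0).slope
        for p in pts:
            assert estimate_c_ag(p.nssc, slope).c_ag_est == pytest.approx(
                p.c_ag, rel=1e-10
            )


class TestCalibrationModel:
    def test_fit_groups_by_diameter_and_serializes(self, tmp_path, rng):
        pts = []
        for d, m in PUBLISHED_PAIRS:
            nssc = rng.uniform(1.2, 10, 8)
            pts += _points(nssc, [m * (x - 1) for x in nssc], d)
        model = CalibrationModel.fit(pts)
        for d, m in PUBLISHED_PAIRS:
            assert model.per_size[d].slope == pytest.approx(m, rel=1e-9)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = CalibrationModel.load(path)
        assert loaded.per_size.keys() == model.per_size.keys()
        assert loaded.size_model.k == pytest.approx(model.size_model.k)

    def test_per_size_requires_calibrated_diameter(self):
        model = reference_model()
        with pytest.raises(CoverageError):
            model.slope_for(70.0, mode="per_size")
        # the combined model interpolates at uncalibrated sizes
        assert model.slope_for(70.0, mode="combined") > 0

    def test_size_model_interpolates_near_per_size_slopes(self):
        """Within the fit's residual, m(d) tracks each per-size slope."""
        model = fit_slope_size_model(_cals(PUBLISHED_PAIRS))
        resid_budget = math.sqrt(model.rss) + 1e-9
        for d, s in PUBLISHED_PAIRS:
            assert abs(model.slope(d) - s) <= resid_budget
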