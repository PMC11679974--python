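import numpy as np
import pytest

from monofilm import (
    AreaIsotherm,
    DegenerateLinesError,
    InsufficientPointsError,
    NoPlateauError,
    NoRootInRangeError,
    PressureAmountIsotherm,
    ValidationError,
    amount_to_area,
    area_at_pressure,
    detect_saturation,
    fit_isotherm_polynomial,
    popc_like_truth,
    simulate_area_isotherm,
    simulate_pressure_amount,
    to_area_isotherm,
)
from monofilm.constants import N_A
from monofilm.isotherm import IsothermPolynomial


def two_line_isotherm(slope=4.0, intercept=-100.0, pi_plateau=50.0):
    """Noiseless piecewise-linear trace: pi = slope*n + intercept up to the
    plateau, then flat.  Steep points stay below pi_plateau - 0.5 so the
    plateau set is pure."""
    n_steep = np.arange(30.0, 37.0)  # pi from 20 to 44
    n_flat = np.array([38.0, 40.0, 42.0, 44.0])
    n = np.concatenate([n_steep, n_flat])
    pi = np.where(n < 37.5, slope * n + intercept, pi_plateau)
    return PressureAmountIsotherm(tuple(n), tuple(pi), trough_area_cm2=100.0)


class TestDetectSaturation:
    def test_exact_two_line_geometry(self):
        sat = detect_saturation(two_line_isotherm())
        assert sat.n_sat_nmol == pytest.approx(37.5, abs=1e-9)
        assert sat.pi_sat_mNm == pytest.approx(50.0, abs=1e-9)
        assert sat.A_sat_A2 == pytest.approx(
            100.0 * 1e16 / (37.5e-9 * N_A), rel=1e-12
        )

    def test_no_plateau_raises(self):
        n = np.arange(10.0, 25.0)
        iso = PressureAmountIsotherm(
            tuple(n), tuple(2.0 * n), trough_area_cm2=100.0
        )
        with pytest.raises(NoPlateauError):
            detect_saturation(iso)

    def test_near_parallel_lines_raise(self):
        n = np.arange(10.0, 26.0)
        # gentle kink: slopes 0.010 vs 0.008, far below 1 degree apart
        pi = np.where(n < 18, 0.010 * n, 0.008 * n + 0.036)
        iso = PressureAmountIsotherm(tuple(n), tuple(pi), trough_area_cm2=100.0)
        with pytest.raises((DegenerateLinesError, NoPlateauError)):
            detect_saturation(iso)

    def test_synthetic_recovery_single_seed(self):
        truth = popc_like_truth(seed=11, noise_sd_pi_mNm=0.3)
        sat = detect_saturation(simulate_pressure_amount(truth))
        assert sat.A_sat_A2 == pytest.approx(truth.A_sat_A2, rel=0.05)

    def test_too_few_points_raise(self):
        iso = PressureAmountIsotherm(
            tuple(np.arange(1.0, 7.0)), (0.0, 1, 2, 3, 3, 3), trough_area_cm2=10.0
        )
        with pytest.raises(InsufficientPointsError):
            detect_saturation(iso, steep_window=5)


class TestAreaConversion:
    def test_unit_arithmetic(self):
        assert float(amount_to_area(33.6, 100.0)) == pytest.approx(
            1e18 / (33.6 * 6.022141e14), rel=1e-12
        )

    def test_inverse_proportionality(self):
        assert float(amount_to_area(20.0, 100.0)) == pytest.approx(
            2.0 * float(amount_to_area(40.0, 100.0)), rel=1e-12
        )

    def test_round_trip_against_generator_truth(self):
        truth = popc_like_truth(seed=0, noise_sd_pi_mNm=0.0)
        iso = simulate_pressure_amount(truth)
        aiso = to_area_isotherm(iso)
        expected = amount_to_area(np.array(iso.n_nmol), iso.trough_area_cm2)
        err = np.abs(np.array(aiso.area_A2) - expected) / expected
        assert err.max() < 1e-12

    def test_preserves_count_and_monotone(self):
        truth = popc_like_truth(seed=0, noise_sd_pi_mNm=0.0)
        iso = simulate_pressure_amount(truth)
        aiso = to_area_isotherm(iso)
        assert len(aiso) == len(iso)
        assert np.all(np.diff(aiso.area_A2) < 0)  # n increasing -> area decreasing


class TestPolynomialFit:
    def test_exact_linear_data(self):
        area = np.linspace(40.0, 90.0, 12)
        aiso = AreaIsotherm(tuple(area), tuple(120.0 - area))
        model = fit_isotherm_polynomial(aiso, degree=1)
        assert model.coeffs == pytest.approx((120.0, -1.0), abs=1e-9)
        assert model.residual_rms < 1e-9

    def test_underdetermined_fit_rejected(self):
        aiso = AreaIsotherm((40.0, 50.0, 60.0), (30.0, 20.0, 10.0))
        with pytest.raises(InsufficientPointsError):
            fit_isotherm_polynomial(aiso, degree=3)

    def test_restriction_to_small_areas(self):
        # points above max_area distort a global fit; they must be ignored
        area = np.concatenate([np.linspace(40, 95, 10), [150.0, 200.0]])
        pi = np.where(area <= 100, 120.0 - area, 80.0)
        model = fit_isotherm_polynomial(
            AreaIsotherm(tuple(area), tuple(pi)), max_area_A2=100.0, degree=1
        )
        assert model.coeffs == pytest.approx((120.0, -1.0), abs=1e-9)
        assert model.fitted_area_range[1] <= 100.0

    def test_noisy_cubic_coefficients_within_3_sigma(self):
        rng = np.random.default_rng(42)
        true = np.array([150.0, -2.5, 0.012, -3e-5])
        area = np.linspace(40.0, 95.0, 60)
        sd = 0.2
        pi = np.polynomial.polynomial.polyval(area, true) + rng.normal(0, sd, 60)
        model = fit_isotherm_polynomial(AreaIsotherm(tuple(area), tuple(pi)))
        X = np.vander(area, 4, increasing=True)
        cov = sd**2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(np.array(model.coeffs) - true) < 3.0 * se)


class TestAreaAtPressure:
    def test_linear_inversion(self):
        model = IsothermPolynomial((120.0, -1.0), (40.0, 100.0), 1, 0.0)
        assert area_at_pressure(model, 30.0) == pytest.approx(90.0)

    def test_recovers_constructed_crossing(self):
        truth = popc_like_truth(seed=3, noise_sd_pi_mNm=0.0, degree=3)
        aiso = simulate_area_isotherm(truth, np.linspace(50.0, 99.0, 30))
        model = fit_isotherm_polynomial(aiso)
        assert area_at_pressure(model, 30.0) == pytest.approx(64.5, abs=0.1)

    def test_round_trip_identity_on_valid_branch(self):
        truth = popc_like_truth(seed=5, noise_sd_pi_mNm=0.2)
        aiso = simulate_area_isotherm(truth, np.linspace(50.0, 99.0, 40))
        model = fit_isotherm_polynomial(aiso)
        for pi in (10.0, 20.0, 30.0, 40.0):
            area = area_at_pressure(model, pi)
            assert model(area) == pytest.approx(pi, abs=1e-8)

    def test_pressure_outside_range_rejected(self):
        model = IsothermPolynomial((120.0, -1.0), (40.0, 100.0), 1, 0.0)
        with pytest.raises(NoRootInRangeError):
            area_at_pressure(model, 500.0)


class TestIsothermTypes:
    def test_amount_isotherm_validation(self):
        with pytest.raises(ValidationError):
            PressureAmountIsotherm((3.0, 2.0, 4.0, 5.0, 6.0, 7.0), (0,) * 6, 100.0)
        with pytest.raises(ValidationError):
            PressureAmountIsotherm(
                tuple(np.arange(6.0)), (0.0, 1, 2, 3, -1, 5), 100.0
            )

    def test_area_isotherm_positive_areas(self):
        with pytest.raises(ValidationError):
            AreaIsotherm((50.0, -1.0), (10.0, 20.0))
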