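import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plmox.calibration import (
    CalibrationCurve,
    CalibrationPoint,
    SplineCalibrationCurve,
    fit_calibration_curve,
    interpolate_curve,
    po2_from_tau,
    tau_from_po2,
)
from plmox.synthetic import generate_calibration_dataset

from oracles import sv_grid_search


def _points(tau0, kq, po2s, temperature=37.0, tau_noise=None):
    taus = 1.0 / (1.0 / tau0 + kq * np.asarray(po2s, dtype=float))
    if tau_noise is not None:
        taus = taus * (1.0 + tau_noise)
    return [
        CalibrationPoint(lifetime_us=float(t), po2_mmHg=float(p), temperature_c=temperature)
        for t, p in zip(taus, po2s)
    ]


class TestFit:
    def test_noiseless_points_recover_parameters_exactly(self):
        pts = _points(40.0, 1.0e-3, [0, 40, 80, 120, 159])
        c = fit_calibration_curve(pts, 37.0)
        assert c.tau0_us == pytest.approx(40.0, rel=1e-9)
        assert c.kq_per_us_mmHg == pytest.approx(1.0e-3, rel=1e-9)
        assert c.fit_residual == pytest.approx(0.0, abs=1e-9)
        assert c.valid_po2_range == (0.0, 159.0)
        assert c.warning is None

    def test_noisy_fit_matches_truth_and_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        noise = 0.01 * rng.standard_normal(5)
        pts = _points(40.0, 1.0e-3, [0, 40, 80, 120, 159], tau_noise=noise)
        c = fit_calibration_curve(pts, 37.0)
        assert c.tau0_us == pytest.approx(40.0, rel=0.05)
        assert c.kq_per_us_mmHg == pytest.approx(1.0e-3, rel=0.05)
        tau0_o, kq_o = sv_grid_search(
            np.array([p.po2_mmHg for p in pts]), np.array([p.lifetime_us for p in pts])
        )
        assert c.tau0_us == pytest.approx(tau0_o, rel=0.005)
        assert c.kq_per_us_mmHg == pytest.approx(kq_o, rel=0.005)

    def test_default_synthetic_runs_store_the_four_standard_temperatures(self, sensor):
        temps = (32.4, 34.2, 35.7, 37.0)
        curves = [
            fit_calibration_curve(generate_calibration_dataset(sensor, t), t) for t in temps
        ]
        assert tuple(c.temperature_c for c in curves) == temps

    def test_too_few_points_raise(self):
        pts = _points(40.0, 1.0e-3, [0, 80, 159])
        with pytest.raises(ValueError, match=">= 4"):
            fit_calibration_curve(pts, 37.0)

    def test_narrow_po2_span_raises(self):
        pts = _points(40.0, 1.0e-3, [50, 60, 70, 80])
        with pytest.raises(ValueError, match="span"):
            fit_calibration_curve(pts, 37.0)

    def test_non_monotone_data_beyond_noise_records_warning(self):
        pts = _points(40.0, 1.0e-3, [0, 40, 80, 120, 159])
        # plant a gross inversion: lifetime rises with Po2 at the third point
        bad = list(pts)
        bad[2] = CalibrationPoint(lifetime_us=45.0, po2_mmHg=80.0, temperature_c=37.0)
        c = fit_calibration_curve(bad, 37.0)
        assert c.warning is not None and "non-monotone" in c.warning

    def test_mixed_temperature_points_rejected(self):
        pts = _points(40.0, 1.0e-3, [0, 40, 80, 159]) + _points(
            45.0, 0.9e-3, [0, 40, 80, 159], temperature=32.4
        )
        with pytest.raises(ValueError, match="temperature"):
            fit_calibration_curve(pts, 37.0)


class TestForwardInverse:
    def test_zero_po2_returns_tau0_exactly(self):
        c = CalibrationCurve(temperature_c=37.0, tau0_us=40.0, kq_per_us_mmHg=1e-3)
        assert tau_from_po2(c, 0.0) == 40.0

    def test_forward_arithmetic(self):
        c = CalibrationCurve(temperature_c=37.0, tau0_us=40.0, kq_per_us_mmHg=1e-3)
        assert tau_from_po2(c, 50.0) == pytest.approx(1.0 / (0.025 + 0.05), rel=1e-12)

    def test_tau_strictly_decreasing_and_vanishing_at_large_po2(self):
        c = CalibrationCurve(temperature_c=37.0, tau0_us=40.0, kq_per_us_mmHg=1e-3)
        grid = np.linspace(0.0, 160.0, 100)
        taus = c.tau_from_po2(grid)
        assert np.all(np.diff(taus) < 0)
        assert c.tau_from_po2(1e7) < 1e-3

    def test_negative_po2_rejected(self):
        c = CalibrationCurve(temperature_c=37.0, tau0_us=40.0, kq_per_us_mmHg=1e-3)
        with pytest.raises(ValueError):
            tau_from_po2(c, -1.0)

    def test_tau0_inverts_to_zero(self, cal_set):
        curve = cal_set.curve_at(37.0)
        assert po2_from_tau(cal_set, curve.tau0_us, 37.0) == 0.0

    def test_roundtrip_identity_at_42_mmHg(self, cal_set):
        curve = cal_set.curve_at(37.0)
        tau = curve.tau_from_po2(42.0)
        assert po2_from_tau(cal_set, tau, 37.0) == pytest.approx(42.0, abs=1e-9)

    def test_roundtrip_over_po2_grid(self, cal_set):
        curve = cal_set.curve_at(35.7)
        for p in np.linspace(0.0, 160.0, 33):
            assert curve.po2_from_tau(curve.tau_from_po2(p)) == pytest.approx(p, abs=1e-6)

    def test_colder_conversion_of_fixed_tau_yields_higher_po2(self, cal_set, sensor):
        tau = sensor.tau(50.0, 37.0)
        assert po2_from_tau(cal_set, tau, 32.4) > po2_from_tau(cal_set, tau, 37.0)

    def test_out_of_range_tau_names_admissible_interval(self, cal_set):
        with pytest.raises(ValueError, match="admissible interval"):
            po2_from_tau(cal_set, 100.0, 37.0)

    def test_temperature_beyond_slack_rejected(self, cal_set):
        with pytest.raises(ValueError, match="outside calibrated range"):
            po2_from_tau(cal_set, 20.0, 45.0)


class TestInterpolation:
    def test_node_temperature_returns_stored_curve_object(self, cal_set):
        c = interpolate_curve(cal_set, 34.2)
        assert c is cal_set.curves[1]

    def test_midpoint_parameters_are_arithmetic_means(self, cal_set):
        lo, hi = cal_set.curves[2], cal_set.curves[3]  # 35.7 and 37.0
        mid = interpolate_curve(cal_set, 0.5 * (35.7 + 37.0))
        assert mid.tau0_us == pytest.approx(0.5 * (lo.tau0_us + hi.tau0_us), rel=1e-12)
        assert mid.kq_per_us_mmHg == pytest.approx(
            0.5 * (lo.kq_per_us_mmHg + hi.kq_per_us_mmHg), rel=1e-12
        )

    def test_interpolant_monotone_between_nodes(self, cal_set):
        # the default sensor has monotone parameters across its four nodes
        ts = np.linspace(32.4, 37.0, 47)
        tau0s = [interpolate_curve(cal_set, t).tau0_us for t in ts]
        kqs = [interpolate_curve(cal_set, t).kq_per_us_mmHg for t in ts]
        assert np.all(np.diff(tau0s) <= 0)
        assert np.all(np.diff(kqs) >= 0)

    def test_slack_clamps_to_edge_curve(self, cal_set):
        assert interpolate_curve(cal_set, 37.4).tau0_us == cal_set.curves[-1].tau0_us
        assert interpolate_curve(cal_set, 32.0).tau0_us == cal_set.curves[0].tau0_us
        with pytest.raises(ValueError):
            interpolate_curve(cal_set, 37.6)


class TestMismatchBias:
    def test_wrong_curve_biases_po2_consistently_matched_curve_does_not(self, sensor, cal_set):
        """Converting 34.2 degC data with the 37 degC curve understates Po2 everywhere."""
        for po2_true in np.linspace(10.0, 120.0, 12):
            tau = sensor.tau(po2_true, 34.2)
            matched = po2_from_tau(cal_set, tau, 34.2)
            wrong = po2_from_tau(cal_set, tau, 37.0)
            assert abs(matched - po2_true) < 0.5
            assert wrong < po2_true  # single consistent direction (right shift)


class TestSplineAlternative:
    def test_spline_matches_linear_sensor_within_tolerance(self, sensor):
        po2s = np.linspace(0.0, 159.0, 12)
        pts = [
            CalibrationPoint(lifetime_us=float(sensor.tau(p, 37.0)), po2_mmHg=float(p), temperature_c=37.0)
            for p in po2s
        ]
        sp = SplineCalibrationCurve(pts)
        for p in (5.0, 42.0, 100.0, 150.0):
            assert sp.po2_from_tau(sp.tau_from_po2(p)) == pytest.approx(p, abs=1e-6)
        assert sp.po2_from_tau(sensor.tau(42.0, 37.0)) == pytest.approx(42.0, abs=0.5)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(8))
    def test_fit_matches_grid_search_across_seeds(self, seed):
        rng = np.random.default_rng(seed)
        po2s = np.array([0, 20, 40, 60, 80, 100, 130, 159], dtype=float)
        noise = 0.01 * rng.standard_normal(len(po2s))
        pts = _points(40.0, 1.0e-3, po2s, tau_noise=noise)
        c = fit_calibration_curve(pts, 37.0)
        tau0_o, kq_o = sv_grid_search(po2s, np.array([p.lifetime_us for p in pts]))
        assert c.tau0_us == pytest.approx(tau0_o, rel=5e-3)
        assert c.kq_per_us_mmHg == pytest.approx(kq_o, rel=5e-3)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    tau0=st.floats(25.0, 60.0),
    kq=st.floats(5e-4, 2e-3),
    po2=st.floats(0.0, 160.0),
)
def test_property_roundtrip_any_linear_curve(tau0, kq, po2):
    c = CalibrationCurve(temperature_c=37.0, tau0_us=tau0, kq_per_us_mmHg=kq)
    assert c.po2_from_tau(c.tau_from_po2(po2)) == pytest.approx(po2, abs=1e-6)
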