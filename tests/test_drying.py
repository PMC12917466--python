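"""Drying-curve analysis: RWD, vapour pressure, conductance, g_min, succulence."""

import numpy as np
import pytest

from camtraits.drying import (
    ConductanceSeries,
    Environment,
    M_WATER,
    ShrinkageModel,
    conductance_series,
    convert_conductance,
    detect_gmin_window,
    fit_shrinkage_model,
    gmin,
    mole_fraction_vpd,
    rwd_series,
    saturation_vapour_pressure,
    succulence,
)
from camtraits.errors import (
    DegenerateRecordError,
    InsufficientDataError,
    NoDrivingForceError,
    NoPlateauError,
    UnknownUnitError,
)
from camtraits.simulate import DryingSimConfig, simulate_drying_curve

from conftest import make_record


class TestRwd:
    def test_hand_arithmetic(self):
        # m_sat 1.25, wax 0.05, dry 0.20 → W_sat = 1.0; m_t 0.75 → W_t 0.5
        rec = make_record([0, 100], [1.25, 0.75], mass_dry=0.20, mass_wax=0.05)
        assert rwd_series(rec) == pytest.approx([0.0, 0.5])

    def test_saturation_and_proportion(self):
        rec = make_record([0, 100, 200], [1.25, 1.25, 0.55])
        rwd = rwd_series(rec)
        assert rwd[0] == 0.0
        assert rwd[1] == 0.0
        # W_t = 0.3 · W_sat → RWD 0.7
        assert rwd[2] == pytest.approx(0.7)

    def test_degenerate_record_signalled(self):
        with pytest.raises(DegenerateRecordError):
            make_record([0, 100], [0.24, 0.2], mass_dry=0.20, mass_wax=0.05)


class TestVapourPressure:
    @pytest.mark.parametrize(
        "t_c,expected",
        [(0.0, 0.61121), (25.0, 3.1685)],
    )
    def test_buck_values(self, t_c, expected):
        assert saturation_vapour_pressure(t_c) == pytest.approx(expected, rel=1e-3)

    def test_monotone_in_temperature(self):
        temps = np.linspace(-10, 50, 25)
        es = [saturation_vapour_pressure(t) for t in temps]
        assert np.all(np.diff(es) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            saturation_vapour_pressure(80.0)

    def test_vpd_zero_at_saturation(self):
        assert mole_fraction_vpd(Environment(relative_humidity=1.0)) == 0.0

    def test_vpd_reference_value(self):
        env = Environment(air_temperature=25.0, relative_humidity=0.5, pressure=101.325)
        assert mole_fraction_vpd(env) == pytest.approx(0.01564, rel=1e-3)

    def test_vpd_linear_in_dryness(self):
        e1 = mole_fraction_vpd(Environment(relative_humidity=0.5))
        e2 = mole_fraction_vpd(Environment(relative_humidity=0.75))
        assert e1 == pytest.approx(2 * e2)


class TestShrinkage:
    def test_exact_recovery_of_linear_loss(self):
        rwd = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
        areas = 2e-3 * (1 - 0.3 * rwd)
        model = fit_shrinkage_model(areas, rwd, "ref")
        assert model.slope == pytest.approx(0.3, abs=1e-6)

    def test_constant_area_gives_zero_loss(self):
        rwd = np.array([0.0, 0.3, 0.5, 0.9])
        model = fit_shrinkage_model(np.full(4, 1e-3), rwd, "ref")
        assert np.all(model.predict(rwd) == 0.0)

    def test_prediction_clamped(self):
        model = ShrinkageModel("ref", slope=0.6)
        assert model.predict(5.0) == 1.0
        assert model.predict(0.0) == 0.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_shrinkage_model([1e-3, 1e-3], [0.0, 0.5], "ref")
        with pytest.raises(InsufficientDataError):
            # no measurement near full hydration
            fit_shrinkage_model([1e-3] * 4, [0.2, 0.4, 0.6, 0.8], "ref")


class TestConductanceSeries:
    def test_hand_arithmetic(self):
        # Δmass 3.6 mg over 1000 s, A_corr = 2·1e-3 m², Δw from the bench
        # environment → E = Δm/Δt/(M_w·A), g = E/Δw
        env = Environment(air_temperature=25.0, relative_humidity=0.5)
        rec = make_record(
            [0, 1000], [1.25, 1.2464], area_saturated=1e-3, env=env
        )
        series = conductance_series(rec)
        dw = mole_fraction_vpd(env)
        e_expected = 3.6e-3 / 1000 / (M_WATER * 2e-3)
        assert series.transpiration[0] == pytest.approx(e_expected, rel=1e-12)
        assert series.conductance[0] == pytest.approx(e_expected / dw, rel=1e-12)
        assert e_expected == pytest.approx(1.0e-4, rel=1e-3)

    def test_zero_mass_change_zero_conductance(self):
        rec = make_record([0, 500, 1000], [1.25, 1.25, 1.25])
        series = conductance_series(rec)
        assert np.all(series.conductance == 0.0)

    def test_shrinkage_halved_area_doubles_conductance(self):
        rec = make_record([0, 1000], [1.25, 1.2], mass_dry=0.20, mass_wax=0.05)
        g_plain = conductance_series(rec).conductance[0]
        # loss 50% at the interval-midpoint RWD
        mid_rwd = conductance_series(rec).rwd[0]
        model = ShrinkageModel("ref", slope=0.5 / mid_rwd)
        g_corr = conductance_series(rec, model).conductance[0]
        assert g_corr == pytest.approx(2 * g_plain, rel=1e-9)

    def test_saturated_air_rejected(self):
        rec = make_record(
            [0, 1000], [1.25, 1.2], env=Environment(relative_humidity=1.0)
        )
        with pytest.raises(NoDrivingForceError):
            conductance_series(rec)


def _step_series(n=40, tlp=0.2, g_hi=5e-3, g_lo=5e-4):
    rwd = np.linspace(0.01, 0.9, n)
    g = np.where(rwd < tlp, g_hi, g_lo)
    return ConductanceSeries(
        leaf_id="L", taxon="t", rwd=rwd, transpiration=g * 0.015,
        conductance=g, corrected_area=np.full(n, 4e-3),
        time_mid=np.linspace(0, 1e4, n), environment=Environment(),
    )


class TestGminWindow:
    def test_step_breakpoint_located(self):
        series = _step_series()
        start, end, tlp = detect_gmin_window(series)
        assert tlp == pytest.approx(0.2, abs=0.05)
        assert np.all(series.rwd[start:end] > tlp)
        assert np.all(series.rwd[start:end] < 0.7)

    def test_flat_series_has_no_plateau(self):
        series = _step_series(g_hi=1e-3, g_lo=1e-3)
        with pytest.raises(NoPlateauError):
            detect_gmin_window(series)

    def test_rwd_max_excludes_tail(self):
        series = _step_series()
        start, end, _ = detect_gmin_window(series, rwd_max=0.5)
        assert np.all(series.rwd[start:end] < 0.5)

    def test_too_few_points(self):
        series = _step_series(n=8)
        with pytest.raises(InsufficientDataError):
            detect_gmin_window(series, rwd_max=0.1)

    def test_fixed_threshold_override(self):
        series = _step_series(g_hi=1e-3, g_lo=1e-3)
        start, end, tlp = detect_gmin_window(series, tlp_rwd_fixed=0.3)
        assert tlp == 0.3
        assert np.all((series.rwd[start:end] > 0.3) & (series.rwd[start:end] < 0.7))


class TestGminRoundTrip:
    @pytest.mark.parametrize("g_c", [0.07, 0.5, 1.0, 5.0])
    def test_noiseless_recovery_within_5_percent(self, g_c):
        rec = simulate_drying_curve(DryingSimConfig(g_c=g_c, seed=1))
        result = gmin(rec, ShrinkageModel("ref", slope=0.2))
        assert result.gmin_molar == pytest.approx(g_c, rel=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_recovery_within_15_percent(self, seed):
        rec = simulate_drying_curve(
            DryingSimConfig(g_c=1.0, mass_noise_sd=0.01, seed=seed)
        )
        result = gmin(rec, ShrinkageModel("ref", slope=0.2))
        assert result.gmin_molar == pytest.approx(1.0, rel=0.15)

    def test_unit_pair_consistency(self):
        rec = simulate_drying_curve(DryingSimConfig(g_c=1.0, seed=3))
        result = gmin(rec, ShrinkageModel("ref", slope=0.2))
        back = convert_conductance(
            result.gmin_velocity, "m s-1", "mmol m-2 s-1",
            temperature_c=rec.environment.air_temperature,
            pressure_kpa=rec.environment.pressure,
        )
        assert back == pytest.approx(result.gmin_molar, rel=1e-9)

    def test_time_rescaling(self):
        """Stretching the weighing schedule k-fold divides conductance by k."""
        rec = simulate_drying_curve(DryingSimConfig(g_c=1.0, seed=4))
        stretched = make_record(
            rec.times * 2.0, rec.masses,
            mass_dry=rec.mass_dry, mass_wax=rec.mass_wax,
            area_saturated=rec.area_saturated, env=rec.environment,
        )
        g1 = gmin(rec, ShrinkageModel("ref", slope=0.2))
        g2 = gmin(stretched, ShrinkageModel("ref", slope=0.2))
        assert g2.gmin_molar == pytest.approx(g1.gmin_molar / 2.0, rel=1e-9)
        assert g2.tlp_rwd == pytest.approx(g1.tlp_rwd)


class TestWaterConservation:
    def test_shrinkage_corrected_flux_reproduces_mass_loss(self):
        rec = simulate_drying_curve(DryingSimConfig(g_c=1.0, seed=5))
        series = conductance_series(rec, ShrinkageModel("ref", slope=0.2))
        dt = np.diff(rec.times)
        integrated = float(
            np.sum(series.transpiration * series.corrected_area * M_WATER * dt)
        )
        total_loss = float(rec.masses[0] - rec.masses[-1])
        assert integrated == pytest.approx(total_loss, rel=0.01)

    def test_rwd_monotone_for_noiseless_record(self):
        rec = simulate_drying_curve(DryingSimConfig(g_c=1.0, seed=6))
        assert np.all(np.diff(rwd_series(rec)) >= -1e-12)


class TestConvertConductance:
    def test_velocity_anchor(self):
        # 1.3 μm s⁻¹ at 25 °C / 101.325 kPa ↔ ~0.053 mmol m⁻² s⁻¹
        out = convert_conductance(1.3e-6, "m s-1", "mmol m-2 s-1", 25.0, 101.325)
        assert out == pytest.approx(0.0531, abs=5e-4)

    def test_round_trip_exact(self):
        v = 2.7e-6
        back = convert_conductance(
            convert_conductance(v, "m s-1", "mmol m-2 s-1"), "mmol m-2 s-1", "m s-1"
        )
        assert back == pytest.approx(v, rel=1e-12)

    def test_zero_maps_to_zero(self):
        assert convert_conductance(0.0, "m s-1", "mol m-2 s-1") == 0.0

    def test_unknown_unit(self):
        with pytest.raises(UnknownUnitError):
            convert_conductance(1.0, "cm s-1", "m s-1")


class TestSucculence:
    def test_ds_hand_arithmetic(self):
        # 1.00 g water over 2 · 5×10⁻⁴ m² → 1000 g m⁻²
        rec = make_record([0, 100], [1.25, 1.2], area_saturated=5e-4)
        assert succulence(rec).DS == pytest.approx(1000.0)

    def test_swc_ratio(self):
        rec = make_record([0, 100], [1.25, 1.2], mass_dry=0.20, mass_wax=0.05)
        assert succulence(rec).SWC == pytest.approx(5.0)

    def test_ds_inverse_in_area(self):
        rec1 = make_record([0, 100], [1.25, 1.2], area_saturated=1e-3)
        rec2 = make_record([0, 100], [1.25, 1.2], area_saturated=2e-3)
        assert succulence(rec1).DS == pytest.approx(2 * succulence(rec2).DS)

    def test_zero_dry_mass_swc_undefined(self):
        rec = make_record([0, 100], [1.25, 1.2], mass_dry=0.0)
        assert succulence(rec).SWC is None
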