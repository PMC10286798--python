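"""Pointwise physiology and ODE integration of the growth model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spectragrow as sg
from spectragrow.errors import ConfigError, ModelValidityWarning, OutOfRangeError
from spectragrow.growth import DEFAULT_PARAMETERS


class TestCo2Compensation:
    @pytest.mark.parametrize("t, expected", [(20.0, 40.0), (30.0, 80.0), (10.0, 20.0)])
    def test_q10_anchored_at_40ppm(self, t, expected):
        assert sg.co2_compensation(t) == pytest.approx(expected)

    @given(t=st.floats(min_value=-10.0, max_value=45.0))
    def test_q10_ratio_holds_everywhere(self, t):
        assert sg.co2_compensation(t + 10.0) / sg.co2_compensation(t) == pytest.approx(2.0)


class TestLightUseEfficiency:
    def test_reaches_quantum_efficiency_without_photorespiration(self):
        assert sg.light_use_efficiency(17.0e-6, 400.0, 0.0) == pytest.approx(17.0e-6)

    def test_ambient_co2_value(self):
        assert sg.light_use_efficiency(17.0e-6, 402.0, 40.0) == pytest.approx(
            1.2768e-5, rel=1e-4
        )

    def test_zero_at_compensation_point(self):
        assert sg.light_use_efficiency(17.0e-6, 40.0, 40.0) == 0.0

    def test_degenerate_denominator_raises(self):
        with pytest.raises(ValueError):
            sg.light_use_efficiency(17.0e-6, 0.0, 0.0)


class TestConductances:
    def test_carboxylation_at_25C(self):
        assert sg.carboxylation_conductance(25.0) == pytest.approx(3.96e-3, rel=1e-6)

    def test_parabola_symmetric_about_vertex(self):
        assert sg.carboxylation_conductance(20.0) == pytest.approx(
            sg.carboxylation_conductance(25.0)
        )

    @pytest.mark.parametrize("t", [5.0, 40.0, 0.0, 45.0])
    def test_outside_validity_range_raises(self, t):
        with pytest.raises(OutOfRangeError):
            sg.carboxylation_conductance(t)

    def test_series_combination(self):
        assert sg.canopy_conductance(0.007, 0.005, 3.96e-3) == pytest.approx(
            1.6796e-3, rel=1e-4
        )

    def test_equal_conductances(self):
        assert sg.canopy_conductance(0.3, 0.3, 0.3) == pytest.approx(0.1)

    def test_large_carboxylation_leaves_series_of_two(self):
        two = 1.0 / (1.0 / 0.007 + 1.0 / 0.005)
        assert sg.canopy_conductance(0.007, 0.005, 1e9) == pytest.approx(two, rel=1e-6)

    def test_total_below_smallest_component(self):
        g = sg.canopy_conductance(0.007, 0.005, 3.96e-3)
        assert g < min(0.007, 0.005, 3.96e-3)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            sg.canopy_conductance(0.0, 0.005, 0.004)


class TestPhotosynthesis:
    def test_dark_gives_zero(self):
        assert sg.max_gross_photosynthesis(1.2e-5, 0.0, 1.7e-3, 402.0, 40.0) == 0.0

    def test_light_saturation_limit(self):
        co2_limited = 1.6796e-3 * DEFAULT_PARAMETERS.c_omega * (402.0 - 40.0)
        f = sg.max_gross_photosynthesis(1.2768e-5, 1e9, 1.6796e-3, 402.0, 40.0)
        assert f == pytest.approx(co2_limited, rel=1e-4)

    def test_rectangular_hyperbola_value(self):
        f = sg.max_gross_photosynthesis(1.2768e-5, 32.8, 1.6796e-3, 402.0, 40.0)
        assert f == pytest.approx(3.0426e-4, rel=1e-3)

    def test_co2_below_compensation_suppresses(self):
        with pytest.warns(ModelValidityWarning):
            assert sg.max_gross_photosynthesis(1.2e-5, 30.0, 1.7e-3, 30.0, 40.0) == 0.0

    def test_canopy_closure(self):
        f_max = 3.0e-4
        assert sg.gross_photosynthesis(0.0, f_max) == 0.0
        assert sg.gross_photosynthesis(1e4, f_max) == pytest.approx(f_max)
        # exponent equals -1 at x_sdm = 1/(c_K c_lar (1-c_tau))
        x_unit = 1.0 / (0.9 * 0.075 * 0.85)
        assert x_unit == pytest.approx(17.43, rel=1e-3)
        assert sg.gross_photosynthesis(x_unit, f_max) == pytest.approx(
            (1.0 - np.exp(-1.0)) * f_max
        )

    def test_bounded_by_maximum(self):
        f_max = 3.0e-4
        for x in (0.1, 1.0, 10.0, 100.0):
            f = sg.gross_photosynthesis(x, f_max)
            assert 0.0 <= f <= f_max


class TestGrowthAndRespiration:
    def test_growth_rate_q10_ratio(self):
        r20 = sg.growth_rate(20.0, 1.0, 2.0)
        r30 = sg.growth_rate(30.0, 1.0, 2.0)
        assert r30 / r20 == pytest.approx(1.6)

    def test_growth_zero_without_reserves(self):
        assert sg.growth_rate(20.0, 0.0, 2.0) == 0.0

    def test_half_saturation(self):
        assert sg.growth_rate(20.0, 1.0, 1.0) == pytest.approx(2.5e-6)

    def test_respiration_q10_ratio(self):
        assert sg.maintenance_respiration(35.0, 1.0) / sg.maintenance_respiration(
            25.0, 1.0
        ) == pytest.approx(2.0)

    def test_respiration_reference_value(self):
        assert sg.maintenance_respiration(25.0, 1.0) == pytest.approx(3.1235e-7, rel=1e-4)

    def test_respiration_zero_without_structure(self):
        assert sg.maintenance_respiration(25.0, 0.0) == 0.0


class TestStateDerivatives:
    def test_zero_state_is_fixed_point(self):
        d = sg.state_derivatives(0.0, 0.0, 23.0, 410.0, 35.0, 1.3e-5)
        assert d == (0.0, 0.0)

    def test_structural_rate_identity(self):
        x_n, x_s = 0.4, 1.5
        _, d_s = sg.state_derivatives(x_n, x_s, 23.0, 410.0, 35.0, 1.3e-5)
        assert d_s == pytest.approx(sg.growth_rate(23.0, x_n, x_s) * x_s)

    def test_total_mass_budget(self):
        """d(total)/dt = c_alpha f_phot - f_resp - 0.25 r_gr x_sdm at c_beta=0.8."""
        x_n, x_s, t, co2, irr, ce = 0.4, 1.5, 23.0, 410.0, 35.0, 1.3e-5
        d_n, d_s = sg.state_derivatives(x_n, x_s, t, co2, irr, ce)
        gamma = sg.co2_compensation(t)
        eps = sg.light_use_efficiency(ce, co2, gamma)
        g = sg.canopy_conductance(0.007, 0.005, sg.carboxylation_conductance(t))
        f_max = sg.max_gross_photosynthesis(eps, irr, g, co2, gamma)
        f_phot = sg.gross_photosynthesis(x_s, f_max)
        f_resp = sg.maintenance_respiration(t, x_s)
        r = sg.growth_rate(t, x_n, x_s)
        assert d_n + d_s == pytest.approx(0.68 * f_phot - f_resp - 0.25 * r * x_s)


class TestEnvironmentSchedule:
    def test_gap_between_segments_rejected(self):
        with pytest.raises(ConfigError):
            sg.EnvironmentSchedule.from_segments(
                [
                    {"t_start_h": 0, "t_end_h": 10, "T_C": 20, "CO2_ppm": 400, "I_W_m2": 30},
                    {"t_start_h": 12, "t_end_h": 24, "T_C": 20, "CO2_ppm": 400, "I_W_m2": 0},
                ]
            )

    def test_values_at_and_truncation(self, day_night_env):
        assert day_night_env.values_at(0.0) == (22.0, 402.0, 33.0)
        assert day_night_env.values_at(21 * 3600.0) == (20.0, 402.0, 0.0)
        cut = day_night_env.truncated(30 * 3600.0)
        assert cut.duration == 30 * 3600.0
        assert cut.n_segments == 3

    def test_repeat_tiles_daily_pattern(self, day_night_env):
        week = day_night_env.repeated_to(7 * 86400.0)
        assert week.duration == 7 * 86400.0
        dark = week.edges[1:][week.irradiance_w_m2 == 0.0]
        assert len(dark) == 7  # one dark segment per day


class TestSimulate:
    def test_infinitesimal_horizon_returns_initial_state(self, constant_env, seedling):
        traj = sg.simulate(seedling, constant_env.truncated(1e-3), 1.3e-5)
        assert traj.t_s[0] == 0.0
        assert traj.x_nsdm[0] == seedling.x_nsdm
        assert traj.x_sdm[0] == seedling.x_sdm
        assert traj.total[-1] == pytest.approx(seedling.total, rel=1e-7)

    def test_dark_schedule_loses_mass(self, seedling):
        dark = sg.EnvironmentSchedule.from_segments(
            [{"t_start_h": 0, "t_end_h": 24, "T_C": 23.0, "CO2_ppm": 410.0, "I_W_m2": 0.0}]
        )
        traj = sg.simulate(seedling, dark, 1.3e-5)
        assert traj.total[-1] < seedling.total

    def test_growth_monotone_in_quantum_efficiency(self, constant_env, seedling):
        masses = [
            sg.simulate(seedling, constant_env, ce).total[-1]
            for ce in (0.8e-5, 1.2e-5, 1.6e-5)
        ]
        assert masses[0] < masses[1] < masses[2]

    def test_matches_fixed_step_rk4_oracle(self, seedling, params):
        """Adaptive integration agrees with a dt=1 s RK4 over 2 hours."""
        t, co2, irr, ce = 23.0, 410.0, 35.0, 1.3e-5
        horizon = 2 * 3600
        env = sg.EnvironmentSchedule.from_segments(
            [{"t_start_h": 0, "t_end_h": 2, "T_C": t, "CO2_ppm": co2, "I_W_m2": irr}]
        )
        traj = sg.simulate(seedling, env, ce, params)

        y = np.array([seedling.x_nsdm, seedling.x_sdm])

        def f(y):
            return np.array(sg.state_derivatives(y[0], y[1], t, co2, irr, ce, params))

        dt = 1.0
        for _ in range(horizon):
            k1 = f(y)
            k2 = f(y + 0.5 * dt * k1)
            k3 = f(y + 0.5 * dt * k2)
            k4 = f(y + dt * k3)
            y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert traj.x_nsdm[-1] == pytest.approx(y[0], rel=1e-6)
        assert traj.x_sdm[-1] == pytest.approx(y[1], rel=1e-6)

    def test_mass_balance_along_trajectory(self, constant_env, seedling, params):
        hours = np.arange(1, 120) * 3600.0
        traj = sg.simulate(seedling, constant_env, 1.3e-5, params, t_eval_s=hours)
        dtotal = np.array(
            [
                sum(
                    sg.state_derivatives(
                        n, s, *constant_env.values_at(t), 1.3e-5, params
                    )
                )
                for t, n, s in zip(traj.t_s, traj.x_nsdm, traj.x_sdm)
            ]
        )
        integral = np.trapezoid(dtotal, traj.t_s)
        change = traj.total[-1] - traj.total[0]
        assert integral == pytest.approx(change, rel=1e-3)

    def test_plant_density_scales_per_plant_only(self, constant_env, seedling, params):
        dense = params.with_(plant_density=2.0)
        t1 = sg.simulate(seedling, constant_env, 1.3e-5, params)
        t2 = sg.simulate(seedling, constant_env, 1.3e-5, dense)
        np.testing.assert_allclose(t1.total, t2.total, rtol=1e-12)
        np.testing.assert_allclose(t1.total_per_plant, 2.0 * t2.total_per_plant, rtol=1e-12)

    def test_trajectory_frame_columns(self, constant_env, seedling):
        frame = sg.simulate(seedling, constant_env, 1.3e-5).to_frame()
        assert list(frame.columns) == [
            "time_h", "x_nsdm_g_m2", "x_sdm_g_m2", "total_g_m2", "total_g_per_plant",
        ]
        assert frame["time_h"].is_monotonic_increasing
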