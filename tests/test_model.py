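"""Core glucoregulatory model: closed-form steady states, conservation
laws, integrator accuracy and mode consistency."""

import numpy as np
import pytest

from t1dvpp.model import (
    ModeError,
    ParameterBatch,
    glucagon_dynamics_deriv,
    glucagon_kinetics_deriv,
    glucose_kinetics_deriv,
    insulin_dynamics_deriv,
    insulin_kinetics_deriv,
    integrate,
    meal_absorption_rate,
    plasma_glucose_mgdl,
    simulate_constant_batch,
    steady_state_glucose_batch,
    steady_state_y0,
)
from t1dvpp.parameters import MealEvent, ModelParameters, ModelState


class TestSubsystemDerivatives:
    def test_null_input_is_fixed_point(self, nominal_dh):
        s = ModelState()
        assert insulin_kinetics_deriv(s, 0.0, nominal_dh) == (0.0, 0.0, 0.0)
        assert insulin_dynamics_deriv(s, nominal_dh) == (0.0, 0.0, 0.0)
        assert glucagon_kinetics_deriv(s, 0.0, nominal_dh) == (0.0, 0.0, 0.0)
        assert glucagon_dynamics_deriv(s, nominal_dh) == (0.0, 0.0)

    def test_negative_infusions_rejected(self, nominal_dh):
        with pytest.raises(ValueError):
            insulin_kinetics_deriv(ModelState(), -0.1, nominal_dh)
        with pytest.raises(ValueError):
            glucagon_kinetics_deriv(ModelState(), -0.1, nominal_dh)

    def test_glucagon_ops_require_dh_mode(self, nominal_sh):
        with pytest.raises(ModeError):
            glucagon_kinetics_deriv(ModelState(), 0.0, nominal_sh)
        with pytest.raises(ModeError):
            glucagon_dynamics_deriv(ModelState(), nominal_sh)

    def test_glucagon_action_gain(self, nominal_dh):
        # k_g = 1e6 * k_c * S_fGG / V_dGG with the default parameters
        assert nominal_dh.k_g == pytest.approx(1e6 * 0.06 * 0.017 / 0.19)
        assert nominal_dh.k_g == pytest.approx(5368.42, rel=1e-4)

    def test_zero_insulin_glucose_balance(self, nominal_sh):
        # with no insulin action and no meal, Q1' reduces to the
        # production/uptake/transfer balance
        s = ModelState(Q_1=6.3834 * 0.16, Q_2=0.1)
        dq1, dq2 = glucose_kinetics_deriv(s, 0.0, nominal_sh)
        expected = nominal_sh.EGP_0 - nominal_sh.F01 + nominal_sh.k_12 * 0.1
        assert dq1 == pytest.approx(expected)
        assert dq2 == pytest.approx(-nominal_sh.k_12 * 0.1)


class TestLinearSteadyStates:
    """48-h constant-input simulations land on the closed forms (<0.1%)."""

    def test_plasma_insulin(self, nominal_batch):
        u = 0.2  # mU/kg/min
        y = simulate_constant_batch(nominal_batch, u, t_end=2880.0)
        i_ss = u / (0.12 * 0.138)
        assert i_ss == pytest.approx(12.0773, rel=1e-3)
        assert y[0, 2] == pytest.approx(i_ss, rel=1e-3)

    def test_insulin_action(self, nominal_sh, nominal_batch):
        u = 0.2
        y = simulate_constant_batch(nominal_batch, u, t_end=2880.0)
        i_ss = u / (nominal_sh.V_I * nominal_sh.k_e)
        for idx, sf in zip((3, 4, 5), nominal_sh.sf_nominal()):
            assert y[0, idx] == pytest.approx(sf * i_ss, rel=1e-3)

    def test_plasma_glucagon(self, nominal_dh):
        pb = ParameterBatch.from_params([nominal_dh])
        u_g = 1e-4  # mg/kg/min
        y = simulate_constant_batch(pb, 0.0, u_g, t_end=2880.0)
        x3g_ss = u_g * nominal_dh.k_1g / (
            (nominal_dh.k_1g + nominal_dh.k_ge1) * nominal_dh.k_ge2
        )
        assert x3g_ss == pytest.approx(2.175 * u_g, rel=1e-3)
        assert y[0, 10] == pytest.approx(x3g_ss, rel=1e-3)


def test_z_equals_dy_dt_along_trajectory(nominal_dh):
    """The state-space glucagon action keeps Z == dY/dt numerically."""
    state0 = ModelState()
    times, traj = integrate(
        state0, nominal_dh, t_end=240.0, dt=1.0, u_g=2e-4, u_I=0.0
    )
    y = traj[:, 11]
    z = traj[:, 12]
    dy_dt = np.gradient(y, times)
    # central differences are O(dt^2); compare away from the endpoints
    assert np.allclose(z[2:-2], dy_dt[2:-2], rtol=5e-3, atol=1e-4)


class TestMealAbsorption:
    def test_no_meals_is_zero(self, nominal_sh):
        assert meal_absorption_rate(123.0, [], nominal_sh) == 0.0

    def test_peak_at_t_maxg(self, nominal_sh):
        meal = [MealEvent(time=10.0, carbs_true=60.0)]
        t = np.linspace(10.0, 400.0, 7801)
        ug = meal_absorption_rate(t, meal, nominal_sh)
        assert t[np.argmax(ug)] - 10.0 == pytest.approx(nominal_sh.t_maxG, abs=0.1)

    def test_carbohydrate_conservation(self, nominal_sh):
        """Integrated absorption equals the bioavailable dose A_G * D_G."""
        meal = [MealEvent(time=0.0, carbs_true=60.0)]
        t = np.arange(0.0, 1441.0)
        ug = meal_absorption_rate(t, meal, nominal_sh)
        total = np.trapezoid(ug, t)
        d_g = 60.0 / (0.18016 * nominal_sh.weight)
        assert total == pytest.approx(nominal_sh.A_G * d_g, rel=5e-3)

    def test_superposition(self, nominal_sh):
        m1 = [MealEvent(time=0.0, carbs_true=40.0)]
        m2 = [MealEvent(time=90.0, carbs_true=70.0)]
        t = np.arange(0.0, 600.0)
        both = meal_absorption_rate(t, m1 + m2, nominal_sh)
        assert np.allclose(
            both,
            meal_absorption_rate(t, m1, nominal_sh) + meal_absorption_rate(t, m2, nominal_sh),
        )


def test_plasma_glucose_conversion(nominal_sh):
    assert plasma_glucose_mgdl(ModelState(), nominal_sh) == 0.0
    s = ModelState(Q_1=6.3834 * nominal_sh.V_G)
    assert plasma_glucose_mgdl(s, nominal_sh) == pytest.approx(115.0, abs=0.01)


class TestIntegrator:
    def test_zero_inputs_only_glucose_evolves(self, nominal_sh):
        """With zero inputs the hormone subsystems stay at zero while
        endogenous production makes glucose rise from an empty pool."""
        _, traj = integrate(ModelState(), nominal_sh, t_end=60.0)
        hormone_cols = [0, 1, 2, 3, 4, 5, 8, 9, 10, 11, 12]
        assert np.all(traj[:, hormone_cols] == 0.0)
        assert np.all(np.diff(traj[:, 6]) > 0)  # EGP fills the glucose pool

    def test_step_refinement(self, nominal_sh, nominal_basal):
        """dt = 1 min agrees with dt = 0.1 min within 0.5 mg/dl over 24 h."""
        pb = ParameterBatch.from_params([nominal_sh])
        y0 = ModelState.from_array(steady_state_y0(pb, nominal_basal)[0])
        meals = [MealEvent(time=120.0, carbs_true=60.0)]
        kw = dict(u_I=nominal_basal, meals=meals)
        _, coarse = integrate(y0, nominal_sh, t_end=1440.0, dt=1.0, **kw)
        _, fine = integrate(y0, nominal_sh, t_end=1440.0, dt=0.1, **kw)
        g_coarse = plasma_glucose_mgdl(coarse, nominal_sh)
        g_fine = plasma_glucose_mgdl(fine[::10], nominal_sh)
        assert np.max(np.abs(g_coarse - g_fine)) < 0.5

    def test_invalid_step_rejected(self, nominal_sh):
        with pytest.raises(ValueError):
            integrate(ModelState(), nominal_sh, t_end=10.0, dt=-1.0)
        with pytest.raises(ValueError):
            integrate(ModelState(), nominal_sh, t_end=10.0, dt=3.0)


def test_sh_dh_equivalence_without_glucagon(nominal_sh, nominal_dh, nominal_basal):
    """With zero glucagon input and states, DH reproduces SH exactly."""
    pb = ParameterBatch.from_params([nominal_sh])
    y0 = ModelState.from_array(steady_state_y0(pb, nominal_basal)[0])
    meals = [MealEvent(time=60.0, carbs_true=50.0)]
    _, sh = integrate(y0, nominal_sh, t_end=720.0, u_I=nominal_basal, meals=meals)
    _, dh = integrate(y0, nominal_dh, t_end=720.0, u_I=nominal_basal, u_g=0.0, meals=meals)
    assert np.array_equal(sh, dh)


class TestMonotonicity:
    def test_higher_sensitivity_lowers_steady_glucose(self, nominal_sh):
        scales = [0.7, 1.0, 1.4]
        params = [
            nominal_sh.replace(
                S_f1=nominal_sh.S_f1 * s, S_f2=nominal_sh.S_f2 * s, S_f3=nominal_sh.S_f3 * s
            )
            for s in scales
        ]
        pb = ParameterBatch.from_params(params)
        g = steady_state_glucose_batch(pb, 0.25)
        assert g[0] > g[1] > g[2]

    def test_higher_basal_lowers_steady_glucose(self, nominal_batch):
        g = np.array(
            [steady_state_glucose_batch(nominal_batch, u)[0] for u in (0.1, 0.2, 0.3)]
        )
        assert g[0] > g[1] > g[2]


def test_egp_floor_prevents_negative_production(nominal_sh):
    """At very high insulin action the EGP term clamps at zero: glucose
    production never turns into an unphysical sink."""
    s = ModelState(X_3=5.0, Q_1=0.5)
    dq1_floored, _ = glucose_kinetics_deriv(s, 0.0, nominal_sh)
    raw = nominal_sh.replace(floor_egp=False)
    dq1_raw, _ = glucose_kinetics_deriv(s, 0.0, raw)
    assert dq1_floored > dq1_raw
    assert dq1_raw < dq1_floored - nominal_sh.EGP_0 * 3.9  # raw term ~ -4*EGP_0


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters(k_e=-0.1)
    with pytest.raises(ValueError):
        ModelParameters(A_G=1.5)
    with pytest.raises(ValueError):
        ModelParameters(mode="XX")


def test_state_count_by_mode(nominal_sh, nominal_dh):
    """SH carries 8 differential states, DH 13."""
    assert nominal_sh.n_states == 8
    assert nominal_dh.n_states == 13
    assert ModelState().as_array("SH").shape == (8,)
    assert ModelState().as_array("DH").shape == (13,)
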