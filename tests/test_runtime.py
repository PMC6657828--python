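"""Closed-loop runtime: perturbation models, rescue policy, controller
contract and reproducibility."""

import math

import numpy as np
import pytest

from t1dvpp.parameters import MealEvent
from t1dvpp.population import SamplingSpec, sample_patient
from t1dvpp.runtime import (
    CGMNoiseSpec,
    ConstantBasalController,
    ControllerCommand,
    ControllerError,
    ControllerObservation,
    PatientPublicInfo,
    ReferenceController,
    RescuePolicy,
    Scenario,
    apply_meal_uncertainty,
    cgm_noise,
    circadian_sensitivity,
    generate_cgm_noise,
    rescue_policy,
    run_closed_loop,
)
from t1dvpp.scenarios import generate_synthetic_scenario


@pytest.fixture(scope="module")
def patient():
    return sample_patient(
        SamplingSpec(sf_sd=(0, 0, 0), weight_sd=0.0), "SH", np.random.default_rng(0)
    )


@pytest.fixture(scope="module")
def dh_patient():
    return sample_patient(
        SamplingSpec(sf_sd=(0, 0, 0), weight_sd=0.0, egp0_sd=0.0, sfgg_sd=0.0,
                     kc_sd=0.0, kg3_sd=0.0),
        "DH", np.random.default_rng(0),
    )


class TestCircadian:
    def test_zero_amplitude_is_identity(self):
        sf = (21e-4, 3.5e-4, 214e-4)
        for t in (0.0, 333.0, 1440.0):
            assert circadian_sensitivity(t, sf, amplitude=0.0, phase=1.2) == sf

    def test_daily_mean_equals_nominal(self):
        """The 24-h sinusoid averages out over exactly one day."""
        sf = (21e-4, 3.5e-4, 214e-4)
        t = np.arange(0.0, 1440.0, 5.0)
        vals = np.array([circadian_sensitivity(tt, sf, 0.3, phase=0.77)[0] for tt in t])
        assert vals.mean() == pytest.approx(sf[0], rel=1e-12)
        assert vals.max() == pytest.approx(sf[0] * 1.3, rel=1e-3)
        assert vals.min() == pytest.approx(sf[0] * 0.7, rel=1e-3)

    def test_period_is_24h_wall_clock(self):
        sf = (1.0, 1.0, 1.0)
        a = circadian_sensitivity(100.0, sf, 0.3, phase=0.5)
        b = circadian_sensitivity(100.0 + 1440.0, sf, 0.3, phase=0.5)
        assert a == pytest.approx(b)


class TestMealUncertainty:
    def test_zero_bound_is_identity(self, rng):
        meal = MealEvent(time=10.0, carbs_true=60.0)
        out = apply_meal_uncertainty(meal, 0.0, rng)
        assert out.carbs_true == 60.0

    def test_bound_respected_and_announcement_kept(self, rng):
        meal = MealEvent(time=10.0, carbs_true=60.0)
        for _ in range(200):
            out = apply_meal_uncertainty(meal, 30.0, rng)
            assert out.carbs_announced == 60.0
            assert 42.0 <= out.carbs_true <= 78.0

    def test_full_positive_draw_scales_by_1p3(self):
        class FullDraw:
            def uniform(self, lo, hi):
                return hi
        out = apply_meal_uncertainty(MealEvent(time=0, carbs_true=60.0), 30.0, FullDraw())
        assert out.carbs_true == pytest.approx(78.0)


class TestRescuePolicy:
    policy = RescuePolicy()

    def test_no_rescue_above_threshold(self):
        assert rescue_policy([100, 90, 80, 71], self.policy) is None

    def test_rescue_scheduled_10_min_after_crossing(self):
        history = [100.0] * 20 + [65.0]  # crossing at sample 20 -> t = 100
        rescue = rescue_policy(history, self.policy)
        assert rescue is not None
        assert rescue.time == 110.0
        assert rescue.carbs_true == 15.0
        assert not rescue.announced

    def test_refractory_suppresses_stacking(self):
        history = [100.0] * 20 + [65.0, 64.0]
        first = rescue_policy(history[:21], self.policy)
        second = rescue_policy(history, self.policy, last_rescue_time=first.time)
        assert second is None

    def test_disabled_policy(self):
        assert rescue_policy([50.0], RescuePolicy(enabled=False)) is None


class TestCGMNoise:
    def test_zero_variance_is_transparent(self, rng):
        g = np.full(100, 120.0)
        out = cgm_noise(g, CGMNoiseSpec(sd=0.0), rng)
        assert np.array_equal(out, g)

    def test_ar1_autocorrelation(self):
        """Lag-1 autocorrelation of the noise matches the AR coefficient."""
        spec = CGMNoiseSpec(ar_coeff=0.7, sd=7.0)
        e = generate_cgm_noise(10_000, spec, np.random.default_rng(99))
        rho = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert rho == pytest.approx(0.7, abs=0.05)
        assert e.std() == pytest.approx(7.0, rel=0.1)

    def test_unstable_coefficient_rejected(self):
        with pytest.raises(ValueError):
            CGMNoiseSpec(ar_coeff=1.2)


class TestReferenceController:
    def _obs(self, t=0.0, cgm=(115.0,), meals=(), tdir=45.0):
        return ControllerObservation(
            time=t,
            cgm_history=list(cgm),
            announced_meals=list(meals),
            patient=PatientPublicInfo(weight=76.3, tdir=tdir, basal_rate=1.0, mode="SH"),
        )

    def test_pure_basal_at_target(self):
        cmd = ReferenceController()(self._obs())
        assert cmd.insulin_basal == 1.0
        assert cmd.insulin_bolus == 0.0
        assert cmd.glucagon_rate == 0.0

    def test_450_rule_meal_bolus(self):
        """60 g announced at TDIR 45 U/day -> 60/(450/45) = 6 U."""
        cmd = ReferenceController(correction=False)(
            self._obs(t=5.0, meals=[(5.0, 60.0)], tdir=45.0)
        )
        assert cmd.insulin_bolus == pytest.approx(6.0)

    def test_meal_bolused_once(self):
        ctrl = ReferenceController(correction=False)
        ctrl(self._obs(t=5.0, meals=[(5.0, 60.0)]))
        cmd = ctrl(self._obs(t=10.0, meals=[(5.0, 60.0)]))
        assert cmd.insulin_bolus == 0.0

    def test_negative_command_rejected(self):
        with pytest.raises(ValueError):
            ControllerCommand(insulin_basal=-1.0)


class TestClosedLoop:
    def test_constant_basal_holds_steady_state(self, patient):
        """At titrated basal with no meals, glucose stays within 2 mg/dl
        of the 115 mg/dl target for 24 h."""
        scen = Scenario(duration=1440.0).deterministic()
        res = run_closed_loop(patient, scen, ConstantBasalController(patient.basal_rate))
        assert np.all(np.abs(res.glucose_true - 115.0) < 2.0)

    def test_reproducibility(self, patient):
        scen = generate_synthetic_scenario(1.0, rng=3)
        a = run_closed_loop(patient, scen, ReferenceController())
        b = run_closed_loop(patient, scen, ReferenceController())
        assert np.array_equal(a.glucose_true, b.glucose_true)
        assert np.array_equal(a.glucose_cgm, b.glucose_cgm)
        assert a.rescues == b.rescues

    def test_perturbation_isolation(self, patient):
        """Disabling every perturbation reproduces the deterministic core
        regardless of the seed."""
        scen = generate_synthetic_scenario(1.0, rng=3).deterministic()
        a = run_closed_loop(patient, scen, ReferenceController())
        import dataclasses
        b = run_closed_loop(
            patient, dataclasses.replace(scen, seed=999), ReferenceController()
        )
        assert np.array_equal(a.glucose_true, b.glucose_true)
        assert np.array_equal(a.glucose_true, a.glucose_cgm)

    def test_controller_never_sees_true_carbs(self, patient):
        """The realized (uncertain) intake differs from what the
        controller is shown."""
        seen: list[tuple[float, float]] = []

        class Spy(ReferenceController):
            def __call__(self, obs):
                seen.extend(obs.announced_meals)
                return super().__call__(obs)

        scen = generate_synthetic_scenario(1.0, rng=8)
        res = run_closed_loop(patient, scen, Spy())
        announced = {t: g for t, g in seen}
        true_by_time = {m.time: m.carbs_true for m in res.meals if m.announced}
        assert set(announced) == set(true_by_time)
        assert any(abs(announced[t] - true_by_time[t]) > 1e-9 for t in announced)
        # rescue meals are never announced
        for m in res.meals:
            if not m.announced:
                assert m.carbs_announced == 0.0

    def test_exercise_increases_hypoglycemic_pressure(self, patient):
        """Adding the post-lunch bout never decreases time below 70 mg/dl."""
        scen = generate_synthetic_scenario(1.0, rng=4).deterministic()
        assert scen.exercise
        import dataclasses
        no_ex = dataclasses.replace(scen, exercise=[])
        with_ex = run_closed_loop(patient, scen, ReferenceController())
        without = run_closed_loop(patient, no_ex, ReferenceController())
        below_with = np.count_nonzero(with_ex.glucose_true < 70.0)
        below_without = np.count_nonzero(without.glucose_true < 70.0)
        assert below_with >= below_without
        # and the bout visibly lowers glucose somewhere
        assert with_ex.glucose_true.min() < without.glucose_true.min()

    def test_dh_patient_runs_and_doses_glucagon_when_low(self, dh_patient):
        scen = generate_synthetic_scenario(1.0, rng=4)
        res = run_closed_loop(dh_patient, scen, ReferenceController())
        assert np.all(res.glucose_true > 20.0) and np.all(res.glucose_true < 450.0)
        if res.glucose_cgm.min() < 80.0:
            assert res.glucagon_rate.sum() > 0.0

    def test_controller_exception_carries_partial_trace(self, patient):
        class Broken:
            def __call__(self, obs):
                if obs.time >= 50.0:
                    raise RuntimeError("boom")
                return ControllerCommand(insulin_basal=1.0)

        scen = Scenario(duration=300.0).deterministic()
        with pytest.raises(ControllerError) as err:
            run_closed_loop(patient, scen, Broken())
        assert err.value.partial is not None
        assert len(err.value.partial.times) == 11  # samples up to t=50
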