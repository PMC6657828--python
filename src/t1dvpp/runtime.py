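"""Closed-loop scenario execution.

The runtime advances a virtual patient through a scenario of meals and
exercise bouts while a pluggable controller, sampled every ``Ts`` = 5
minutes from a (possibly noisy) CGM signal, commands insulin basal
rates, meal boluses and (in DH mode) glucagon.  Real-world perturbations
are layered on top of the deterministic core and can each be disabled:

* meal uncertainty — the gut absorbs ``announced * (1 + U(-b, b))``
  grams while the controller only ever sees the announced amount;
* circadian insulin-sensitivity modulation — a 24-h sinusoid of
  amplitude 0.3 with a phase drawn once per run and shared by all
  patients;
* rescue carbohydrates — an unannounced meal 10 minutes after glucose
  first drops below 70 mg/dl, with a refractory period;
* CGM noise — additive first-order autoregressive noise on the 5-min
  sampling grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .exercise import ExerciseBout, ExerciseProfile
from .model import integrate, plasma_glucose_mgdl
from .parameters import (
    MGDL_PER_MMOLL,
    MealEvent,
    ModelState,
    glucagon_mcgkghr_to_mgkgmin,
    insulin_uhr_to_mukgmin,
)
from .population import VirtualPatient

TS_MIN = 5.0  # controller/CGM sampling interval, minutes

__all__ = [
    "Scenario",
    "RescuePolicy",
    "CircadianSpec",
    "CGMNoiseSpec",
    "ControllerCommand",
    "ControllerObservation",
    "SimulationResult",
    "circadian_sensitivity",
    "apply_meal_uncertainty",
    "rescue_policy",
    "generate_cgm_noise",
    "cgm_noise",
    "run_closed_loop",
    "ReferenceController",
    "ConstantBasalController",
]


# ---------------------------------------------------------------------------
# scenario description
# ---------------------------------------------------------------------------

@dataclass
class RescuePolicy:
    """Unannounced rescue-carb rule: ``grams`` given ``delay`` minutes
    after glucose drops below ``threshold``, at most once per
    ``refractory`` minutes."""

    enabled: bool = True
    threshold: float = 70.0    # mg/dl
    delay: float = 10.0        # min
    grams: float = 15.0
    refractory: float = 30.0   # min


@dataclass
class CircadianSpec:
    """24-h sinusoidal modulation of the insulin sensitivities."""

    amplitude: float = 0.3
    period: float = 1440.0     # min
    phase: float | None = None  # radians; drawn from the run seed if None

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude < 1:
            raise ValueError("circadian amplitude must lie in [0, 1)")


@dataclass
class CGMNoiseSpec:
    """First-order autoregressive sensor noise on the Ts grid.

    ``e_k = ar_coeff * e_{k-1} + w_k`` with stationary SD ``sd`` mg/dl.
    The exact published sensor-error coefficients are not reproduced
    here; the AR(1) default is a configurable stand-in with the same
    coloured-noise character.
    """

    enabled: bool = True
    ar_coeff: float = 0.7
    sd: float = 7.0

    def __post_init__(self) -> None:
        if not abs(self.ar_coeff) < 1:
            raise ValueError("AR(1) coefficient must be inside the unit circle")
        if self.sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class Scenario:
    """Timestamped inputs and perturbation settings for one simulation."""

    duration: float                       # minutes
    meals: list[MealEvent] = field(default_factory=list)
    exercise: list[ExerciseBout] = field(default_factory=list)
    meal_uncertainty_pct: float = 30.0    # +/- bound on true vs announced carbs
    rescue: RescuePolicy = field(default_factory=RescuePolicy)
    circadian: CircadianSpec = field(default_factory=CircadianSpec)
    cgm_noise: CGMNoiseSpec = field(default_factory=CGMNoiseSpec)
    seed: int = 0
    start_time_of_day: float = 480.0      # minutes after midnight (08:00)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("scenario duration must be positive")
        for m in self.meals:
            if not 0 <= m.time <= self.duration:
                raise ValueError(f"meal at t={m.time} outside [0, {self.duration}]")
        for b in self.exercise:
            if not 0 <= b.start <= self.duration:
                raise ValueError(f"exercise bout at t={b.start} outside scenario")
        if not 0 <= self.meal_uncertainty_pct < 100:
            raise ValueError("meal uncertainty bound must lie in [0, 100)")

    def deterministic(self) -> "Scenario":
        """Copy with every stochastic perturbation disabled."""
        return replace(
            self,
            meal_uncertainty_pct=0.0,
            rescue=replace(self.rescue, enabled=False),
            circadian=replace(self.circadian, amplitude=0.0, phase=0.0),
            cgm_noise=replace(self.cgm_noise, enabled=False),
        )


# ---------------------------------------------------------------------------
# controller contract
# ---------------------------------------------------------------------------

@dataclass
class ControllerCommand:
    """Doses commanded for the next sampling interval."""

    insulin_basal: float = 0.0   # U/hr
    insulin_bolus: float = 0.0   # U, delivered at the start of the interval
    glucagon_rate: float = 0.0   # mcg/kg/hr; ignored in SH mode

    def __post_init__(self) -> None:
        if min(self.insulin_basal, self.insulin_bolus, self.glucagon_rate) < 0:
            raise ValueError("controller commands must be non-negative")


@dataclass
class PatientPublicInfo:
    """What a controller may know about its patient: no true parameters."""

    weight: float
    tdir: float
    basal_rate: float
    mode: str


@dataclass
class ControllerObservation:
    """Inputs available to a controller at one sampling instant."""

    time: float                                  # minutes from scenario start
    cgm_history: Sequence[float]                 # mg/dl, up to and incl. now
    announced_meals: Sequence[tuple[float, float]]  # (time, grams), announced only
    patient: PatientPublicInfo


class Controller(Protocol):
    def __call__(self, obs: ControllerObservation) -> ControllerCommand: ...


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def circadian_sensitivity(
    t: float,
    sf_nominal: tuple[float, float, float],
    amplitude: float = 0.3,
    phase: float = 0.0,
    period: float = 1440.0,
) -> tuple[float, float, float]:
    """Insulin sensitivities at wall-clock minute ``t``.

    ``S_fi(t) = S_fi* (1 + amplitude sin(2 pi t / period + phase))`` —
    a 24-h sinusoid whose mean over a full day is the nominal value.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    m = 1.0 + amplitude * math.sin(2.0 * math.pi * t / period + phase)
    return (sf_nominal[0] * m, sf_nominal[1] * m, sf_nominal[2] * m)


def apply_meal_uncertainty(
    meal: MealEvent, bound_pct: float = 30.0, rng: np.random.Generator | None = None
) -> MealEvent:
    """Perturb the absorbed carbs by a uniform relative error.

    The gut receives ``announced * (1 + U(-bound, bound))`` grams; the
    announcement the controller sees is unchanged.
    """
    if not 0 <= bound_pct < 100:
        raise ValueError("bound must lie in [0, 100)")
    rng = rng or np.random.default_rng()
    frac = rng.uniform(-bound_pct / 100.0, bound_pct / 100.0)
    return MealEvent(
        time=meal.time,
        carbs_true=meal.carbs_announced * (1.0 + frac),
        carbs_announced=meal.carbs_announced,
        announced=meal.announced,
    )


def rescue_policy(
    glucose_history: Sequence[float],
    policy: RescuePolicy,
    ts: float = TS_MIN,
    last_rescue_time: float | None = None,
) -> MealEvent | None:
    """Rescue decision from a glucose series sampled every ``ts`` minutes.

    If the latest sample has crossed below the threshold and no rescue
    fell within the refractory window, returns the unannounced rescue
    meal scheduled ``delay`` minutes after the crossing.
    """
    if not policy.enabled or len(glucose_history) == 0:
        return None
    t_now = (len(glucose_history) - 1) * ts
    if glucose_history[-1] >= policy.threshold:
        return None
    if last_rescue_time is not None and t_now + policy.delay - last_rescue_time < policy.refractory:
        return None
    return MealEvent(
        time=t_now + policy.delay,
        carbs_true=policy.grams,
        carbs_announced=0.0,
        announced=False,
    )


def generate_cgm_noise(
    n: int, spec: CGMNoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise series of length ``n`` (mg/dl)."""
    if not spec.enabled or spec.sd == 0:
        return np.zeros(n)
    phi, sd = spec.ar_coeff, spec.sd
    w_sd = sd * math.sqrt(1.0 - phi * phi)
    e = np.empty(n)
    prev = rng.normal(0.0, sd)
    for k in range(n):
        prev = phi * prev + rng.normal(0.0, w_sd)
        e[k] = prev
    return e


def cgm_noise(
    true_glucose: Sequence[float], spec: CGMNoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Noisy CGM series from a true glucose series on the Ts grid."""
    g = np.asarray(true_glucose, dtype=float)
    return g + generate_cgm_noise(len(g), spec, rng)


# ---------------------------------------------------------------------------
# controllers
# ---------------------------------------------------------------------------

@dataclass
class ConstantBasalController:
    """Open-loop controller delivering a fixed basal rate (U/hr)."""

    basal_uhr: float

    def __call__(self, obs: ControllerObservation) -> ControllerCommand:
        return ControllerCommand(insulin_basal=self.basal_uhr)


class ReferenceController:
    """Simple basal-bolus reference controller.

    This is a deliberately plain stand-in for the clinical control
    algorithm (which is external to this package): constant basal at the
    patient's daily basal requirement, a carbohydrate bolus from the
    450-rule ratio (CR = 450/TDIR g per U) at meal announcement, an
    optional proportional correction above 180 mg/dl using the 1700-rule
    factor, and in DH mode a small fixed glucagon pulse when the CGM is
    below 80 mg/dl and falling.  It sees only announced carbs and the
    public patient info (weight, TDIR, basal rate), never the true
    model parameters or true intakes.
    """

    def __init__(
        self,
        correction: bool = True,
        correction_threshold: float = 180.0,
        correction_interval: float = 60.0,
        glucagon_threshold: float = 80.0,
        glucagon_pulse_mcgkghr: float = 5.0,
        glucagon_refractory: float = 30.0,
    ):
        self.correction = correction
        self.correction_threshold = correction_threshold
        self.correction_interval = correction_interval
        self.glucagon_threshold = glucagon_threshold
        self.glucagon_pulse = glucagon_pulse_mcgkghr
        self.glucagon_refractory = glucagon_refractory
        self._bolused: set[float] = set()
        self._last_correction = -math.inf
        self._last_glucagon = -math.inf

    def __call__(self, obs: ControllerObservation) -> ControllerCommand:
        tdir = obs.patient.tdir
        bolus = 0.0
        for t_meal, grams in obs.announced_meals:
            if t_meal <= obs.time and t_meal not in self._bolused:
                bolus += grams / (450.0 / tdir)
                self._bolused.add(t_meal)
        cgm = obs.cgm_history[-1]
        if (
            self.correction
            and cgm > self.correction_threshold
            and obs.time - self._last_correction >= self.correction_interval
        ):
            bolus += (cgm - self.correction_threshold) / (1700.0 / tdir)
            self._last_correction = obs.time
        glucagon = 0.0
        if obs.patient.mode == "DH" and len(obs.cgm_history) >= 2:
            falling = obs.cgm_history[-1] < obs.cgm_history[-2]
            if (
                cgm < self.glucagon_threshold
                and falling
                and obs.time - self._last_glucagon >= self.glucagon_refractory
            ):
                glucagon = self.glucagon_pulse
                self._last_glucagon = obs.time
        return ControllerCommand(
            insulin_basal=obs.patient.basal_rate,
            insulin_bolus=bolus,
            glucagon_rate=glucagon,
        )


# ---------------------------------------------------------------------------
# the closed loop
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Time-indexed traces and event log of one closed-loop run."""

    times: np.ndarray             # min, Ts grid
    glucose_true: np.ndarray      # mg/dl
    glucose_cgm: np.ndarray       # mg/dl
    insulin_basal: np.ndarray     # U/hr commanded per interval
    insulin_bolus: np.ndarray     # U per interval
    glucagon_rate: np.ndarray     # mcg/kg/hr per interval
    meals: list[MealEvent]        # realized meals, rescues included
    exercise: list[ExerciseBout]
    rescues: list[float]          # rescue meal times
    final_state: ModelState
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        def _pad(x: np.ndarray) -> np.ndarray:
            # dosing covers intervals; pad so every sample row is complete
            return np.append(x, 0.0) if len(x) == len(self.times) - 1 else x

        return pd.DataFrame(
            {
                "time_min": self.times,
                "glucose_true_mgdl": self.glucose_true,
                "glucose_cgm_mgdl": self.glucose_cgm,
                "insulin_basal_uhr": _pad(self.insulin_basal),
                "insulin_bolus_u": _pad(self.insulin_bolus),
                "glucagon_mcgkghr": _pad(self.glucagon_rate),
            }
        )


class ControllerError(RuntimeError):
    """The controller raised; carries the partial trace."""

    def __init__(self, message: str, partial: SimulationResult | None = None):
        super().__init__(message)
        self.partial = partial


def run_closed_loop(
    patient: VirtualPatient,
    scenario: Scenario,
    controller: Controller,
    dt: float = 1.0,
    initial_state: ModelState | None = None,
) -> SimulationResult:
    """Simulate a scenario under closed-loop control.

    The patient starts from the titrated 115 mg/dl steady state unless
    ``initial_state`` overrides.  Every Ts = 5 min the controller sees
    the CGM history and announced meals and returns dosing for the next
    interval; the model is advanced with fixed-step RK4 (``dt`` = 1 min)
    under exercise and circadian sensitivity modulation.  Identical
    (patient, scenario, controller, seed) reproduce identical results.
    """
    params = patient.params
    rng_meal, rng_phase, rng_noise = np.random.default_rng(scenario.seed).spawn(3)

    realized = [
        apply_meal_uncertainty(m, scenario.meal_uncertainty_pct, rng_meal)
        for m in scenario.meals
    ]
    phase = (
        scenario.circadian.phase
        if scenario.circadian.phase is not None
        else 2.0 * math.pi * rng_phase.uniform()
    )
    exercise = ExerciseProfile(scenario.exercise)
    sf_nom = params.sf_nominal()

    def sf_effective(t: float) -> tuple[float, float, float]:
        sf = circadian_sensitivity(
            t, sf_nom, scenario.circadian.amplitude, phase, scenario.circadian.period
        )
        return exercise.sensitivities(t, sf)

    n_intervals = int(round(scenario.duration / TS_MIN))
    noise = generate_cgm_noise(n_intervals + 1, scenario.cgm_noise, rng_noise)

    if initial_state is None:
        from .model import ParameterBatch, steady_state_y0

        pb = ParameterBatch.from_params([params])
        y = steady_state_y0(pb, patient.basal_mukgmin, patient.steady_glucose)[0]
        state = ModelState.from_array(y)
    else:
        state = initial_state

    announced = [(m.time, m.carbs_announced) for m in scenario.meals if m.announced]
    public = PatientPublicInfo(
        weight=patient.weight,
        tdir=patient.tdir,
        basal_rate=patient.basal_rate,
        mode=params.mode,
    )

    times = TS_MIN * np.arange(n_intervals + 1)
    g_true = np.empty(n_intervals + 1)
    g_cgm = np.empty(n_intervals + 1)
    basal_log = np.zeros(n_intervals)
    bolus_log = np.zeros(n_intervals)
    glucagon_log = np.zeros(n_intervals)
    rescues: list[float] = []
    last_rescue: float | None = None

    g_true[0] = plasma_glucose_mgdl(state, params)
    g_cgm[0] = g_true[0] + noise[0]

    for k in range(n_intervals):
        t = times[k]
        obs = ControllerObservation(
            time=t,
            cgm_history=g_cgm[: k + 1].tolist(),
            announced_meals=[(tm, g) for tm, g in announced if tm <= t],
            patient=public,
        )
        try:
            cmd = controller(obs)
        except Exception as exc:  # pragma: no cover - exercised via tests
            partial = SimulationResult(
                times[: k + 1], g_true[: k + 1], g_cgm[: k + 1],
                basal_log[:k], bolus_log[:k], glucagon_log[:k],
                realized, scenario.exercise, rescues, state, scenario.seed,
            )
            raise ControllerError(f"controller failed at t={t}: {exc}", partial) from exc

        basal_log[k] = cmd.insulin_basal
        bolus_log[k] = cmd.insulin_bolus
        u_I = insulin_uhr_to_mukgmin(cmd.insulin_basal, patient.weight)
        if cmd.insulin_bolus > 0:
            state.S_1 += cmd.insulin_bolus * 1000.0 / patient.weight  # U -> mU/kg
        u_g = 0.0
        if params.mode == "DH" and cmd.glucagon_rate > 0:
            glucagon_log[k] = cmd.glucagon_rate
            u_g = glucagon_mcgkghr_to_mgkgmin(cmd.glucagon_rate)

        _, traj = integrate(
            state, params, t_end=t + TS_MIN, t0=t, dt=dt,
            u_I=u_I, u_g=u_g, meals=realized, sf_effective=sf_effective,
        )
        state = ModelState.from_array(traj[-1])
        g_true[k + 1] = plasma_glucose_mgdl(state, params)
        g_cgm[k + 1] = g_true[k + 1] + noise[k + 1]

        rescue = rescue_policy(
            g_true[: k + 2], scenario.rescue, ts=TS_MIN, last_rescue_time=last_rescue
        )
        if rescue is not None:
            realized.append(rescue)
            rescues.append(rescue.time)
            last_rescue = rescue.time

    return SimulationResult(
        times=times,
        glucose_true=g_true,
        glucose_cgm=g_cgm,
        insulin_basal=basal_log,
        insulin_bolus=bolus_log,
        glucagon_rate=glucagon_log,
        meals=realized,
        exercise=list(scenario.exercise),
        rescues=rescues,
        final_state=state,
        seed=scenario.seed,
    )
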