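"""Aerobic-exercise sub-model.

During an aerobic bout, active tissue takes up extra glucose.  The
steady-state uptake is a quadratic in exercise intensity (percent of
VO2max); the actual uptake Gamma_PGUA relaxes toward it with a 30-min
time constant and decays back after the bout.  Hepatic production by
active tissue Gamma_HGPA is taken equal to Gamma_PGUA for
short-duration exercise.  Three multipliers — peripheral glucose uptake
M_PGU, peripheral insulin uptake M_PIU and hepatic glucose production
M_HGP — scale the insulin sensitivities while exercise is in effect:

    S_f1_EX = M_PGU * M_PIU * S_f1
    S_f2_EX = M_PGU * M_PIU * S_f2
    S_f3_EX = M_HGP * S_f3

All three multipliers are exactly 1 at rest, so an empty exercise
schedule reproduces the sedentary trajectory bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

GAMMA_TAU_MIN = 30.0          # min, relaxation time constant of Gamma_PGUA
BASAL_PGU_MG_MIN = 35.0       # mg/min, basal peripheral glucose uptake
BASAL_HGP_MG_MIN = 155.0      # mg/min, basal hepatic glucose production


@dataclass
class ExerciseBout:
    """One aerobic exercise bout.

    ``pvo2max`` is the exercise intensity as a fraction of maximal
    oxygen consumption (0.60 for the 60%-VO2max study protocol);
    ``pamm`` the fraction of muscular mass active (0.5 for moderate
    treadmill running, ~0.25 for two-legged cycling).
    """

    start: float          # minutes from scenario start
    duration: float       # minutes
    pvo2max: float = 0.60
    pamm: float = 0.50

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("bout duration must be positive")
        if not 0 < self.pvo2max <= 1:
            raise ValueError("pvo2max must be a fraction in (0, 1]")
        if not 0 < self.pamm <= 1:
            raise ValueError("pamm must be a fraction in (0, 1]")

    @property
    def end(self) -> float:
        return self.start + self.duration


def pvo2max_from_met(met: float, met_max: float) -> float:
    """Exercise intensity fraction from metabolic equivalents MET/MET_max."""
    if met_max <= 0:
        raise ValueError("met_max must be positive")
    if not 0 < met <= met_max:
        raise ValueError("met must lie in (0, met_max]")
    return met / met_max


def gamma_pgua_steady_state(pvo2max: float) -> float:
    """Steady-state active-tissue glucose uptake (mg/min) at a given intensity.

    Quadratic in intensity expressed in percent units; negative values
    at very low intensity (below ~8% VO2max) are floored to zero.
    """
    p = 100.0 * pvo2max
    return max(0.0, 0.006 * p * p + 1.2264 * p - 10.1958)


def gamma_dynamics_deriv(gamma: float, gamma_ss: float) -> float:
    """dGamma_PGUA/dt: first-order relaxation toward ``gamma_ss``."""
    return (gamma_ss - gamma) / GAMMA_TAU_MIN


def exercise_multipliers(gamma_pgua: float, pamm: float) -> tuple[float, float, float]:
    """(M_PGU, M_PIU, M_HGP) for a given uptake level and active-mass fraction.

    ``gamma_pgua = 0`` (rest) yields the identity (1, 1, 1); M_PIU only
    departs from 1 while a bout is in effect, which this function
    encodes by gating on ``gamma_pgua > 0``.
    """
    if not 0 < pamm <= 1:
        raise ValueError("pamm must be a fraction in (0, 1]")
    if gamma_pgua <= 0.0:
        return (1.0, 1.0, 1.0)
    m_pgu = 1.0 + gamma_pgua * pamm / BASAL_PGU_MG_MIN
    m_piu = 1.0 + 2.4 * pamm
    m_hgp = 1.0 + gamma_pgua * pamm / BASAL_HGP_MG_MIN  # Gamma_HGPA == Gamma_PGUA
    return (m_pgu, m_piu, m_hgp)


def apply_exercise_to_sensitivities(
    sf_nominal: tuple[float, float, float],
    multipliers: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Scale (S_f1, S_f2, S_f3) by the exercise multipliers."""
    m_pgu, m_piu, m_hgp = multipliers
    if min(sf_nominal) <= 0 or min(multipliers) <= 0:
        raise ValueError("sensitivities and multipliers must be positive")
    return (m_pgu * m_piu * sf_nominal[0], m_pgu * m_piu * sf_nominal[1], m_hgp * sf_nominal[2])


class ExerciseProfile:
    """Closed-form Gamma_PGUA(t) over a schedule of bouts.

    The target uptake is piecewise constant (the steady-state value
    inside a bout, zero outside), so Gamma follows exact exponential
    segments between bout boundaries.  Evaluating analytically keeps
    every RK4 stage consistent and makes the profile a pure function of
    time.
    """

    def __init__(self, bouts: Sequence[ExerciseBout]):
        self.bouts = sorted(bouts, key=lambda b: b.start)
        for a, b in zip(self.bouts, self.bouts[1:]):
            if b.start < a.end:
                raise ValueError("exercise bouts must not overlap")
        # breakpoints: (time, gamma at time, target after time, pamm after time)
        self._segments: list[tuple[float, float, float, float]] = [(0.0, 0.0, 0.0, 0.0)]
        g = 0.0
        t_prev, target_prev = 0.0, 0.0
        for bout in self.bouts:
            g = self._relax(g, target_prev, bout.start - t_prev)
            target = gamma_pgua_steady_state(bout.pvo2max)
            self._segments.append((bout.start, g, target, bout.pamm))
            g = self._relax(g, target, bout.duration)
            self._segments.append((bout.end, g, 0.0, bout.pamm))
            t_prev, target_prev = bout.end, 0.0

    @staticmethod
    def _relax(g0: float, target: float, dt: float) -> float:
        return target + (g0 - target) * math.exp(-dt / GAMMA_TAU_MIN)

    def gamma(self, t: float) -> float:
        seg = self._segments[0]
        for s in self._segments:
            if s[0] <= t:
                seg = s
            else:
                break
        t0, g0, target, _ = seg
        return self._relax(g0, target, t - t0)

    def _active_pamm(self, t: float) -> float:
        """PAMM in force at time t: the bout's fraction during a bout or its
        decay tail, zero before any exercise has occurred."""
        pamm = 0.0
        for t0, _, _, p in self._segments:
            if t0 <= t:
                pamm = p
            else:
                break
        return pamm

    def multipliers(self, t: float) -> tuple[float, float, float]:
        g = self.gamma(t)
        in_bout = any(b.start <= t < b.end for b in self.bouts)
        if g <= 0.0 and not in_bout:
            return (1.0, 1.0, 1.0)
        pamm = self._active_pamm(t)
        if pamm == 0.0:
            return (1.0, 1.0, 1.0)
        m_pgu = 1.0 + g * pamm / BASAL_PGU_MG_MIN
        m_hgp = 1.0 + g * pamm / BASAL_HGP_MG_MIN
        m_piu = 1.0 + 2.4 * pamm if in_bout else 1.0
        return (m_pgu, m_piu, m_hgp)

    def sensitivities(
        self, t: float, sf_nominal: tuple[float, float, float]
    ) -> tuple[float, float, float]:
        m = self.multipliers(t)
        if m == (1.0, 1.0, 1.0):
            return sf_nominal
        return apply_exercise_to_sensitivities(sf_nominal, m)
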