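"""Virtual patient generation.

A virtual patient is a draw from the population distribution of the
sensitive inter-subject model parameters, plus a body weight, with a
basal insulin rate titrated so that the meal-free steady-state glucose
is 115 mg/dl.  The total daily insulin requirement (TDIR) follows from
the titrated basal via the empirical basal-to-total factor 1.8 (55.6%
of daily insulin from basal, 44.4% from meals).

Single-hormone (SH) patients sample the three insulin sensitivities
(S_f1, S_f2, S_f3) from a correlated multivariate normal; dual-hormone
(DH) patients additionally sample EGP_0, S_fGG, k_c and k_g3
independently.  Sampled candidates must pass physiologic feasibility
screens (2 criteria for SH, 4 for DH) to enter the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    ParameterBatch,
    simulate_constant_batch,
    steady_state_glucose_batch,
    steady_state_y0,
)
from .parameters import (
    MGDL_PER_MMOLL,
    NONDIABETIC_SF,
    ModelParameters,
    glucagon_mcgkghr_to_mgkgmin,
    insulin_mukgmin_to_uday,
    insulin_mukgmin_to_uhr,
)

__all__ = [
    "SamplingSpec",
    "VirtualPatient",
    "TitrationError",
    "titrate_basal",
    "sc_to_tdir",
    "sc_tdir_curve",
    "sample_patient",
    "feasibility_screen",
    "generate_population",
    "match_patient",
]

GLUCOSE_TARGET_MGDL = 115.0
BASAL_TO_TDIR_FACTOR = 1.8
REFERENCE_SC = 0.4  # composite at which the published T1D means apply


class TitrationError(RuntimeError):
    """Basal titration could not reach the glucose target."""


@dataclass
class SamplingSpec:
    """Population distribution of the sampled parameters.

    Sensitivity means/SDs are for the T1D population (sensitivity
    composite 0.4 relative to non-diabetic nominals); correlations are
    corr(S_f1,S_f2) = 0.75 and corr(S_f2,S_f3) = 0.25, with the
    unspecified corr(S_f1,S_f3) set to 0.  DH mode additionally samples
    EGP_0, glucagon sensitivity S_fGG, remote clearance k_c and the
    EGP-rate gain k_g3 from independent normals.  Non-positive draws are
    rejected and redrawn; weight is floored at 40 kg.
    """

    sf_mean: tuple[float, float, float] = (21e-4, 3.5e-4, 214e-4)
    sf_sd: tuple[float, float, float] = (5.9e-4, 1.4e-4, 5.9e-4)
    rho_12: float = 0.75
    rho_23: float = 0.25
    rho_13: float = 0.0
    weight_mean: float = 76.3
    weight_sd: float = 14.6
    weight_floor: float = 40.0
    egp0_mean: float = 1.61e-2
    egp0_sd: float = 0.15e-2
    sfgg_mean: float = 1.7e-2
    sfgg_sd: float = 0.47e-2
    kc_mean: float = 6.0e-2
    kc_sd: float = 1.95e-2
    kg3_mean: float = 140.0
    kg3_sd: float = 39.9
    sc: float = REFERENCE_SC

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sf_sd) or self.weight_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if np.linalg.eigvalsh(self.sf_correlation()).min() <= 0:
            raise ValueError("sensitivity correlation matrix must be positive-definite")

    def sf_correlation(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.rho_12, self.rho_13],
                [self.rho_12, 1.0, self.rho_23],
                [self.rho_13, self.rho_23, 1.0],
            ]
        )

    def sf_covariance(self) -> np.ndarray:
        sd = np.asarray(self.sf_sd)
        return self.sf_correlation() * np.outer(sd, sd)

    def scaled_to(self, sc: float) -> "SamplingSpec":
        """Spec at a different sensitivity composite.

        Sensitivity means and SDs scale proportionally with the
        composite (the published SDs are taken as already composite-
        scaled, i.e. constant coefficient of variation).
        """
        if sc <= 0:
            raise ValueError("sensitivity composite must be positive")
        r = sc / self.sc
        return SamplingSpec(
            sf_mean=tuple(m * r for m in self.sf_mean),
            sf_sd=tuple(s * r for s in self.sf_sd),
            rho_12=self.rho_12,
            rho_23=self.rho_23,
            rho_13=self.rho_13,
            weight_mean=self.weight_mean,
            weight_sd=self.weight_sd,
            weight_floor=self.weight_floor,
            egp0_mean=self.egp0_mean,
            egp0_sd=self.egp0_sd,
            sfgg_mean=self.sfgg_mean,
            sfgg_sd=self.sfgg_sd,
            kc_mean=self.kc_mean,
            kc_sd=self.kc_sd,
            kg3_mean=self.kg3_mean,
            kg3_sd=self.kg3_sd,
            sc=sc,
        )


@dataclass
class VirtualPatient:
    """A sampled, titrated (and possibly screened) in-silico subject."""

    params: ModelParameters
    weight: float
    sc: float
    basal_mukgmin: float        # titrated constant infusion, mU/kg/min
    basal_rate: float           # same, as pump rate U/hr
    basal_tdir: float           # U/day from basal alone
    tdir: float                 # total daily insulin requirement, U/day
    steady_glucose: float       # achieved meal-free steady state, mg/dl
    feasible: bool = True
    criteria: dict = field(default_factory=dict)

    @property
    def mode(self) -> str:
        return self.params.mode


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _rejection_normal(rng, mean, sd, n, lower=0.0, max_rejects=1000):
    """Normal draws truncated at ``lower`` by rejection."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(max_rejects):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise ValueError(
        f"more than {max_rejects} consecutive rejections sampling N({mean}, {sd})"
    )


def _sample_sf(rng, spec: SamplingSpec, n: int, max_rejects=1000) -> np.ndarray:
    """Correlated (n, 3) sensitivity draws, all components positive."""
    mean = np.asarray(spec.sf_mean)
    cov = spec.sf_covariance()
    draws = rng.multivariate_normal(mean, cov, size=n, method="svd")
    for _ in range(max_rejects):
        bad = (draws <= 0).any(axis=1)
        if not bad.any():
            return draws
        draws[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()), method="svd")
    raise ValueError(f"more than {max_rejects} consecutive rejections sampling sensitivities")


def sample_parameter_batch(
    spec: SamplingSpec, mode: str, rng: np.random.Generator, n: int
) -> ParameterBatch:
    """Draw n candidate parameter sets as a structure-of-arrays batch."""
    base = ModelParameters()
    sf = _sample_sf(rng, spec, n)
    weight = _rejection_normal(rng, spec.weight_mean, spec.weight_sd, n, lower=spec.weight_floor)
    kwargs = {
        name: np.full(n, getattr(base, name))
        for name in ParameterBatch._ARRAY_FIELDS
    }
    kwargs.update(S_f1=sf[:, 0], S_f2=sf[:, 1], S_f3=sf[:, 2], weight=weight)
    if mode == "DH":
        kwargs["EGP_0"] = _rejection_normal(rng, spec.egp0_mean, spec.egp0_sd, n)
        kwargs["S_fGG"] = _rejection_normal(rng, spec.sfgg_mean, spec.sfgg_sd, n)
        kwargs["k_c"] = _rejection_normal(rng, spec.kc_mean, spec.kc_sd, n)
        kwargs["k_g3"] = _rejection_normal(rng, spec.kg3_mean, spec.kg3_sd, n)
    return ParameterBatch(**kwargs)


# ---------------------------------------------------------------------------
# basal titration and the Sc -> TDIR relationship
# ---------------------------------------------------------------------------

def titrate_basal_batch(
    pb: ParameterBatch,
    target_glucose: float = GLUCOSE_TARGET_MGDL,
    tol_mgdl: float = 0.5,
    u_max: float = 10.0,
    max_iter: int = 60,
    t_end: float = 2880.0,
    dt: float = 1.0,
):
    """Bisect constant basal insulin to the glucose target for n subjects.

    Each bisection evaluation runs a 48-h meal-free simulation to steady
    state.  Returns ``(u, G, G_zero, converged)`` where ``u`` is the
    titrated infusion (mU/kg/min, NaN on failure), ``G`` the achieved
    steady-state glucose, ``G_zero`` the zero-insulin steady state
    (reused by the feasibility screen) and ``converged`` a boolean mask.
    """
    n = pb.n
    G_zero = steady_state_glucose_batch(pb, 0.0, t_end=t_end, dt=dt)
    reachable = G_zero > target_glucose - tol_mgdl
    lo = np.zeros(n)
    hi = np.full(n, u_max)
    u = np.full(n, np.nan)
    G = np.full(n, np.nan)
    done = ~reachable
    for _ in range(max_iter):
        if done.all():
            break
        mid = 0.5 * (lo + hi)
        G_mid = steady_state_glucose_batch(pb, mid, t_end=t_end, dt=dt)
        newly = (~done) & (np.abs(G_mid - target_glucose) < tol_mgdl)
        u[newly] = mid[newly]
        G[newly] = G_mid[newly]
        done |= newly
        high = G_mid > target_glucose
        lo = np.where(high & ~done, mid, lo)
        hi = np.where(~high & ~done, mid, hi)
    converged = done & reachable & np.isfinite(u)
    return u, G, G_zero, converged


def titrate_basal(
    params: ModelParameters, target_glucose: float = GLUCOSE_TARGET_MGDL, **kwargs
) -> float:
    """Titrated constant basal (mU/kg/min) for a single subject."""
    pb = ParameterBatch.from_params([params])
    u, _, _, ok = titrate_basal_batch(pb, target_glucose=target_glucose, **kwargs)
    if not ok[0]:
        raise TitrationError(
            f"steady-state glucose target {target_glucose} mg/dl unreachable"
        )
    return float(u[0])


def sc_to_tdir(
    sc: float, weight: float = 76.3, base_params: ModelParameters | None = None
) -> float:
    """Total daily insulin requirement (U/day) at a sensitivity composite.

    Scales the non-diabetic nominal sensitivities by ``sc``, titrates
    basal to 115 mg/dl, converts to U/day at the given weight, and
    applies the 1.8 basal-to-total factor.
    """
    if not 0.1 <= sc <= 2.0:
        raise ValueError("sensitivity composite must lie in [0.1, 2]")
    base = base_params or ModelParameters()
    params = base.replace(
        S_f1=NONDIABETIC_SF[0] * sc,
        S_f2=NONDIABETIC_SF[1] * sc,
        S_f3=NONDIABETIC_SF[2] * sc,
        weight=weight,
    )
    u = titrate_basal(params)
    return float(insulin_mukgmin_to_uday(u, weight) * BASAL_TO_TDIR_FACTOR)


def sc_tdir_curve(
    sc_values: Sequence[float],
    weight: float = 76.3,
    base_params: ModelParameters | None = None,
) -> np.ndarray:
    """TDIR (U/day) for each composite in ``sc_values``, titrated in batch."""
    sc_arr = np.asarray(sc_values, dtype=float)
    base = base_params or ModelParameters()
    n = len(sc_arr)
    kwargs = {
        name: np.full(n, getattr(base, name)) for name in ParameterBatch._ARRAY_FIELDS
    }
    kwargs.update(
        S_f1=NONDIABETIC_SF[0] * sc_arr,
        S_f2=NONDIABETIC_SF[1] * sc_arr,
        S_f3=NONDIABETIC_SF[2] * sc_arr,
        weight=np.full(n, weight),
    )
    pb = ParameterBatch(**kwargs)
    u, _, _, ok = titrate_basal_batch(pb)
    tdir = insulin_mukgmin_to_uday(u, weight) * BASAL_TO_TDIR_FACTOR
    tdir[~ok] = np.nan
    return tdir


# ---------------------------------------------------------------------------
# feasibility screening
# ---------------------------------------------------------------------------

HIGH_INSULIN_U_HR = 15.0            # criterion-2 challenge dose
HIGH_GLUCAGON_MCGKGHR = 20.0        # criterion-3 challenge dose
LOW_GLUCAGON_MCGKGHR = 0.2          # criterion-4 challenge dose
ZERO_INSULIN_THRESHOLD = 300.0      # mg/dl
HIGH_INSULIN_DROP = 100.0           # mg/dl below baseline
GLUCAGON_RISE_MIN = 50.0            # mg/dl above baseline within 2 h
GLUCAGON_RISE_MAX = 100.0           # mg/dl cap for the low dose
GLUCAGON_DELIVERY_MIN = 60.0        # min, duration of the challenge delivery
GLUCAGON_HIGH_HORIZON = 120.0       # min, observation window from dose start
GLUCAGON_LOW_HORIZON = 240.0        # min


def feasibility_screen_batch(
    pb: ParameterBatch,
    basal_u: np.ndarray,
    baseline_G: np.ndarray,
    mode: str,
    G_zero: np.ndarray | None = None,
    absolute_high_insulin: bool = False,
    glucagon_delivery_min: float = GLUCAGON_DELIVERY_MIN,
) -> dict[str, np.ndarray]:
    """Physiologic feasibility criteria for n titrated candidates.

    SH: (1) zero-insulin steady-state glucose above 300 mg/dl;
    (2) a 15 U/hr insulin challenge drives steady-state glucose more
    than 100 mg/dl below the 115 mg/dl baseline (``absolute_high_insulin``
    switches to the alternative reading: steady state below 100 mg/dl).
    DH adds two glucagon challenges, each delivered at the stated pump
    rate for ``glucagon_delivery_min`` minutes (a one-hour dose) from
    the titrated steady state: (3) 20 mcg/kg/hr must raise glucose more
    than 50 mg/dl above baseline within 2 h of the dose start;
    (4) 0.2 mcg/kg/hr must never raise it more than 100 mg/dl above
    baseline (observed over 4 h, which covers the full transient).
    A sustained (never-ending) infusion can be requested with
    ``glucagon_delivery_min=inf``; see docs/methods.md for why the
    finite delivery is the default.
    """
    out: dict[str, np.ndarray] = {}
    if G_zero is None:
        G_zero = steady_state_glucose_batch(pb, 0.0)
    out["zero_insulin"] = G_zero > ZERO_INSULIN_THRESHOLD

    u_high = HIGH_INSULIN_U_HR * 1000.0 / (60.0 * pb.weight)
    G_high = steady_state_glucose_batch(pb, u_high)
    if absolute_high_insulin:
        out["high_insulin"] = G_high < 100.0
    else:
        out["high_insulin"] = (baseline_G - G_high) > HIGH_INSULIN_DROP

    if mode == "DH":
        basal = np.where(np.isfinite(basal_u), basal_u, 0.0)
        y0 = steady_state_y0(pb, basal, glucose_mgdl=GLUCOSE_TARGET_MGDL)
        y0[:, 6] = np.where(
            np.isfinite(baseline_G), baseline_G, GLUCOSE_TARGET_MGDL
        ) / MGDL_PER_MMOLL * pb.V_G
        y0[:, 7] = np.where(y0[:, 3] > 0, y0[:, 3] * y0[:, 6] / (pb.k_12 + y0[:, 4]), 0.0)

        base = np.where(np.isfinite(baseline_G), baseline_G, GLUCOSE_TARGET_MGDL)
        rise_high = glucagon_challenge_rise_batch(
            pb, basal, y0, HIGH_GLUCAGON_MCGKGHR, GLUCAGON_HIGH_HORIZON,
            delivery_min=glucagon_delivery_min,
        ) - base
        out["glucagon_high"] = rise_high > GLUCAGON_RISE_MIN

        rise_low = glucagon_challenge_rise_batch(
            pb, basal, y0, LOW_GLUCAGON_MCGKGHR, GLUCAGON_LOW_HORIZON,
            delivery_min=glucagon_delivery_min,
        ) - base
        out["glucagon_low"] = rise_low <= GLUCAGON_RISE_MAX
    return out


def glucagon_challenge_rise_batch(
    pb: ParameterBatch,
    basal_u: np.ndarray,
    y0: np.ndarray,
    dose_mcgkghr: float,
    horizon_min: float,
    delivery_min: float = GLUCAGON_DELIVERY_MIN,
) -> np.ndarray:
    """Maximum plasma glucose (mg/dl) during a glucagon challenge.

    Glucagon is infused at ``dose_mcgkghr`` for ``delivery_min`` minutes
    (infinite for a sustained infusion) while basal insulin is held
    constant; the maximum glucose within ``horizon_min`` of the dose
    start is returned.
    """
    ug = glucagon_mcgkghr_to_mgkgmin(dose_mcgkghr)
    t_on = min(delivery_min, horizon_min)
    y, G_on = simulate_constant_batch(
        pb, basal_u, ug, t_end=t_on, y0=np.array(y0), record_glucose=True
    )
    g_max = G_on.max(axis=1)
    if horizon_min > t_on:
        _, G_off = simulate_constant_batch(
            pb, basal_u, 0.0, t_end=horizon_min - t_on, y0=y, record_glucose=True
        )
        g_max = np.maximum(g_max, G_off.max(axis=1))
    return g_max


def feasibility_screen(
    patient: VirtualPatient, absolute_high_insulin: bool = False
) -> dict[str, bool]:
    """Per-criterion pass/fail for one titrated patient."""
    pb = ParameterBatch.from_params([patient.params])
    res = feasibility_screen_batch(
        pb,
        np.array([patient.basal_mukgmin]),
        np.array([patient.steady_glucose]),
        patient.mode,
        absolute_high_insulin=absolute_high_insulin,
    )
    return {k: bool(v[0]) for k, v in res.items()}


# ---------------------------------------------------------------------------
# population assembly
# ---------------------------------------------------------------------------

def _build_patients(
    pb: ParameterBatch, mode: str, sc: float, u, G, G_zero, converged
) -> tuple[list[VirtualPatient], dict]:
    criteria = feasibility_screen_batch(pb, u, G, mode, G_zero=G_zero)
    names = list(criteria)
    pass_all = converged.copy()
    for v in criteria.values():
        pass_all &= v
    patients = []
    for i in range(pb.n):
        basal_u = float(u[i]) if converged[i] else float("nan")
        w = float(pb.weight[i])
        basal_tdir = insulin_mukgmin_to_uday(basal_u, w) if converged[i] else float("nan")
        crit_i = {k: bool(criteria[k][i]) for k in names}
        crit_i["titration"] = bool(converged[i])
        patients.append(
            VirtualPatient(
                params=pb.subject(i, mode=mode),
                weight=w,
                sc=sc,
                basal_mukgmin=basal_u,
                basal_rate=insulin_mukgmin_to_uhr(basal_u, w) if converged[i] else float("nan"),
                basal_tdir=basal_tdir,
                tdir=basal_tdir * BASAL_TO_TDIR_FACTOR if converged[i] else float("nan"),
                steady_glucose=float(G[i]) if converged[i] else float("nan"),
                feasible=bool(pass_all[i]),
                criteria=crit_i,
            )
        )
    report = {
        "n_drawn": int(pb.n),
        "n_feasible": int(pass_all.sum()),
        "pass_counts": {k: int(v.sum()) for k, v in criteria.items()},
        "titration_failures": int((~converged).sum()),
        "tdir": [p.tdir for p in patients if p.feasible],
    }
    return patients, report


def sample_patient(
    spec: SamplingSpec, mode: str, rng: np.random.Generator
) -> VirtualPatient:
    """Draw, titrate and screen a single candidate (may be infeasible)."""
    pb = sample_parameter_batch(spec, mode, rng, 1)
    u, G, G_zero, conv = titrate_basal_batch(pb)
    patients, _ = _build_patients(pb, mode, spec.sc, u, G, G_zero, conv)
    return patients[0]


def generate_population(
    n_target: int,
    spec: SamplingSpec | None = None,
    mode: str = "SH",
    rng: np.random.Generator | int | None = None,
    exact_n: bool = False,
    min_pass_rate: float = 0.1,
) -> tuple[list[VirtualPatient], dict]:
    """Generate a virtual patient population.

    Default behaviour draws ``n_target`` candidates and keeps the
    feasible ones (the published construction: 100 draws, ~99 SH / ~90
    DH passers).  With ``exact_n`` it keeps drawing until ``n_target``
    feasible patients have accumulated.  Returns the feasible patients
    and a generation report with per-criterion pass counts and the TDIR
    values for histogramming.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    spec = spec or SamplingSpec()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    feasible: list[VirtualPatient] = []
    reports: list[dict] = []
    drawn = 0
    while True:
        n_batch = n_target if not exact_n else max(n_target - len(feasible), 1)
        pb = sample_parameter_batch(spec, mode, rng, n_batch)
        u, G, G_zero, conv = titrate_basal_batch(pb)
        patients, rep = _build_patients(pb, mode, spec.sc, u, G, G_zero, conv)
        drawn += n_batch
        feasible.extend(p for p in patients if p.feasible)
        reports.append(rep)
        if not exact_n or len(feasible) >= n_target:
            break
        if drawn > 20 * n_target:
            raise RuntimeError("feasible-patient yield too low")
    if drawn >= 20 and len(feasible) / drawn < min_pass_rate:
        raise RuntimeError(
            f"feasibility pass rate {len(feasible) / drawn:.2f} below sanity floor"
        )
    report = {
        "mode": mode,
        "n_drawn": drawn,
        "n_feasible": len(feasible),
        "pass_counts": {
            k: sum(r["pass_counts"][k] for r in reports)
            for k in reports[0]["pass_counts"]
        },
        "titration_failures": sum(r["titration_failures"] for r in reports),
        "tdir": [p.tdir for p in feasible],
    }
    if exact_n:
        feasible = feasible[:n_target]
    return feasible, report


def match_patient(
    target_tdir: float,
    target_weight: float,
    spec: SamplingSpec | None = None,
    mode: str = "SH",
    rng: np.random.Generator | int | None = None,
    pool_size: int = 100,
    sc_grid: Sequence[float] | None = None,
) -> VirtualPatient:
    """Virtual twin of a clinical subject by closest TDIR at their weight.

    Builds the Sc->TDIR curve at the subject's actual weight, picks the
    composite whose TDIR is nearest the target, generates a temporary
    pool of feasible patients at that composite (weight fixed), and
    returns the pool member with minimal |TDIR - target|.
    """
    if target_tdir <= 0 or target_weight <= 0:
        raise ValueError("targets must be positive")
    spec = spec or SamplingSpec()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    grid = np.asarray(sc_grid if sc_grid is not None else np.arange(0.1, 2.0001, 0.05))
    tdir_curve = sc_tdir_curve(grid, weight=target_weight)
    valid = np.isfinite(tdir_curve)
    if not valid.any():
        raise TitrationError("no composite on the grid could be titrated")
    best_sc = float(grid[valid][np.argmin(np.abs(tdir_curve[valid] - target_tdir))])
    pool_spec = spec.scaled_to(best_sc)
    pool_spec = pool_spec.__class__(
        **{**pool_spec.__dict__, "weight_mean": target_weight, "weight_sd": 0.0}
    )
    pool, _ = generate_population(pool_size, pool_spec, mode=mode, rng=rng)
    if not pool:
        raise RuntimeError("empty feasible pool during matching")
    return min(pool, key=lambda p: abs(p.tdir - target_tdir))
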