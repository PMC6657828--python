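"""Model parameters, state containers and unit conversions.

The glucoregulatory model is a Hovorka-family compartmental ODE system.
In single-hormone (SH) mode it has 8 states: two subcutaneous insulin
masses ``S_1, S_2`` (mU/kg), plasma insulin ``I`` (mU/L), three insulin
action variables ``X_1, X_2, X_3`` and two glucose masses ``Q_1, Q_2``
(mmol/kg).  Dual-hormone (DH) mode adds 13 states in total: three
subcutaneous/plasma glucagon masses ``X_1g, X_2g, X_3g`` (mg/kg) and the
glucagon-action pair ``Y, Z`` (``Y`` multiplies endogenous glucose
production, ``Z = dY/dt`` puts the second-order action model in
state-space form).

Default parameter values are the published population means for adults
with type 1 diabetes; the dataclass validates positivity and the
bioavailability bound on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

# molar mass of glucose, g/mmol — used to convert meal grams to mmol/kg
GLUCOSE_MOLAR_MASS_G_PER_MMOL = 0.18016

# mg/dl per mmol/L for glucose
MGDL_PER_MMOLL = 18.016

#: State vector layout (DH carries all 13; SH uses the first 8).
STATE_NAMES = (
    "S_1", "S_2", "I", "X_1", "X_2", "X_3", "Q_1", "Q_2",
    "X_1g", "X_2g", "X_3g", "Y", "Z",
)
N_STATES_SH = 8
N_STATES_DH = 13

# mass compartments clamped non-negative by the integrator
MASS_STATE_INDICES = (0, 1, 6, 7, 8, 9, 10)

#: Non-diabetic nominal insulin sensitivities.  The published T1D means
#: correspond to a sensitivity composite Sc = 0.4 applied to these
#: (people with T1D are modelled with 60% lower insulin sensitivity).
NONDIABETIC_SF = (21e-4 / 0.4, 3.5e-4 / 0.4, 214e-4 / 0.4)


def mmoll_to_mgdl(g: float | np.ndarray) -> float | np.ndarray:
    """Convert glucose concentration mmol/L -> mg/dl."""
    return np.asarray(g) * MGDL_PER_MMOLL if isinstance(g, np.ndarray) else g * MGDL_PER_MMOLL


def mgdl_to_mmoll(g: float | np.ndarray) -> float | np.ndarray:
    return g / MGDL_PER_MMOLL


def insulin_uhr_to_mukgmin(rate_u_hr: float, weight_kg: float) -> float:
    """Pump basal rate U/hr -> model infusion mU/kg/min."""
    return rate_u_hr * 1000.0 / (60.0 * weight_kg)


def insulin_mukgmin_to_uhr(u_i: float, weight_kg: float) -> float:
    return u_i * 60.0 * weight_kg / 1000.0


def insulin_mukgmin_to_uday(u_i: float | np.ndarray, weight_kg: float | np.ndarray):
    """Constant infusion mU/kg/min -> daily total U/day."""
    return u_i * 1440.0 * weight_kg / 1000.0


def glucagon_mcgkghr_to_mgkgmin(rate: float) -> float:
    """Glucagon pump rate mcg/kg/hr -> model infusion mg/kg/min."""
    return rate * 1e-3 / 60.0


@dataclass
class ModelParameters:
    """Rate constants, volumes and sensitivities of the SH/DH ODE system.

    Defaults are the published population means.  ``mode`` selects the
    single-hormone (insulin only, 8 states) or dual-hormone (insulin +
    glucagon, 13 states) configuration.
    """

    # insulin kinetics
    t_max: float = 55.0        # min, time-to-max insulin absorption
    V_I: float = 0.12          # L/kg, insulin distribution volume
    k_e: float = 0.138         # 1/min, insulin elimination
    # insulin dynamics
    k_a1: float = 0.006        # 1/min
    k_a2: float = 0.06         # 1/min
    k_a3: float = 0.03         # 1/min
    S_f1: float = 21e-4        # 1/min per mU/L
    S_f2: float = 3.5e-4       # 1/min per mU/L
    S_f3: float = 214e-4       # per mU/L
    # glucose kinetics
    k_12: float = 0.066        # 1/min
    V_G: float = 0.16          # L/kg
    EGP_0: float = 1.61e-2     # mmol/kg/min
    F01: float = 0.0097        # mmol/kg/min, nominal non-insulin uptake
    # meal absorption
    t_maxG: float = 40.0       # min
    A_G: float = 0.8           # carb bioavailability, (0, 1]
    # glucagon kinetics/dynamics (DH)
    k_1g: float = 0.0065       # 1/min
    k_2g: float = 0.02777      # 1/min
    k_ge1: float = 0.0772      # 1/min
    k_ge2: float = 0.0357      # 1/min
    V_dGG: float = 0.19        # L/kg
    k_c: float = 6.0e-2        # 1/min
    S_fGG: float = 1.7e-2      # (ng/L)^-1 min^-1
    k_g3: float = 140.0        # unitless gain on Z
    # subject
    weight: float = 76.3       # kg
    mode: str = "SH"           # "SH" | "DH"
    # behavioural switches (see docs/methods.md)
    constant_f01c: bool = False  # literal constant non-insulin uptake
    floor_egp: bool = True       # clamp EGP term at zero

    def __post_init__(self) -> None:
        if self.mode not in ("SH", "DH"):
            raise ValueError(f"mode must be 'SH' or 'DH', got {self.mode!r}")
        for f in fields(self):
            if f.type == "float":
                v = getattr(self, f.name)
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")
        if not 0 < self.A_G <= 1:
            raise ValueError(f"A_G must lie in (0, 1], got {self.A_G}")

    @property
    def k_g(self) -> float:
        """Derived glucagon-action gain, 1e6 * k_c * S_fGG / V_dGG."""
        return 1e6 * self.k_c * self.S_fGG / self.V_dGG

    @property
    def n_states(self) -> int:
        return N_STATES_DH if self.mode == "DH" else N_STATES_SH

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def sf_nominal(self) -> tuple[float, float, float]:
        return (self.S_f1, self.S_f2, self.S_f3)


@dataclass
class ModelState:
    """ODE state at one time point (units in the module docstring)."""

    S_1: float = 0.0
    S_2: float = 0.0
    I: float = 0.0
    X_1: float = 0.0
    X_2: float = 0.0
    X_3: float = 0.0
    Q_1: float = 0.0
    Q_2: float = 0.0
    X_1g: float = 0.0
    X_2g: float = 0.0
    X_3g: float = 0.0
    Y: float = 0.0
    Z: float = 0.0

    def as_array(self, mode: str = "DH") -> np.ndarray:
        n = N_STATES_DH if mode == "DH" else N_STATES_SH
        return np.array([getattr(self, name) for name in STATE_NAMES[:n]], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        vals = dict(zip(STATE_NAMES, np.asarray(y, dtype=float)))
        return cls(**vals)


@dataclass
class MealEvent:
    """A carbohydrate intake.

    ``carbs_announced`` is what the controller is told; ``carbs_true`` is
    what the gut model absorbs (they differ under meal uncertainty).
    Unannounced meals (rescue carbs) have ``announced=False``.
    """

    time: float                      # minutes from scenario start
    carbs_true: float                # grams
    carbs_announced: float | None = None
    announced: bool = True

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("meal time must be >= 0")
        if self.carbs_true < 0:
            raise ValueError("carbs_true must be >= 0")
        if self.carbs_announced is None:
            self.carbs_announced = self.carbs_true
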