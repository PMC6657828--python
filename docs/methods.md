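# Methods

This note records the modelling choices behind `t1dvpp`: the model and its
assumptions, defaults and their rationale, what the synthetic protocol
does and does not emulate, numerical details, and known limitations.

## Model structure and assumptions

The glucoregulatory core couples four linear hormone subsystems
(subcutaneous insulin kinetics, insulin action, subcutaneous glucagon
kinetics, glucagon action) to a two-compartment nonlinear glucose model.
Key assumptions:

- **Single insulin route.** Rapid-acting subcutaneous insulin with a
  two-compartment depot (time-to-maximum `t_max` = 55 min); no analog PK
  variants, no intraperitoneal/inhaled routes.
- **Glucagon acts through EGP only.** The action variable Y scales
  endogenous glucose production; the pair (Y, Z = Ẏ) expresses the
  second-order action model in state-space form. Units of Y/Z are treated
  as dimensionless modifiers of EGP, which is what the glucose equation
  implies. In SH mode Y ≡ Z ≡ 0.
- **Non-insulin uptake and renal clearance.** The glucose equation names
  F01c and F_R without formulas, and the parameter table lists a constant
  F01c = 0.0097 mmol/kg/min. We implement the standard Cambridge-family
  nonlinearities — F01c = F01·min(1, G/4.5) and
  F_R = 0.003·(G−9)·V_G for G > 9 mmol/L, with F01 = 0.0097 — because the
  model is of that family and a constant-only reading leaves the
  zero-insulin steady state unbounded (production would always exceed uptake).
  `constant_f01c=True` restores the literal constant reading.
- **EGP floor.** EGP₀(1 − X₃ + Y + k_g3·Z) is clamped at zero so that high
  insulin action cannot turn hepatic production into an unphysical sink
  (`floor_egp=False` disables).
- **Carbohydrate conversion.** Meal grams convert to mmol/kg with the
  glucose molar mass 180.16 g/mol and the subject's weight; the gamma-
  shaped gut model conserves the bioavailable dose A_G·D_G exactly.

## Exercise

Aerobic bouts raise the insulin sensitivities through three multipliers
driven by the active-tissue uptake Γ_PGUA. Choices:

- The steady-state uptake polynomial takes its argument in **percent** of
  VO₂max (at 60 % it yields ≈85 mg/min, commensurate with the 35 mg/min
  basal peripheral uptake; a fractional argument would be negative). The
  API stores intensities as fractions and converts internally.
- The sensitivity scalings are **products** M_PGU·M_PIU (for S_f1, S_f2)
  and M_HGP (for S_f3), following the antecedent exercise model.
- Γ_PGUA is floored at 0 (the polynomial is negative below ≈8 % VO₂max),
  and Γ_HGPA = Γ_PGUA (valid for short bouts).
- At bout end the uptake target snaps to 0 and Γ decays with the same
  30-min constant; no post-exercise sensitivity persistence (glycogen
  repletion) is modelled.
- Within the runtime Γ(t) is evaluated from its exact piecewise-
  exponential closed form, so every RK4 stage sees a consistent value.

## Patient generation

- **Sensitivity composite.** Non-diabetic nominal sensitivities are the
  published T1D means divided by 0.4 (T1D subjects carry 60 % lower
  insulin sensitivity); a composite Sc ∈ [0.1, 2] scales them jointly.
  The published SDs are taken as already composite-scaled, i.e. constant
  coefficient of variation when the composite changes.
- **Correlations.** corr(S_f1,S_f2) = 0.75, corr(S_f2,S_f3) = 0.25; the
  unstated corr(S_f1,S_f3) is set to 0 (minimal assumption; the matrix is
  positive-definite, det 0.375). Non-positive draws are rejected and
  redrawn; weight is floored at 40 kg.
- **Titration.** Bisection on constant basal over [0, 10] mU/kg/min, each
  evaluation a 48-h meal-free simulation, stopping inside ±0.5 mg/dl of
  the 115 mg/dl target. Simulations warm-start with the linear subsystems
  at their constant-input steady state, so only the glucose compartments
  settle. TDIR = basal·1440·weight/1000 × 1.8 (the printed TDIR-from-basal
  sentence is circular; the 44.4 %/55.6 % meal/basal split forces this
  reading).
- **Feasibility screens.** SH: (1) zero-insulin steady state > 300 mg/dl;
  (2) a 15 U/hr insulin challenge drives the steady state more than
  100 mg/dl below baseline (read as a drop relative to baseline — the
  grammatically likelier reading; a flag selects the absolute "below
  100 mg/dl" variant). DH adds the two glucagon challenges below.
- **Glucagon challenge protocol.** The challenges specify pump rates (20
  and 0.2 mcg/kg/hr) but no delivery duration. Implemented as a
  **one-hour delivery** of the stated rate from the titrated steady state
  with basal insulin held constant: the high dose must raise glucose more
  than 50 mg/dl above baseline within 2 h of the dose start; the low dose
  must never exceed 100 mg/dl above baseline (observed over 4 h, which
  covers the full transient). Rationale: under a *sustained* low-dose
  infusion the Ż-term alone contributes an integrated EGP excess of
  EGP₀·k_g3·ΔY ≈ +165 mg/dl, so even the population-mean patient breaches
  the 100 mg/dl cap and essentially no candidate could pass — contradicting
  the published construction in which most do. Over a finite dose the
  Z-transient integrates to zero and the mean patient responds ≈79 mg/dl.
  `glucagon_delivery_min=inf` restores the sustained-infusion reading.
  With the one-hour protocol, 100-draw DH pass counts average ≈75
  (ten-seed mean; ≈3 % fail the zero-insulin screen via the EGP₀ lower
  tail and ≈22 % the low-dose cap via the S_fGG/k_c/k_g3 upper tail),
  somewhat below the ≈90 of the original construction — the residual gap
  traces to the unpublished details of the challenge protocol and is
  documented rather than calibrated away.
- **Twin matching.** The Sc→TDIR curve is rebuilt at the clinical
  subject's actual weight (grid step 0.05 by default), the nearest
  composite selected, a temporary pool (default 100) generated at that
  composite with weight fixed, and the pool member with minimal
  |TDIR − target| returned.

## Closed-loop runtime

- Fixed-step RK4 with internal dt = 1 min; controller and CGM sampled
  every Ts = 5 min. Mass compartments are clamped non-negative after each
  step. Boluses enter the first subcutaneous depot as impulses (U →
  mU/kg); basal and glucagon commands convert to mU/kg/min and mg/kg/min.
- Circadian modulation multiplies all three sensitivities by
  1 + 0.3·sin(2πt/1440 + φ) — a 24-h period in wall-clock minutes (the
  printed argument is a 24-h period only if t counts samples; the intent
  is a daily rhythm). φ is drawn once per run from the scenario seed and
  shared by all patients.
- Meal uncertainty draws one U(−30 %, +30 %) factor per meal; the gut
  receives the perturbed grams, the controller only ever sees the
  announcement. Rescue carbs (default 15 g — a standard clinical choice,
  configurable) are delivered 10 min after true glucose first drops below
  70 mg/dl, are never announced, and respect a 30-min refractory period.
- CGM noise is additive AR(1) on the Ts grid (coefficient 0.7, stationary
  SD 7 mg/dl by default, fully configurable). The published sensor-error
  coefficients are not reproduced here; this is a configurable coloured-
  noise model of the same character, and nothing downstream depends on
  specific coefficients.
- The bundled `ReferenceController` is a deliberately simple basal-bolus
  rule (basal-TDIR/24 U/hr, 450-rule carb ratio, optional 1700-rule
  correction above 180 mg/dl, small fixed glucagon pulse below a falling
  80 mg/dl in DH mode). It stands in for whatever external controller a
  user plugs in; it is not exercise-aware and makes no claim of matching
  any clinical algorithm.

## Synthetic protocol

`generate_synthetic_scenario` emulates a 3.5-day outpatient study
starting at 08:00: three meals/day of 30–90 g (times jittered ±20 min
around 08:00/12:30/18:30) and one 45-min bout at 60 % VO₂max (PAMM 0.5)
two hours after lunch on days 1 and 4. It does **not** emulate real-world
features such as snacking, announcement-time errors, intermittent or
resistance exercise, pump/CGM latency or dropout — so passing tests show
internal consistency of the model chain, not fidelity to any particular
clinical dataset.

## Numerics

- RK4 at dt = 1 min agrees with dt = 0.1 min within 0.5 mg/dl over 24 h
  on a meal scenario; linear-subsystem steady states match closed forms
  to <0.1 % after 48 h.
- Steady-state evaluations exploit the warm start: because the action
  variables sit at their exact constant-input steady state, the glucose
  subsystem is linear with a computable eigenvalue bound, and the step is
  shrunk below the RK4 stability limit when extreme sensitivity draws
  make it fast (this matters near the top of the titration bracket).
- Everything stochastic flows from explicit seeds (numpy Generators);
  identical seeds reproduce populations and simulation results exactly.
- Problem sizes used by the test suite and the acceptance script —
  48-h steady-state runs, 100-draw populations, ten seeds per mode,
  1–3.5-day closed-loop scenarios — were chosen so the full pipeline
  runs in minutes on one core while keeping sampling error well inside
  the asserted tolerances.

## Known limitations

- No Bayesian/MCMC individual fitting; populations are statistical, not
  identified from traces.
- The glucagon challenge protocol details are our reading (see above).
- Exercise model validated only for continuous aerobic bouts at constant
  intensity; PAMM is fixed per bout, not adapted to the subject.
- LBGI/HBGI use the standard mg/dl risk-transform constants
  (1.509, 1.084, 5.381), which are conventional rather than printed in
  the source construction.
- The t-test comparison defaults to the classical equal-variance
  two-sample form ("student t-test"); Welch and paired variants are flags.
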