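"""Scenario construction and serialization.

A scenario holds timestamped meals and exercise bouts plus the
perturbation settings of the validation protocol.  The synthetic
generator emulates a 3.5-day outpatient study: three meals a day with
variable carbohydrate content, and a 45-minute aerobic bout at 60% of
VO2max (50% active muscle mass) starting two hours after lunch on days
1 and 4, with the clock starting at 08:00.

Scenarios serialize to YAML/JSON (lossless) and to a flat CSV event
dialect (one row per event: ``time_min, event_type, grams,
duration_min, pvo2max_pct, pamm_pct``) suitable for importing published
meal-scenario tables; scalar settings travel as ``# key=value`` header
comments in the CSV form.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .exercise import ExerciseBout
from .parameters import MealEvent
from .runtime import CGMNoiseSpec, CircadianSpec, RescuePolicy, Scenario

SCHEMA_VERSION = 1

# default outpatient meal times, minutes from the 08:00 start
MEAL_TIMES = (0.0, 270.0, 630.0)          # 08:00, 12:30, 18:30
MEAL_JITTER_MIN = 20.0
CARB_RANGE_G = (30.0, 90.0)
EXERCISE_DAYS = (0, 3)                     # study days 1 and 4
EXERCISE_AFTER_LUNCH_MIN = 120.0
EXERCISE_DURATION_MIN = 45.0
EXERCISE_PVO2MAX = 0.60
EXERCISE_PAMM = 0.50


def generate_synthetic_scenario(
    days: float = 3.5,
    rng: np.random.Generator | int | None = None,
    template: str = "outpatient-3.5d",
) -> Scenario:
    """Synthetic outpatient scenario with meals and in-clinic exercise.

    Three meals per day (30-90 g carbs, times jittered +/-20 min around
    08:00, 12:30 and 18:30) and a 45-min bout at 60% VO2max two hours
    after lunch on days 1 and 4.  Only events inside the scenario
    duration are emitted, so fractional ``days`` truncate the last day.
    """
    if days < 1:
        raise ValueError("scenario must span at least one day")
    if template != "outpatient-3.5d":
        raise ValueError(f"unknown template {template!r}")
    seed = rng if isinstance(rng, (int, np.integer)) else 0
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    duration = days * 1440.0
    meals: list[MealEvent] = []
    bouts: list[ExerciseBout] = []
    n_days = int(np.ceil(days))
    for day in range(n_days):
        lunch_time = None
        for slot, base in enumerate(MEAL_TIMES):
            t = day * 1440.0 + base + rng.uniform(-MEAL_JITTER_MIN, MEAL_JITTER_MIN)
            carbs = float(np.round(rng.uniform(*CARB_RANGE_G)))
            if slot == 1:
                lunch_time = t
            if 0 <= t <= duration:
                meals.append(MealEvent(time=round(t, 1), carbs_true=carbs))
        if day in EXERCISE_DAYS and lunch_time is not None:
            start = round(lunch_time + EXERCISE_AFTER_LUNCH_MIN, 1)
            if start + EXERCISE_DURATION_MIN <= duration:
                bouts.append(
                    ExerciseBout(
                        start=start,
                        duration=EXERCISE_DURATION_MIN,
                        pvo2max=EXERCISE_PVO2MAX,
                        pamm=EXERCISE_PAMM,
                    )
                )
    return Scenario(
        duration=duration,
        meals=sorted(meals, key=lambda m: m.time),
        exercise=bouts,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "duration": scenario.duration,
        "seed": scenario.seed,
        "start_time_of_day": scenario.start_time_of_day,
        "meal_uncertainty_pct": scenario.meal_uncertainty_pct,
        "rescue": dataclasses.asdict(scenario.rescue),
        "circadian": dataclasses.asdict(scenario.circadian),
        "cgm_noise": dataclasses.asdict(scenario.cgm_noise),
        "meals": [
            {
                "time": m.time,
                "carbs_true": m.carbs_true,
                "carbs_announced": m.carbs_announced,
                "announced": m.announced,
            }
            for m in scenario.meals
        ],
        "exercise": [dataclasses.asdict(b) for b in scenario.exercise],
    }


def scenario_from_dict(d: dict) -> Scenario:
    version = d.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported scenario schema version {version}")
    return Scenario(
        duration=float(d["duration"]),
        meals=[MealEvent(**m) for m in d.get("meals", [])],
        exercise=[ExerciseBout(**b) for b in d.get("exercise", [])],
        meal_uncertainty_pct=float(d.get("meal_uncertainty_pct", 30.0)),
        rescue=RescuePolicy(**d.get("rescue", {})),
        circadian=CircadianSpec(**d.get("circadian", {})),
        cgm_noise=CGMNoiseSpec(**d.get("cgm_noise", {})),
        seed=int(d.get("seed", 0)),
        start_time_of_day=float(d.get("start_time_of_day", 480.0)),
    )


_CSV_COLUMNS = ("time_min", "event_type", "grams", "duration_min", "pvo2max_pct", "pamm_pct")
_CSV_SCALARS = ("duration", "seed", "start_time_of_day", "meal_uncertainty_pct")


def _scenario_to_csv(scenario: Scenario, path: Path) -> None:
    with path.open("w", newline="") as fh:
        for key in _CSV_SCALARS:
            fh.write(f"# {key}={getattr(scenario, key)}\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for m in scenario.meals:
            kind = "meal" if m.announced else "rescue"
            writer.writerow([m.time, kind, m.carbs_announced if m.announced else m.carbs_true, "", "", ""])
        for b in scenario.exercise:
            writer.writerow([b.start, "exercise", "", b.duration, 100 * b.pvo2max, 100 * b.pamm])


def _scenario_from_csv(path: Path) -> Scenario:
    scalars: dict[str, float] = {}
    rows: list[dict[str, str]] = []
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                scalars[key.strip()] = float(value)
                continue
            cells = next(csv.reader([line]))
            if header is None:
                header = [c.strip() for c in cells]
                missing = set(_CSV_COLUMNS) - set(header)
                if missing:
                    raise ValueError(f"{path}:{lineno}: missing columns {sorted(missing)}")
                continue
            rows.append(dict(zip(header, cells, strict=False), _lineno=str(lineno)))
    if header is None:
        raise ValueError(f"{path}: no header row found")
    meals, bouts = [], []
    for row in rows:
        kind = row["event_type"].strip()
        t = float(row["time_min"])
        if kind == "meal":
            meals.append(MealEvent(time=t, carbs_true=float(row["grams"])))
        elif kind == "rescue":
            meals.append(
                MealEvent(time=t, carbs_true=float(row["grams"]), carbs_announced=0.0, announced=False)
            )
        elif kind == "exercise":
            bouts.append(
                ExerciseBout(
                    start=t,
                    duration=float(row["duration_min"]),
                    pvo2max=float(row["pvo2max_pct"]) / 100.0,
                    pamm=float(row["pamm_pct"]) / 100.0,
                )
            )
        else:
            raise ValueError(f"{path}:{row['_lineno']}: unknown event_type {kind!r}")
    duration = scalars.get("duration", max((m.time for m in meals), default=0.0) + 1440.0)
    return Scenario(
        duration=duration,
        meals=meals,
        exercise=bouts,
        meal_uncertainty_pct=scalars.get("meal_uncertainty_pct", 30.0),
        seed=int(scalars.get("seed", 0)),
        start_time_of_day=scalars.get("start_time_of_day", 480.0),
    )


def _dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    suffix = path.suffix.lower().lstrip(".")
    return {"yml": "yaml"}.get(suffix, suffix)


def write_scenario(scenario: Scenario, path: str | Path, dialect: str | None = None) -> None:
    """Serialize a scenario; dialect inferred from the file suffix."""
    path = Path(path)
    d = _dialect(path, dialect)
    if d == "json":
        path.write_text(json.dumps(scenario_to_dict(scenario), indent=1))
    elif d == "yaml":
        path.write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))
    elif d == "csv":
        _scenario_to_csv(scenario, path)
    else:
        raise ValueError(f"unknown scenario dialect {d!r}")


def read_scenario(path: str | Path, dialect: str | None = None) -> Scenario:
    path = Path(path)
    d = _dialect(path, dialect)
    if d == "json":
        return scenario_from_dict(json.loads(path.read_text()))
    if d == "yaml":
        return scenario_from_dict(yaml.safe_load(path.read_text()))
    if d == "csv":
        return _scenario_from_csv(path)
    raise ValueError(f"unknown scenario dialect {d!r}")
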