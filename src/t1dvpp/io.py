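"""Population and result serialization.

Populations persist as versioned JSON (one record per patient with all
model parameters, weight, composite, titrated basal, TDIR and the
per-criterion feasibility outcomes, plus the generation report and
seed).  Simulation results export as tidy CSV (one row per 5-min
sample) and metric tables as CSV in the clinical-vs-simulated layout.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import OutcomeMetrics, compare_populations, mae_outcomes
from .parameters import ModelParameters
from .population import VirtualPatient
from .runtime import SimulationResult

SCHEMA_VERSION = 1

_PARAM_FIELDS = [
    f.name for f in dataclasses.fields(ModelParameters) if f.type == "float"
]


def patient_to_dict(p: VirtualPatient) -> dict:
    return {
        "params": {name: getattr(p.params, name) for name in _PARAM_FIELDS},
        "mode": p.params.mode,
        "weight": p.weight,
        "sc": p.sc,
        "basal_mukgmin": p.basal_mukgmin,
        "basal_rate": p.basal_rate,
        "basal_tdir": p.basal_tdir,
        "tdir": p.tdir,
        "steady_glucose": p.steady_glucose,
        "feasible": p.feasible,
        "criteria": p.criteria,
    }


def patient_from_dict(d: dict) -> VirtualPatient:
    params = ModelParameters(mode=d["mode"], **d["params"])
    return VirtualPatient(
        params=params,
        weight=d["weight"],
        sc=d["sc"],
        basal_mukgmin=d["basal_mukgmin"],
        basal_rate=d["basal_rate"],
        basal_tdir=d["basal_tdir"],
        tdir=d["tdir"],
        steady_glucose=d["steady_glucose"],
        feasible=d["feasible"],
        criteria=dict(d.get("criteria", {})),
    )


def save_population(
    patients: list[VirtualPatient],
    path: str | Path,
    report: dict | None = None,
    seed: int | None = None,
) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "report": report,
        "patients": [patient_to_dict(p) for p in patients],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_population(path: str | Path) -> tuple[list[VirtualPatient], dict | None]:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported population schema version {version}")
    return [patient_from_dict(d) for d in doc["patients"]], doc.get("report")


def tdir_histogram_csv(tdir_values: list[float], path: str | Path, bin_width: float = 5.0) -> None:
    """Histogram of population TDIR values (U/day) as a two-column CSV."""
    tdir = np.asarray(tdir_values, dtype=float)
    hi = max(5.0, np.ceil(tdir.max() / bin_width) * bin_width) if tdir.size else 5.0
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(tdir, bins=edges)
    pd.DataFrame({"tdir_bin_left": edges[:-1], "count": counts}).to_csv(path, index=False)


def save_result(result: SimulationResult, path: str | Path) -> None:
    """Tidy per-sample CSV plus a JSON event-log sidecar (.events.json)."""
    path = Path(path)
    result.to_dataframe().to_csv(path, index=False)
    events = {
        "seed": result.seed,
        "meals": [
            {
                "time": m.time,
                "carbs_true": m.carbs_true,
                "carbs_announced": m.carbs_announced,
                "announced": m.announced,
            }
            for m in result.meals
        ],
        "exercise": [dataclasses.asdict(b) for b in result.exercise],
        "rescues": result.rescues,
    }
    path.with_suffix(path.suffix + ".events.json").write_text(json.dumps(events, indent=1))


def validation_table(
    clinical: pd.DataFrame, simulated: pd.DataFrame, paired: bool = False
) -> pd.DataFrame:
    """Clinical-vs-simulated outcome table (mean +/- SD, p-value, MAE).

    Both frames hold one row per scenario/patient and one column per
    outcome metric; rows must be paired.
    """
    common = [c for c in clinical.columns if c in simulated.columns]
    if not common:
        raise ValueError("no shared outcome columns between the two tables")
    mae = mae_outcomes(
        clinical[common].to_dict("records"), simulated[common].to_dict("records")
    )
    rows = []
    for metric in common:
        cmp = compare_populations(
            clinical[metric].to_numpy(), simulated[metric].to_numpy(), paired=paired
        )
        rows.append(
            {
                "metric": metric,
                "clinical_mean": cmp["mean_a"],
                "clinical_sd": cmp["sd_a"],
                "simulated_mean": cmp["mean_b"],
                "simulated_sd": cmp["sd_b"],
                "p_value": cmp["p_value"],
                "mae": mae[metric],
            }
        )
    return pd.DataFrame(rows)
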