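"""CSV/JSON readers and writers for the package's external formats.

Patients: CSV with columns ``id,age,sex,body_weight`` (sex ``M``/``F``;
missing body weight imputed from the bundled age/sex table) or a JSON array
of objects with the same fields.  Burden series: CSV with columns
``patient_id,day,bcr_abl_ratio``.  Profiles and schedules are exported as
two-column CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pk import (ConcentrationProfile, DoseSchedule, PatientRecord,
                 impute_body_weight)
from .tumor import BurdenSeries

_SEX_CODE = {"M": 1, "F": 0, "m": 1, "f": 0, "1": 1, "0": 0, 1: 1, 0: 0}


def _record_from_mapping(row) -> PatientRecord:
    sex = _SEX_CODE.get(row["sex"])
    if sex is None:
        raise ValueError(f"unrecognized sex {row['sex']!r} (use M or F)")
    bw = row.get("body_weight")
    age = float(row["age"])
    if bw is None or (isinstance(bw, float) and np.isnan(bw)) or bw == "":
        bw = impute_body_weight(age, sex)
    return PatientRecord(id=str(row["id"]), age=age, sex=sex,
                         body_weight=float(bw))


def read_patients(path) -> list:
    """Read a patient table from CSV or a JSON array of objects."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        rows = df.to_dict(orient="records")
    errors, records = [], []
    for i, row in enumerate(rows):
        try:
            records.append(_record_from_mapping(row))
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("malformed patient rows:\n" + "\n".join(errors))
    return records


def write_patients_csv(patients, path) -> None:
    df = pd.DataFrame([{"id": p.id, "age": p.age,
                        "sex": "M" if p.sex == 1 else "F",
                        "body_weight": p.body_weight} for p in patients])
    df.to_csv(path, index=False)


def read_burden_csv(path) -> dict:
    """Burden series per patient, keyed by patient id.

    Patients with fewer than 3 points (or non-positive ratios) are returned
    under the second element as ``{patient_id: reason}`` instead of raising,
    mirroring the cohort inclusion filter.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"burden file {path} contains no measurements")
    needed = {"patient_id", "day", "bcr_abl_ratio"}
    if not needed.issubset(df.columns):
        raise ValueError(f"burden CSV must have columns {sorted(needed)}")
    series, excluded = {}, {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("day")
        if len(grp) < 3:
            excluded[str(pid)] = "too few data points"
            continue
        try:
            series[str(pid)] = BurdenSeries(
                patient_id=str(pid), times=tuple(grp["day"].astype(float)),
                burden=tuple(grp["bcr_abl_ratio"].astype(float)))
        except ValueError as exc:
            excluded[str(pid)] = str(exc)
    return series, excluded


def write_burden_csv(series_list, path) -> None:
    rows = []
    for s in series_list:
        for t, b in zip(s.times, s.burden):
            rows.append({"patient_id": s.patient_id, "day": t,
                         "bcr_abl_ratio": b})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_profile_csv(profile: ConcentrationProfile, path) -> None:
    pd.DataFrame({"time_h": profile.grid,
                  "conc_mg_per_L": profile.values}).to_csv(path, index=False)


def write_schedule_csv(schedule: DoseSchedule, path) -> None:
    pd.DataFrame({"time_h": schedule.times,
                  "dose_mg": schedule.doses}).to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
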