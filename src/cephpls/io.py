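"""CSV / JSON input and output.

Two CSV dialects are supported:

* **Landmark CSV** (long): columns ``patient_id, timepoint, landmark,
  x_mm, y_mm``; one digitised point per line, y increasing upward.
* **Measurement CSV** (wide): ``patient_id`` first, then one column per
  derived variable named ``{landmark}_{s|f}_{suffix}`` (``VD_{suffix}``
  for the occlusal vertical dimension), suffix 0/1/2 for T0/T1/T2 and
  10/21/20 for increments — e.g. ``B_s_10``, ``Cp_f_1``, ``VD_10``,
  ``B_s_20``.

Both round-trip losslessly through :func:`write_landmarks` /
:func:`read_landmarks` and :func:`write_measurements` /
:func:`read_measurements`.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .ceph import TIMEPOINTS, CephError, LandmarkRecord, MeasurementRow
from .engine import BlockSpec, InnerSpec, PLSPMResult

__all__ = [
    "KNOWN_LANDMARKS",
    "read_landmarks",
    "write_landmarks",
    "read_measurements",
    "write_measurements",
    "read_model_spec",
    "write_result",
]

LANDMARK_COLUMNS = ["patient_id", "timepoint", "landmark", "x_mm", "y_mm"]

KNOWN_LANDMARKS = frozenset(
    {
        "Po", "Or", "S", "Na", "Ba", "Cd", "Cp", "A", "B", "Pog", "Me", "Gn",
        "PNS", "ANS", "U1", "L1", "U1t", "U1r", "L1t", "L1r", "U6", "L6",
        "U6mc", "L6mc",
    }
)


def read_landmarks(path) -> list[LandmarkRecord]:
    """Read a long-format landmark CSV into per-patient-timepoint records.

    Malformed headers/rows raise :class:`CephError` naming the file and
    line; unknown landmark names only trigger a warning listing them.
    Records are returned grouped by patient then timepoint, in file
    order of first appearance.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "timepoint": str,
                                      "landmark": str},
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise CephError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise CephError(f"{path}: missing landmark CSV columns {missing}")
    unknown = sorted(set(df["landmark"]) - KNOWN_LANDMARKS)
    if unknown:
        warnings.warn(
            f"{path}: unknown landmark names (kept as-is): {unknown}",
            stacklevel=2,
        )
    records: dict[tuple[str, str], LandmarkRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tp = row.timepoint
        if tp not in TIMEPOINTS:
            raise CephError(
                f"{path}:{i}: column 'timepoint': invalid value {tp!r}"
                f" (expected one of {TIMEPOINTS})"
            )
        try:
            x, y = float(row.x_mm), float(row.y_mm)
        except (TypeError, ValueError):
            raise CephError(
                f"{path}:{i}: columns 'x_mm'/'y_mm': non-numeric coordinates"
            ) from None
        if not (np.isfinite(x) and np.isfinite(y)):
            raise CephError(f"{path}:{i}: non-finite coordinates")
        key = (row.patient_id, tp)
        rec = records.get(key)
        if rec is None:
            rec = records[key] = LandmarkRecord(
                patient_id=row.patient_id, timepoint=tp, points={}
            )
        rec.points[row.landmark] = np.array([x, y])
    return list(records.values())


def write_landmarks(records: list[LandmarkRecord], path) -> None:
    rows = []
    for rec in records:
        for name in sorted(rec.points):
            x, y = rec.points[name]
            rows.append((rec.patient_id, rec.timepoint, name, repr(float(x)),
                         repr(float(y))))
    df = pd.DataFrame(rows, columns=LANDMARK_COLUMNS)
    df.to_csv(path, index=False)


def read_measurements(path) -> list[MeasurementRow]:
    """Read a wide measurement CSV (patient_id first column)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns.empty or df.columns[0] != "patient_id":
        raise CephError(
            f"{path}: first column must be 'patient_id',"
            f" got {list(df.columns[:1])}"
        )
    rows = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        values = {}
        for col, val in zip(df.columns[1:], rec[1:]):
            if pd.isna(val):
                continue
            try:
                values[col] = float(val)
            except (TypeError, ValueError):
                raise CephError(
                    f"{path}:{i}: column {col!r}: non-numeric value {val!r}"
                ) from None
        rows.append(MeasurementRow(patient_id=str(rec[0]), values=values))
    return rows


def write_measurements(rows: list[MeasurementRow], path) -> None:
    columns: list[str] = []
    for row in rows:
        for key in row.values:
            if key not in columns:
                columns.append(key)
    data = {
        "patient_id": [r.patient_id for r in rows],
        **{
            c: [
                repr(float(r.values[c])) if c in r.values else ""
                for r in rows
            ]
            for c in columns
        },
    }
    pd.DataFrame(data).to_csv(path, index=False)


def read_model_spec(path) -> tuple[tuple[BlockSpec, ...], InnerSpec]:
    """Read a user model file: JSON with ``blocks`` (lv -> {mvs, mode})
    and ``inner`` ({lvs, edges})."""
    with open(path) as fh:
        spec = json.load(fh)
    try:
        blocks = tuple(
            BlockSpec(lv, tuple(b["mvs"]), mode=b.get("mode", "reflective"))
            for lv, b in spec["blocks"].items()
        )
        inner = InnerSpec(
            lv_names=tuple(spec["inner"]["lvs"]),
            edges=tuple((a, b) for a, b in spec["inner"]["edges"]),
        )
    except (KeyError, TypeError) as exc:
        raise CephError(f"{path}: malformed model spec ({exc})") from exc
    return blocks, inner


def write_result(result: PLSPMResult, path) -> None:
    result.to_json(path)
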