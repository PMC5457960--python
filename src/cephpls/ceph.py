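"""Cephalometric measurement geometry.

Lateral-cephalogram landmarks are 2-D points in mm (Cartesian, y
increasing upward in input files).  Two reference directions define the
measurement frame: the Frankfort-horizontal (FH) direction through
Porion (Po) and Orbitale (Or), and its perpendicular through Sella (S),
the "S-perpendicular".  Each landmark L yields

* ``L^s`` — signed distance to the S-perpendicular line (component of
  L - S along the FH direction; anterior positive), and
* ``L^f`` — signed vertical coordinate (component of L - S along the
  S-perpendicular direction; inferior positive).

Both are measured from Sella: the package's vertical reference is the
line through S parallel to FH, which keeps horizontal and vertical
coordinates a single orthonormal frame and makes the landmark
synthesiser an exact inverse.  The occlusal vertical dimension (VD) is
the absolute difference of the first-molar mesial-contact verticals.

Variables are named ``{landmark}_{s|f}_{suffix}`` with suffix 0/1/2 for
the presurgical/postsurgical/posttreatment timepoints (T0/T1/T2) and
10/21/20 for the increments T1-T0, T2-T1, T2-T0 (VD drops the s/f
component: ``VD_0``, ``VD_10``, ...).  The model columns of the
surgery-first analysis are ``B_s_10, Me_s_10, A_s_1, Cp_f_1, VD_10`` and
the response ``B_s_20``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkRecord",
    "ReferenceFrame",
    "MeasurementRow",
    "CephError",
    "TIMEPOINTS",
    "MODEL_COLUMNS",
    "GNATHIC_LANDMARKS",
    "build_frame",
    "horiz_dist",
    "vert_dist",
    "occlusal_vd",
    "derive_measurements",
    "extract_mv_table",
]

TIMEPOINTS = ("T0", "T1", "T2")
_TP_SUFFIX = {"T0": "0", "T1": "1", "T2": "2"}

#: the manifest variables of the surgery-first PLS path model, plus the
#: reflective response (final B-point setback T0->T2)
MODEL_COLUMNS = ("B_s_10", "Me_s_10", "A_s_1", "Cp_f_1", "VD_10", "B_s_20")

#: landmarks usable as an "inferior" witness when orienting the vertical
#: axis (all lie well below the FH line in normal anatomy)
GNATHIC_LANDMARKS = ("Me", "B", "Pog", "Gn", "L1t", "L6mc")

_FRAME_LANDMARKS = ("Po", "Or", "S")


class CephError(ValueError):
    """Invalid landmark geometry or incomplete measurement input."""


@dataclass
class LandmarkRecord:
    """Digitised landmarks for one patient at one timepoint."""

    patient_id: str
    timepoint: str
    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise CephError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        pts = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (2,) or not np.isfinite(arr).all():
                raise CephError(
                    f"{self.patient_id}/{self.timepoint}: landmark {name!r}"
                    " must be a finite 2-D point"
                )
            pts[name] = arr
        self.points = pts

    def point(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise CephError(
                f"patient {self.patient_id!r}, timepoint {self.timepoint}:"
                f" missing landmark {name!r}"
            ) from None


@dataclass(frozen=True)
class ReferenceFrame:
    """Orthonormal FH / S-perpendicular frame anchored at Sella."""

    origin: np.ndarray
    fh_axis: np.ndarray
    sperp_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "fh_axis", "sperp_axis"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        if abs(np.linalg.norm(self.fh_axis) - 1.0) > 1e-9 or abs(
            np.linalg.norm(self.sperp_axis) - 1.0
        ) > 1e-9:
            raise CephError("frame axes must be unit vectors")
        if abs(float(self.fh_axis @ self.sperp_axis)) > 1e-9:
            raise CephError("frame axes must be orthogonal")


def build_frame(Po, Or, S, inferior_witness=None) -> ReferenceFrame:
    """Construct the measurement frame from Po, Or and Sella.

    ``fh_axis`` points Po -> Or (posterior to anterior).  ``sperp_axis``
    is the perpendicular, oriented toward ``inferior_witness`` when one
    is given (any gnathic landmark works); without a witness, inputs are
    assumed y-up and the axis points toward decreasing y.
    """
    Po = np.asarray(Po, dtype=float)
    Or = np.asarray(Or, dtype=float)
    S = np.asarray(S, dtype=float)
    d = Or - Po
    nrm = float(np.linalg.norm(d))
    if nrm < 1e-12:
        raise CephError("Po and Or coincide; the FH direction is undefined")
    fh = d / nrm
    sperp = np.array([fh[1], -fh[0]])  # fh rotated -90 deg: "down" for y-up input
    if inferior_witness is not None:
        w = np.asarray(inferior_witness, dtype=float)
        proj = float((w - S) @ sperp)
        if proj < 0:
            sperp = -sperp
    return ReferenceFrame(origin=S, fh_axis=fh, sperp_axis=sperp)


def horiz_dist(p, frame: ReferenceFrame) -> float:
    """Signed distance from the S-perpendicular line (anterior +)."""
    return float((np.asarray(p, dtype=float) - frame.origin) @ frame.fh_axis)


def vert_dist(p, frame: ReferenceFrame) -> float:
    """Signed distance along the S-perpendicular direction (inferior +)."""
    return float((np.asarray(p, dtype=float) - frame.origin) @ frame.sperp_axis)


def occlusal_vd(U6mc, L6mc, frame: ReferenceFrame) -> float:
    """Occlusal vertical dimension: |vertical(L6mc) - vertical(U6mc)|,
    i.e. the molar mesial-contact gap projected on the S-perp direction."""
    return abs(vert_dist(L6mc, frame) - vert_dist(U6mc, frame))


@dataclass
class MeasurementRow:
    """Derived measurement variables for one patient (wide format)."""

    patient_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values


def _frame_from_record(rec: LandmarkRecord) -> ReferenceFrame:
    witness = None
    for name in GNATHIC_LANDMARKS:
        if name in rec.points:
            witness = rec.points[name]
            break
    return build_frame(rec.point("Po"), rec.point("Or"), rec.point("S"), witness)


def derive_measurements(
    records: dict[str, LandmarkRecord] | list[LandmarkRecord],
    frame: ReferenceFrame | None = None,
) -> MeasurementRow:
    """Turn one patient's T0/T1/T2 landmark records into a MeasurementRow.

    The frame is built from the T0 record's Po/Or/S (records are assumed
    superimposed on the cranial base) unless one is supplied.  Every
    present landmark yields ``{L}_s_{t}`` and ``{L}_f_{t}``; the molar
    mesial contacts additionally yield ``VD_{t}``.  Increments ``_10``,
    ``_21`` and ``_20`` are exact differences of the timepoint values.
    """
    if isinstance(records, list):
        records = {r.timepoint: r for r in records}
    missing_tp = [tp for tp in TIMEPOINTS if tp not in records]
    if missing_tp:
        raise CephError(f"missing timepoints: {missing_tp}")
    pids = {r.patient_id for r in records.values()}
    if len(pids) != 1:
        raise CephError(f"records mix patients: {sorted(pids)}")
    (pid,) = pids
    if frame is None:
        frame = _frame_from_record(records["T0"])

    values: dict[str, float] = {}
    for tp in TIMEPOINTS:
        rec = records[tp]
        sfx = _TP_SUFFIX[tp]
        for name, p in rec.points.items():
            if name in _FRAME_LANDMARKS:
                continue
            values[f"{name}_s_{sfx}"] = horiz_dist(p, frame)
            values[f"{name}_f_{sfx}"] = vert_dist(p, frame)
        if "U6mc" in rec.points and "L6mc" in rec.points:
            values[f"VD_{sfx}"] = occlusal_vd(
                rec.points["U6mc"], rec.points["L6mc"], frame
            )

    bases = sorted({v.rsplit("_", 1)[0] for v in values})
    for base in bases:
        v0, v1, v2 = (values.get(f"{base}_{s}") for s in ("0", "1", "2"))
        if v0 is not None and v1 is not None:
            values[f"{base}_10"] = v1 - v0
        if v1 is not None and v2 is not None:
            values[f"{base}_21"] = v2 - v1
        if v0 is not None and v2 is not None:
            values[f"{base}_20"] = v2 - v0
    return MeasurementRow(patient_id=pid, values=values)


def extract_mv_table(
    rows: list[MeasurementRow],
    columns: tuple[str, ...] = MODEL_COLUMNS,
) -> pd.DataFrame:
    """Assemble the patients x MVs DataMatrix for the path model.

    Every requested column must be present in every row; the default is
    the six-variable roster of the surgery-first model (``Pog_f_10`` or
    any other derived name may be added via ``columns``).
    """
    if not rows:
        raise CephError("no measurement rows")
    data = {}
    index = []
    for row in rows:
        missing = [c for c in columns if c not in row.values]
        if missing:
            raise CephError(
                f"patient {row.patient_id!r}: missing variables {missing}"
            )
        index.append(row.patient_id)
        for c in columns:
            data.setdefault(c, []).append(float(row.values[c]))
    return pd.DataFrame(data, index=pd.Index(index, name="patient_id"),
                        columns=list(columns))
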