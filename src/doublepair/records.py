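"""Occupant-record I/O and validation.

The in-memory container for occupant-level crash data is a pandas
DataFrame with one row per occupant and the column contract below.  The
format on disk is header-labeled CSV (RFC 4180, UTF-8, "." decimals):

==================  =======================================================
column              values
==================  =======================================================
crash_id            opaque string
vehicle_id          opaque string, unique within crash
person_id           opaque string, unique within vehicle
crash_year          integer calendar year
vehicle_body        passenger_car | light_truck | other
rollover            0 | 1
n_vehicles_in_crash integer >= 1
impact_point        front | driver_side | passenger_side | rear | other |
                    unknown
seat                driver | front_right | rear_left | rear_center |
                    rear_right | other | unknown
sex                 female | male | unknown
age_years           integer in [0, 120], empty field when unknown
belted              belted | unbelted | unknown
airbag              deployed | not_deployed | unknown
died                0 | 1   (dead at scene or within 30 days)
==================  =======================================================

Unknown categorical values are the literal token ``unknown``; an unknown
age is an empty field (NaN in memory).  Native FARS numeric recoding is
out of scope: upstream tooling is expected to deliver this contract.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "OCCUPANT_COLUMNS",
    "ENUM_VALUES",
    "ValidationReport",
    "InvalidRecordsError",
    "read_occupants",
    "validate_occupants",
    "write_occupants",
    "write_estimates",
    "read_estimates",
]

OCCUPANT_COLUMNS = [
    "crash_id",
    "vehicle_id",
    "person_id",
    "crash_year",
    "vehicle_body",
    "rollover",
    "n_vehicles_in_crash",
    "impact_point",
    "seat",
    "sex",
    "age_years",
    "belted",
    "airbag",
    "died",
]

ENUM_VALUES = {
    "vehicle_body": ("passenger_car", "light_truck", "other"),
    "impact_point": ("front", "driver_side", "passenger_side", "rear",
                     "other", "unknown"),
    "seat": ("driver", "front_right", "rear_left", "rear_center",
             "rear_right", "other", "unknown"),
    "sex": ("female", "male", "unknown"),
    "belted": ("belted", "unbelted", "unknown"),
    "airbag": ("deployed", "not_deployed", "unknown"),
}

_BOOL_COLUMNS = ("rollover", "died")

AGE_MAX = 120


class InvalidRecordsError(ValueError):
    """Raised in strict mode when any row fails validation."""


@dataclasses.dataclass
class ValidationReport:
    """Summary of rows dropped during non-strict validation."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: dict[str, int] = dataclasses.field(default_factory=dict)

    def add(self, reason: str, n: int) -> None:
        if n:
            self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + int(n)


def _row_validity(frame: pd.DataFrame) -> tuple[pd.Series, dict[str, pd.Series]]:
    """Return (valid mask, per-reason invalid masks) for a raw frame."""
    reasons: dict[str, pd.Series] = {}
    for col, allowed in ENUM_VALUES.items():
        reasons[f"invalid_{col}"] = ~frame[col].isin(allowed)
    for col in _BOOL_COLUMNS:
        reasons[f"invalid_{col}"] = ~frame[col].isin([0, 1])
    age = pd.to_numeric(frame["age_years"], errors="coerce")
    # empty field (NaN) means unknown and is valid; known ages must be ints
    # in [0, AGE_MAX]
    known = frame["age_years"].notna() & (
        frame["age_years"].astype(str).str.strip() != ""
    )
    bad_age = known & (age.isna() | (age < 0) | (age > AGE_MAX) | (age % 1 != 0))
    reasons["invalid_age_years"] = bad_age
    year = pd.to_numeric(frame["crash_year"], errors="coerce")
    reasons["invalid_crash_year"] = year.isna() | (year % 1 != 0)
    nveh = pd.to_numeric(frame["n_vehicles_in_crash"], errors="coerce")
    reasons["invalid_n_vehicles_in_crash"] = nveh.isna() | (nveh < 1) | (nveh % 1 != 0)

    valid = pd.Series(True, index=frame.index)
    for mask in reasons.values():
        valid &= ~mask.fillna(True).astype(bool)
    return valid, reasons


def _finalize_types(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in ("crash_id", "vehicle_id", "person_id"):
        out[col] = out[col].astype(str)
    out["crash_year"] = out["crash_year"].astype(np.int64)
    out["n_vehicles_in_crash"] = out["n_vehicles_in_crash"].astype(np.int64)
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(np.int64).astype(bool)
    out["age_years"] = pd.to_numeric(out["age_years"], errors="coerce").astype(
        "Float64"
    )
    return out


def validate_occupants(
    frame: pd.DataFrame, strict: bool = False
) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate a raw occupant frame against the column contract.

    With ``strict=False`` invalid rows are dropped and tallied in the
    returned :class:`ValidationReport`; with ``strict=True`` any invalid
    row raises :class:`InvalidRecordsError`.
    """
    missing = [c for c in OCCUPANT_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidRecordsError(f"missing required columns: {missing}")

    report = ValidationReport(n_read=len(frame))
    if len(frame) == 0:
        empty = _finalize_types(frame.iloc[0:0][OCCUPANT_COLUMNS].assign())
        return empty, report

    valid, reasons = _row_validity(frame)
    if strict and not valid.all():
        bad = frame.index[~valid][:5].tolist()
        raise InvalidRecordsError(
            f"{(~valid).sum()} invalid rows (first indices: {bad})"
        )
    for reason, mask in reasons.items():
        report.add(reason, int(mask.fillna(True).astype(bool)[~valid].sum()))
    kept = _finalize_types(frame.loc[valid, OCCUPANT_COLUMNS])

    dup = kept.duplicated(subset=["crash_id", "vehicle_id", "person_id"])
    if dup.any():
        if strict:
            raise InvalidRecordsError(
                f"{int(dup.sum())} duplicate (crash_id, vehicle_id, person_id) keys"
            )
        report.add("duplicate_key", int(dup.sum()))
        kept = kept.loc[~dup]

    report.n_kept = len(kept)
    report.n_dropped = report.n_read - report.n_kept
    return kept.reset_index(drop=True), report


def read_occupants(
    path: Union[str, Path], strict: bool = False
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate an occupant CSV.

    Returns ``(records, report)``.  Missing file or missing required
    columns raise regardless of ``strict``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path,
        dtype={"crash_id": str, "vehicle_id": str, "person_id": str},
        keep_default_na=True,
    )
    if len(raw.columns) == 1 and raw.empty and raw.columns[0].count(","):
        # header-only file read as a single unsplit column never happens
        # with pandas; guard kept for clarity
        pass
    return validate_occupants(raw, strict=strict)


def write_occupants(path: Union[str, Path], records: pd.DataFrame) -> None:
    """Write occupant records to CSV under the documented contract."""
    out = records.copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out["age_years"] = out["age_years"].astype(object).where(
        out["age_years"].notna(), ""
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# estimate tables


def _round3(x: float) -> str:
    """Display rounding matching the tables' style: 3 dp, trailing zeros
    trimmed but at least one decimal (1.0, 0.95, 0.699)."""
    if x is None or not np.isfinite(x):
        return ""
    s = f"{x:.3f}".rstrip("0")
    if s.endswith("."):
        s += "0"
    return s


def _estimate_to_row(est) -> dict:
    row = dict(est.as_dict())
    for key in list(row):
        val = row[key]
        if isinstance(val, float):
            row[f"{key}_display"] = _round3(val)
    return row


def write_estimates(path: Union[str, Path], estimates: Sequence) -> None:
    """Write risk/pooled estimates as CSV (or JSON for .json paths).

    Numeric columns are serialized at full precision (17 significant
    digits survive a float round-trip); each also gets a display-rounded
    companion column at 3 decimals.
    """
    rows = [_estimate_to_row(e) for e in estimates]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2))
        return
    if rows:
        frame = pd.DataFrame(rows)
    else:
        frame = pd.DataFrame(columns=["stratum_label"])
    frame.to_csv(path, index=False, float_format="%.17g")


def read_estimates(path: Union[str, Path]) -> pd.DataFrame:
    """Read back an estimates table written by :func:`write_estimates`."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path, float_precision="round_trip")
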