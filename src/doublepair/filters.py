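"""Case selection and age binning.

Case selection is vehicle-level: a vehicle qualifies when it carries at
least ``min_occupants`` occupants and (by default) at least one occupant
who died, it did not roll over, and it passes the configured body-type,
year, impact-direction and crash-size filters.  All occupants of a
qualifying vehicle are retained together.

Subject occupants are binned into closed five-year age windows centered
on a nominal age (center +/- 2, so "25-year-olds" means ages 23-27);
control occupants use the conventional coarse bands 16-24, 25-34, 35-54
and 55+.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "CaseCriteria",
    "AgeBinning",
    "CONTROL_BANDS",
    "select_cases",
    "control_age_band",
    "control_age_band_series",
    "in_subject_bin",
]

# (label, low, high-inclusive); None = unbounded above
CONTROL_BANDS = (
    ("b16_24", 16, 24),
    ("b25_34", 25, 34),
    ("b35_54", 35, 54),
    ("b55_plus", 55, None),
)

CONTROL_BAND_LABELS = tuple(b[0] for b in CONTROL_BANDS)


@dataclasses.dataclass(frozen=True)
class CaseCriteria:
    """Vehicle-level selection rules for qualifying crash cases."""

    year_range: tuple[int, int] = (1975, 2020)
    vehicle_body: str = "any"          # passenger_car | light_truck | other | any
    min_occupants: int = 2
    require_vehicle_fatality: bool = True
    exclude_rollover: bool = True
    n_vehicles: str = "any"            # one | two | three_plus | any
    impact: str = "any"                # front | driver_side | passenger_side | any

    def __post_init__(self):
        lo, hi = self.year_range
        if lo > hi:
            raise ValueError(f"year_range lower bound {lo} exceeds upper {hi}")
        if self.min_occupants < 1:
            raise ValueError("min_occupants must be >= 1")
        if self.n_vehicles not in ("one", "two", "three_plus", "any"):
            raise ValueError(f"bad n_vehicles: {self.n_vehicles!r}")
        if self.impact not in ("front", "driver_side", "passenger_side", "any"):
            raise ValueError(f"bad impact: {self.impact!r}")


@dataclasses.dataclass(frozen=True)
class AgeBinning:
    """Closed subject-age window [center - halfwidth, center + halfwidth]."""

    center: int
    halfwidth: int = 2

    @property
    def low(self) -> int:
        return self.center - self.halfwidth

    @property
    def high(self) -> int:
        return self.center + self.halfwidth


def select_cases(records: pd.DataFrame, criteria: CaseCriteria) -> pd.DataFrame:
    """Retain occupants of vehicles satisfying all case criteria."""
    if len(records) == 0:
        return records.copy()

    df = records
    veh_key = ["crash_id", "vehicle_id"]
    grp = df.groupby(veh_key, sort=False)
    n_occ = grp["person_id"].transform("size")
    keep = n_occ >= criteria.min_occupants
    if criteria.require_vehicle_fatality:
        keep &= grp["died"].transform("any")
    if criteria.exclude_rollover:
        keep &= ~df["rollover"]
    lo, hi = criteria.year_range
    keep &= df["crash_year"].between(lo, hi)
    if criteria.vehicle_body != "any":
        keep &= df["vehicle_body"] == criteria.vehicle_body
    if criteria.impact != "any":
        keep &= df["impact_point"] == criteria.impact
    if criteria.n_vehicles == "one":
        keep &= df["n_vehicles_in_crash"] == 1
    elif criteria.n_vehicles == "two":
        keep &= df["n_vehicles_in_crash"] == 2
    elif criteria.n_vehicles == "three_plus":
        keep &= df["n_vehicles_in_crash"] >= 3
    # vehicle-level: a vehicle is kept iff every vehicle-level predicate
    # holds; the per-row predicates above are constant within a vehicle
    # (year, body, rollover, impact, n_vehicles are vehicle attributes),
    # so requiring all rows of the vehicle pass is equivalent and robust
    # to inconsistent inputs.
    veh_ok = keep.groupby([df[k] for k in veh_key], sort=False).transform("all")
    return df.loc[veh_ok].reset_index(drop=True)


def control_age_band(age_years: Union[int, float]) -> str:
    """Map a known age to its control band label, or ``out_of_range``."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        raise ValueError("control_age_band requires a known age")
    for label, low, high in CONTROL_BANDS:
        if age_years >= low and (high is None or age_years <= high):
            return label
    return "out_of_range"


def control_age_band_series(ages: pd.Series) -> pd.Series:
    """Vectorized :func:`control_age_band`; unknown ages map to NaN."""
    out = pd.Series("out_of_range", index=ages.index, dtype=object)
    a = ages.astype(float)
    for label, low, high in CONTROL_BANDS:
        mask = a >= low
        if high is not None:
            mask &= a <= high
        out[mask.fillna(False)] = label
    out[a.isna()] = np.nan
    return out


def in_subject_bin(age_years: Union[int, float], binning: AgeBinning) -> bool:
    """True iff the age lies in the closed subject window."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        raise ValueError("in_subject_bin requires a known age")
    return binning.low <= age_years <= binning.high
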