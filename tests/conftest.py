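"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-apply every selection/pairing predicate with
plain Python loops over individual rows, independent of the vectorized
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from doublepair.filters import AgeBinning, CaseCriteria, CONTROL_BANDS
from doublepair.pairs import StratumSpec


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a valid occupant frame from sparse row dicts."""
    defaults = dict(
        crash_id="c0", vehicle_id="v0", person_id=None, crash_year=2015,
        vehicle_body="passenger_car", rollover=False, n_vehicles_in_crash=2,
        impact_point="front", seat="driver", sex="male", age_years=30.0,
        belted="belted", airbag="deployed", died=False,
    )
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, **row)
        if rec["person_id"] is None:
            rec["person_id"] = f"p{i}"
        out.append(rec)
    df = pd.DataFrame(out, columns=list(defaults))
    df["age_years"] = df["age_years"].astype("Float64")
    return df


def random_records(rng: np.random.Generator, n_vehicles: int = 20,
                   unknown_frac: float = 0.1) -> pd.DataFrame:
    """Randomized multi-vehicle fixture exercising every enum value."""
    rows = []
    for v in range(n_vehicles):
        crash = f"c{v // 2}"
        n_occ = int(rng.integers(1, 5))
        seats = ["driver", "front_right", "rear_left", "rear_right"]
        for k in range(n_occ):
            age = float(rng.integers(10, 90))
            rows.append(dict(
                crash_id=crash,
                vehicle_id=f"v{v}",
                person_id=f"p{k}",
                crash_year=int(rng.integers(2005, 2021)),
                vehicle_body=str(rng.choice(
                    ["passenger_car", "light_truck", "other"])),
                rollover=bool(rng.random() < 0.2),
                n_vehicles_in_crash=int(rng.integers(1, 5)),
                impact_point=str(rng.choice(
                    ["front", "driver_side", "passenger_side", "rear",
                     "other", "unknown"])),
                seat=seats[k],
                sex=str(rng.choice(["female", "male", "unknown"],
                                   p=[0.45, 0.45, 0.1])),
                age_years=np.nan if rng.random() < unknown_frac else age,
                belted=str(rng.choice(["belted", "unbelted", "unknown"],
                                      p=[0.5, 0.4, 0.1])),
                airbag=str(rng.choice(["deployed", "not_deployed", "unknown"],
                                      p=[0.45, 0.35, 0.2])),
                died=bool(rng.random() < 0.4),
            ))
    df = pd.DataFrame(rows)
    df["age_years"] = df["age_years"].astype("Float64")
    return df


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_select_cases(records: pd.DataFrame,
                        criteria: CaseCriteria) -> pd.DataFrame:
    """Row-by-row reimplementation of vehicle-level case selection."""
    kept_idx = []
    for (_, _), grp in records.groupby(["crash_id", "vehicle_id"],
                                       sort=False):
        ok = len(grp) >= criteria.min_occupants
        if criteria.require_vehicle_fatality:
            ok = ok and any(bool(d) for d in grp["died"])
        for _, row in grp.iterrows():
            if criteria.exclude_rollover and row["rollover"]:
                ok = False
            lo, hi = criteria.year_range
            if not (lo <= row["crash_year"] <= hi):
                ok = False
            if criteria.vehicle_body != "any" \
                    and row["vehicle_body"] != criteria.vehicle_body:
                ok = False
            if criteria.impact != "any" \
                    and row["impact_point"] != criteria.impact:
                ok = False
            nv = row["n_vehicles_in_crash"]
            if criteria.n_vehicles == "one" and nv != 1:
                ok = False
            if criteria.n_vehicles == "two" and nv != 2:
                ok = False
            if criteria.n_vehicles == "three_plus" and nv < 3:
                ok = False
        if ok:
            kept_idx.extend(grp.index)
    return records.loc[sorted(kept_idx)].reset_index(drop=True)


def _oracle_band(age: float) -> str | None:
    if pd.isna(age):
        return None
    for label, low, high in CONTROL_BANDS:
        if age >= low and (high is None or age <= high):
            return label
    return "out_of_range"


def oracle_build_pairs(records: pd.DataFrame,
                       spec: StratumSpec) -> set[tuple]:
    """Exhaustive double loop over occupants applying every predicate."""
    pairs = set()
    for (crash, veh), grp in records.groupby(["crash_id", "vehicle_id"],
                                             sort=False):
        rows = grp.to_dict("records")
        for s in rows:
            if s["seat"] != spec.subject_seat:
                continue
            if s["belted"] != spec.subject_belted:
                continue
            if s["sex"] not in ("female", "male"):
                continue
            a = s["age_years"]
            if pd.isna(a) or not (spec.subject_age.low <= a
                                  <= spec.subject_age.high):
                continue
            for c in rows:
                if c is s or c["person_id"] == s["person_id"]:
                    continue
                if c["seat"] != spec.control_seat:
                    continue
                if c["belted"] != spec.control_belted:
                    continue
                if c["sex"] != spec.control_sex:
                    continue
                if _oracle_band(c["age_years"]) != spec.control_age_band:
                    continue
                if spec.airbag_mode != "any":
                    sa, ca = s["airbag"], c["airbag"]
                    if sa == "unknown" or ca == "unknown" or sa != ca:
                        continue
                    if spec.airbag_mode == "subject_deployed" \
                            and sa != "deployed":
                        continue
                    if spec.airbag_mode == "subject_not_deployed" \
                            and sa != "not_deployed":
                        continue
                pairs.add((crash, veh, s["person_id"], c["person_id"]))
    return pairs


def oracle_tabulate(pairs_df: pd.DataFrame) -> dict[str, int]:
    """Independent tally of the six stratified counters."""
    tally = dict(a_both=0, b_subj_only=0, c_ctrl_only=0,
                 e_both=0, f_subj_only=0, g_ctrl_only=0)
    for _, p in pairs_df.iterrows():
        fem = p["subject_sex"] == "female"
        sd, cd = bool(p["subject_died"]), bool(p["control_died"])
        if not sd and not cd:
            continue
        if fem and sd and cd:
            tally["a_both"] += 1
        elif fem and sd:
            tally["b_subj_only"] += 1
        elif fem:
            tally["c_ctrl_only"] += 1
        elif sd and cd:
            tally["e_both"] += 1
        elif sd:
            tally["f_subj_only"] += 1
        else:
            tally["g_ctrl_only"] += 1
    return tally


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
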