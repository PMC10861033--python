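"""Subject-control pair enumeration and stratified count tabulation.

Within each selected vehicle, every occupant in the subject seat whose
age falls in the subject window and whose belt use matches is paired
with every co-occupant in the control seat matching the control cohort
(sex, coarse age band, belt use).  Airbag handling follows the matched
convention: under ``matched`` mode both occupants' deployment status
must be known and equal; ``subject_deployed`` / ``subject_not_deployed``
additionally fix the shared state.  Subjects of unknown sex are
excluded; pairing is strictly within-vehicle.

The six stratified fatality counts split each subject or control death
by whether the paired occupant also died, which is what makes a proper
variance for ln R possible:

    A  female subject killed, control also killed
    B  female subject killed, control not killed
    C  control killed, female subject not killed
    E  male subject killed, control also killed
    F  male subject killed, control not killed
    G  control killed, male subject not killed

The classical aggregate counts are recovered as A_orig = A + B,
B_orig = A + C, C_orig = E + F, D_orig = E + G.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .filters import AgeBinning, CaseCriteria, control_age_band_series

__all__ = ["StratumSpec", "PairCounts", "build_pairs", "tabulate"]

AIRBAG_MODES = ("matched", "subject_deployed", "subject_not_deployed", "any")


@dataclasses.dataclass(frozen=True)
class StratumSpec:
    """Full definition of one analysis stratum."""

    subject_seat: str
    subject_belted: str
    subject_age: AgeBinning
    control_seat: str
    control_sex: str
    control_age_band: str
    control_belted: str
    airbag_mode: str = "matched"
    case_criteria: Optional[CaseCriteria] = None

    def __post_init__(self):
        if self.subject_seat == self.control_seat:
            raise ValueError("subject_seat and control_seat must differ")
        if self.airbag_mode not in AIRBAG_MODES:
            raise ValueError(f"bad airbag_mode: {self.airbag_mode!r}")

    @property
    def label(self) -> str:
        return (
            f"subject={self.subject_seat}/{self.subject_belted}/"
            f"{self.subject_age.center}"
            f"|control={self.control_sex}/{self.control_age_band}/"
            f"{self.control_seat}/{self.control_belted}"
            f"|airbag={self.airbag_mode}"
        )


@dataclasses.dataclass(frozen=True)
class PairCounts:
    """Stratified fatality counts for one stratum."""

    a_both: int = 0
    b_subj_only: int = 0
    c_ctrl_only: int = 0
    e_both: int = 0
    f_subj_only: int = 0
    g_ctrl_only: int = 0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"negative count {f.name}")

    # classical aggregate counts
    @property
    def A_orig(self) -> int:
        return self.a_both + self.b_subj_only

    @property
    def B_orig(self) -> int:
        return self.a_both + self.c_ctrl_only

    @property
    def C_orig(self) -> int:
        return self.e_both + self.f_subj_only

    @property
    def D_orig(self) -> int:
        return self.e_both + self.g_ctrl_only

    @property
    def n_fatalities(self) -> int:
        """Total deaths among paired occupants (a death shared by both
        members of a pair counts twice, once per occupant)."""
        return (
            2 * self.a_both + self.b_subj_only + self.c_ctrl_only
            + 2 * self.e_both + self.f_subj_only + self.g_ctrl_only
        )


PAIR_COLUMNS = [
    "crash_id", "vehicle_id", "subject_person_id", "control_person_id",
    "subject_sex", "subject_died", "control_died",
]


def build_pairs(records: pd.DataFrame, spec: StratumSpec) -> pd.DataFrame:
    """Enumerate (subject, control) pairs for one stratum.

    ``records`` must already have passed :func:`~doublepair.filters.
    select_cases` for ``spec.case_criteria``.  Pairs where neither
    occupant died are retained (they matter for resampling) but
    contribute nothing to the counts.
    """
    df = records
    empty = pd.DataFrame(columns=PAIR_COLUMNS)
    if len(df) == 0:
        return empty

    age = df["age_years"].astype(float)
    subj = (
        (df["seat"] == spec.subject_seat)
        & (df["belted"] == spec.subject_belted)
        & df["sex"].isin(["female", "male"])
        & age.between(spec.subject_age.low, spec.subject_age.high)
    )
    band = control_age_band_series(df["age_years"])
    ctrl = (
        (df["seat"] == spec.control_seat)
        & (df["belted"] == spec.control_belted)
        & (df["sex"] == spec.control_sex)
        & (band == spec.control_age_band)
    )

    cols = ["crash_id", "vehicle_id", "person_id", "sex", "died", "airbag"]
    s = df.loc[subj, cols].rename(
        columns={"person_id": "subject_person_id", "sex": "subject_sex",
                 "died": "subject_died", "airbag": "subject_airbag"}
    )
    c = df.loc[ctrl, cols].rename(
        columns={"person_id": "control_person_id", "sex": "control_sex",
                 "died": "control_died", "airbag": "control_airbag"}
    )
    if len(s) == 0 or len(c) == 0:
        return empty
    pairs = s.merge(c, on=["crash_id", "vehicle_id"], how="inner")
    pairs = pairs[pairs["subject_person_id"] != pairs["control_person_id"]]

    if spec.airbag_mode != "any":
        ok = (
            pairs["subject_airbag"].isin(["deployed", "not_deployed"])
            & (pairs["subject_airbag"] == pairs["control_airbag"])
        )
        if spec.airbag_mode == "subject_deployed":
            ok &= pairs["subject_airbag"] == "deployed"
        elif spec.airbag_mode == "subject_not_deployed":
            ok &= pairs["subject_airbag"] == "not_deployed"
        pairs = pairs[ok]

    return pairs[PAIR_COLUMNS].reset_index(drop=True)


def tabulate(pairs: pd.DataFrame) -> PairCounts:
    """Tally the six stratified fatality counts over a pair table.

    Each pair increments exactly one counter according to the subject's
    sex and the (subject died, control died) outcome; both-survived
    pairs increment nothing.
    """
    if len(pairs) == 0:
        return PairCounts()
    if not pairs["subject_sex"].isin(["female", "male"]).all():
        raise ValueError("pairs with unknown subject sex cannot be tabulated")
    fem = (pairs["subject_sex"] == "female").to_numpy()
    sd = pairs["subject_died"].to_numpy(dtype=bool)
    cd = pairs["control_died"].to_numpy(dtype=bool)
    return PairCounts(
        a_both=int((fem & sd & cd).sum()),
        b_subj_only=int((fem & sd & ~cd).sum()),
        c_ctrl_only=int((fem & ~sd & cd).sum()),
        e_both=int((~fem & sd & cd).sum()),
        f_subj_only=int((~fem & sd & ~cd).sum()),
        g_ctrl_only=int((~fem & ~sd & cd).sum()),
    )
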