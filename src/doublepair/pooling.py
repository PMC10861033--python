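"""Weighted pooling of stratum risk ratios, bootstrap CIs, age sweeps.

Stratum log risk ratios are pooled with inverse-variance weights,

    R_bar = exp( sum(ln R_i * w_i) / sum(w_i) ),    w_i = 1 / var_i,
    var_bar = 1 / sum(w_i),

where var_i is the count-based variance of ln R_i.  Because the pooled
variance is itself the reciprocal of the summed weights, this pooling is
associative: pooling control cohorts within each subject stratum and
then pooling the subject-stratum summaries gives exactly the same
number as pooling all strata at once.  Both views are exposed — the
two-level form mirrors how per-subject summary tables are built.

Confidence intervals are percentile bootstrap: vehicles (the pairing
unit) are resampled with replacement from the case-selected dataset,
every stratum is re-tabulated and re-pooled per replicate, and the CI
is the middle 95% of the replicate R_bar distribution.  Replicates on
which no stratum is usable are redrawn up to a bounded budget.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .filters import AgeBinning, CaseCriteria, CONTROL_BAND_LABELS, select_cases
from .pairs import PairCounts, StratumSpec, build_pairs, tabulate
from .stats import RiskEstimate, UndefinedRatioError, estimate_stratum

__all__ = [
    "PooledEstimate",
    "ControlCohort",
    "SubjectStratum",
    "pooled_R",
    "pool_estimates",
    "bootstrap_ci",
    "age_sweep",
    "default_control_cohorts",
    "default_subject_strata",
    "build_stratum_specs",
]

_QUANTILES = (0.01, 0.025, 0.25, 0.5, 0.75, 0.975, 0.99)


@dataclasses.dataclass(frozen=True)
class PooledEstimate:
    """Inverse-variance weighted pooled relative risk with bootstrap CI."""

    R_bar: float
    var_bar: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_strata: int = 0
    n_dropped: int = 0
    n_boot: int = 0
    seed: Optional[int] = None
    n_redrawn: int = 0
    n_fatalities: int = 0
    stratum_label: str = "pooled"
    replicate_summary: dict = dataclasses.field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "stratum_label": self.stratum_label,
            "R_bar": self.R_bar,
            "var_bar": self.var_bar,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_strata": self.n_strata,
            "n_dropped": self.n_dropped,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
            "n_fatalities": self.n_fatalities,
        }
        for q, v in self.replicate_summary.items():
            d[f"boot_q{q}"] = v
        return d


@dataclasses.dataclass(frozen=True)
class ControlCohort:
    """One control cell: sex x coarse age band (+ optional seat/belt)."""

    sex: str
    age_band: str
    seat: Optional[str] = None     # None: seat paired opposite the subject
    belted: Optional[str] = None   # None: same belt use as the subject


@dataclasses.dataclass(frozen=True)
class SubjectStratum:
    """One subject cell: seat x belt use x airbag condition."""

    seat: str
    belted: str
    airbag_mode: str = "matched"


def default_control_cohorts() -> list[ControlCohort]:
    """The eight conventional control cohorts (sex x four age bands)."""
    return [ControlCohort(sex=s, age_band=b)
            for s in ("male", "female") for b in CONTROL_BAND_LABELS]


def default_subject_strata() -> list[SubjectStratum]:
    """Front-seat subject strata: seat x belt x airbag state (matched)."""
    return [
        SubjectStratum(seat=seat, belted=belt, airbag_mode=mode)
        for seat in ("driver", "front_right")
        for belt in ("belted", "unbelted")
        for mode in ("subject_deployed", "subject_not_deployed")
    ]


def _opposite_front(seat: str) -> str:
    return {"driver": "front_right", "front_right": "driver"}.get(seat, "driver")


def build_stratum_specs(
    age: AgeBinning,
    subjects: Optional[Sequence[SubjectStratum]] = None,
    controls: Optional[Sequence[ControlCohort]] = None,
    case_criteria: Optional[CaseCriteria] = None,
) -> list[StratumSpec]:
    """Expand subject strata x control cohorts into concrete specs."""
    subjects = list(subjects) if subjects is not None else default_subject_strata()
    controls = list(controls) if controls is not None else default_control_cohorts()
    specs = []
    for sub in subjects:
        for ctl in controls:
            specs.append(StratumSpec(
                subject_seat=sub.seat,
                subject_belted=sub.belted,
                subject_age=age,
                control_seat=ctl.seat or _opposite_front(sub.seat),
                control_sex=ctl.sex,
                control_age_band=ctl.age_band,
                control_belted=ctl.belted or sub.belted,
                airbag_mode=sub.airbag_mode,
                case_criteria=case_criteria,
            ))
    return specs


# ---------------------------------------------------------------------------
# pooling


def _pool_arrays(
    counts: np.ndarray, weight_mode: str = "variance"
) -> tuple[float, float, int, int]:
    """Pool a (k, 6) array of stratified counts.

    Returns (R_bar, var_bar, n_used, n_dropped); (nan, nan, 0, k) when no
    stratum is usable.
    """
    a, b, c, e, f, g = (counts[:, i].astype(float) for i in range(6))
    A, B, C, D = a + b, a + c, e + f, e + g
    with np.errstate(divide="ignore", invalid="ignore"):
        den = A * B * C * D
        num = (a * (a + b + c) + b * c) * (f + g) \
            + (e * (e + f + g) + f * g) * (b + c)
        var = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        lnR = np.log(A / B) - np.log(C / D)
    k = counts.shape[0]
    finite = np.isfinite(lnR) & np.isfinite(var)
    usable = finite & (var > 0)
    if not usable.any():
        # degenerate fallback: strata with no discordant pairs have zero
        # variance; if they are all there is, pool them equally weighted
        zero = finite & (var == 0)
        if zero.any():
            return float(np.exp(lnR[zero].mean())), 0.0, int(zero.sum()), \
                int(k - zero.sum())
        return float("nan"), float("nan"), 0, k
    var_u = var[usable]
    w = 1.0 / var_u if weight_mode == "variance" else 1.0 / var_u**2
    sw = w.sum()
    lnR_bar = float((lnR[usable] * w).sum() / sw)
    var_bar = float(1.0 / sw) if weight_mode == "variance" else float(
        (w**2 * var_u).sum() / sw**2
    )
    return float(np.exp(lnR_bar)), var_bar, int(usable.sum()), int(k - usable.sum())


def _counts_matrix(estimates: Iterable[RiskEstimate]) -> np.ndarray:
    rows = []
    for est in estimates:
        c = est.counts
        rows.append([c.a_both, c.b_subj_only, c.c_ctrl_only,
                     c.e_both, c.f_subj_only, c.g_ctrl_only])
    return np.asarray(rows, dtype=float).reshape(-1, 6)


def pooled_R(
    estimates: Sequence[RiskEstimate], weight_mode: str = "variance"
) -> tuple[float, float]:
    """Inverse-variance weighted pooled (R_bar, var_bar).

    Strata with undefined or non-positive R or variance are skipped with
    a warning; an empty usable set raises :class:`UndefinedRatioError`.
    """
    lnRs, vars_, zero_lnRs = [], [], []
    n_dropped = 0
    for est in estimates:
        if (np.isfinite(est.R) and est.R > 0
                and np.isfinite(est.var_logR) and est.var_logR > 0):
            lnRs.append(np.log(est.R))
            vars_.append(est.var_logR)
        elif (np.isfinite(est.R) and est.R > 0 and est.var_logR == 0):
            zero_lnRs.append(np.log(est.R))
        else:
            n_dropped += 1
    if not lnRs:
        if zero_lnRs:
            # all strata degenerate (no discordant pairs): equal weights
            return float(np.exp(np.mean(zero_lnRs))), 0.0
        raise UndefinedRatioError(["all_strata"])
    n_dropped += len(zero_lnRs)
    if n_dropped:
        warnings.warn(f"pooled_R dropped {n_dropped} undefined strata",
                      stacklevel=2)
    lnRs = np.asarray(lnRs)
    v = np.asarray(vars_)
    w = 1.0 / v if weight_mode == "variance" else 1.0 / v**2
    sw = w.sum()
    var_bar = float(1.0 / sw) if weight_mode == "variance" else float(
        (w**2 * v).sum() / sw**2
    )
    return float(np.exp((lnRs * w).sum() / sw)), var_bar


def pool_estimates(
    estimates: Sequence[RiskEstimate],
    weight_mode: str = "variance",
    stratum_label: str = "pooled",
) -> PooledEstimate:
    """Pool estimates into a :class:`PooledEstimate` (no bootstrap CI)."""
    pos = [e for e in estimates
           if np.isfinite(e.R) and e.R > 0
           and np.isfinite(e.var_logR) and e.var_logR > 0]
    zero = [e for e in estimates
            if np.isfinite(e.R) and e.R > 0 and e.var_logR == 0]
    usable = pos if pos else zero
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R_bar, var_bar = pooled_R(estimates, weight_mode=weight_mode)
    return PooledEstimate(
        R_bar=R_bar, var_bar=var_bar,
        n_strata=len(usable), n_dropped=len(estimates) - len(usable),
        n_fatalities=sum(e.n_fatalities for e in usable),
        stratum_label=stratum_label,
    )


# ---------------------------------------------------------------------------
# bootstrap engine


class _StratumTables:
    """Precomputed pair tables enabling fast per-replicate re-tabulation.

    Every pair is reduced to (vehicle code, outcome class); a bootstrap
    replicate is then a single weighted bincount with the resampled
    vehicle multiplicities as weights.
    """

    CLS = {("female", True, True): 0, ("female", True, False): 1,
           ("female", False, True): 2, ("male", True, True): 3,
           ("male", True, False): 4, ("male", False, True): 5}

    def __init__(self, records: pd.DataFrame, specs: Sequence[StratumSpec]):
        self.specs = list(specs)
        filtered: dict[Optional[CaseCriteria], pd.DataFrame] = {}
        for spec in self.specs:
            crit = spec.case_criteria
            if crit not in filtered:
                filtered[crit] = (records if crit is None
                                  else select_cases(records, crit))
        veh_keys = pd.concat(
            [df[["crash_id", "vehicle_id"]] for df in filtered.values()],
            ignore_index=True,
        ).drop_duplicates()
        self.n_vehicles = len(veh_keys)
        key_codes = {
            (c, v): i
            for i, (c, v) in enumerate(
                zip(veh_keys["crash_id"], veh_keys["vehicle_id"])
            )
        }

        veh_all, slot_all = [], []
        self.full_counts = np.zeros((len(self.specs), 6), dtype=np.int64)
        for k, spec in enumerate(self.specs):
            pairs = build_pairs(filtered[spec.case_criteria], spec)
            if len(pairs) == 0:
                continue
            fem = pairs["subject_sex"].to_numpy()
            sd = pairs["subject_died"].to_numpy(dtype=bool)
            cd = pairs["control_died"].to_numpy(dtype=bool)
            cls = np.full(len(pairs), -1, dtype=np.int64)
            for (sex, s_died, c_died), code in self.CLS.items():
                cls[(fem == sex) & (sd == s_died) & (cd == c_died)] = code
            keep = cls >= 0      # both-survived pairs never change counts
            if not keep.any():
                continue
            codes = np.fromiter(
                (key_codes[(c, v)] for c, v in zip(
                    pairs.loc[keep, "crash_id"], pairs.loc[keep, "vehicle_id"])),
                dtype=np.int64, count=int(keep.sum()),
            )
            slots = 6 * k + cls[keep]
            veh_all.append(codes)
            slot_all.append(slots)
            self.full_counts[k] = np.bincount(cls[keep], minlength=6)

        if veh_all:
            self.pair_veh = np.concatenate(veh_all)
            self.pair_slot = np.concatenate(slot_all)
        else:
            self.pair_veh = np.empty(0, dtype=np.int64)
            self.pair_slot = np.empty(0, dtype=np.int64)
        self.n_slots = 6 * len(self.specs)

    def replicate_counts(self, mult: np.ndarray) -> np.ndarray:
        """(k, 6) counts under vehicle multiplicities ``mult``."""
        flat = np.bincount(self.pair_slot, weights=mult[self.pair_veh],
                           minlength=self.n_slots)
        return flat.reshape(len(self.specs), 6)

    def full_estimates(self) -> list[RiskEstimate]:
        out = []
        for spec, row in zip(self.specs, self.full_counts):
            counts = PairCounts(*(int(x) for x in row))
            try:
                out.append(estimate_stratum(counts, stratum_label=spec.label))
            except UndefinedRatioError:
                out.append(RiskEstimate(
                    stratum_label=spec.label, r1=float("nan"),
                    r2=float("nan"), R=float("nan"), var_logR=float("nan"),
                    counts=counts, n_fatalities=counts.n_fatalities,
                ))
        return out


def bootstrap_ci(
    records: pd.DataFrame,
    specs: Sequence[StratumSpec],
    n_boot: int = 5000,
    seed: int = 0,
    weight_mode: str = "variance",
    resample: str = "vehicles",
    max_redraw_factor: int = 10,
) -> PooledEstimate:
    """Pooled estimate with a percentile bootstrap 95% CI.

    Vehicles are resampled with replacement from the case-selected
    dataset (``resample="strata"`` instead resamples the usable stratum
    summaries); all strata are re-tabulated and re-pooled per replicate.
    Deterministic given ``seed``.
    """
    tables = _StratumTables(records, specs)
    point = _pool_arrays(tables.full_counts, weight_mode=weight_mode)
    R_bar, var_bar, n_used, n_dropped = point
    if n_used == 0:
        raise UndefinedRatioError(["all_strata"])

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot, dtype=float)
    n_redrawn = 0
    budget = max_redraw_factor * n_boot
    V = tables.n_vehicles

    if resample == "strata":
        ests = tables.full_estimates()
        lnR = np.array([np.log(e.R) for e in ests])
        var = np.array([e.var_logR for e in ests])
        ok = np.isfinite(lnR) & np.isfinite(var) & (var > 0)
        lnR, var = lnR[ok], var[ok]
        k = len(lnR)
        for i in range(n_boot):
            idx = rng.integers(0, k, size=k)
            w = 1.0 / var[idx] if weight_mode == "variance" else 1.0 / var[idx]**2
            reps[i] = np.exp((lnR[idx] * w).sum() / w.sum())
    elif resample == "vehicles":
        i = 0
        draws = 0
        while i < n_boot:
            if draws >= budget:
                raise RuntimeError(
                    f"bootstrap redraw budget exhausted after {draws} draws"
                )
            draws += 1
            mult = np.bincount(rng.integers(0, V, size=V), minlength=V
                               ).astype(float)
            r, _, used, _ = _pool_arrays(
                tables.replicate_counts(mult), weight_mode=weight_mode
            )
            if used == 0 or not np.isfinite(r):
                n_redrawn += 1
                continue
            reps[i] = r
            i += 1
    else:
        raise ValueError(f"bad resample mode: {resample!r}")

    lo, hi = np.percentile(reps, [2.5, 97.5])
    summary = {str(q): float(np.quantile(reps, q)) for q in _QUANTILES}
    full = tables.full_estimates()
    pos = [e for e in full
           if np.isfinite(e.R) and e.R > 0
           and np.isfinite(e.var_logR) and e.var_logR > 0]
    zero = [e for e in full
            if np.isfinite(e.R) and e.R > 0 and e.var_logR == 0]
    n_fatal = sum(e.n_fatalities for e in (pos if pos else zero))
    return PooledEstimate(
        R_bar=R_bar, var_bar=var_bar, ci_low=float(lo), ci_high=float(hi),
        n_strata=n_used, n_dropped=n_dropped, n_boot=n_boot, seed=seed,
        n_redrawn=n_redrawn, n_fatalities=n_fatal,
        replicate_summary=summary,
    )


def age_sweep(
    records: pd.DataFrame,
    centers: Sequence[int],
    subjects: Optional[Sequence[SubjectStratum]] = None,
    controls: Optional[Sequence[ControlCohort]] = None,
    case_criteria: Optional[CaseCriteria] = None,
    halfwidth: int = 2,
    n_boot: int = 5000,
    seed: int = 0,
    weight_mode: str = "variance",
) -> pd.DataFrame:
    """Pooled relative risk per subject age center.

    For each center, control cohorts are pooled within each subject
    stratum and the subject-stratum summaries are pooled in turn (the
    two stages collapse to one flat inverse-variance pool).  Centers
    with no usable stratum yield a flagged empty row.
    """
    if not centers:
        raise ValueError("centers must be nonempty")
    base = records if case_criteria is None else select_cases(records, case_criteria)
    rows = []
    for j, center in enumerate(centers):
        specs = build_stratum_specs(
            AgeBinning(center=center, halfwidth=halfwidth),
            subjects=subjects, controls=controls, case_criteria=None,
        )
        row = {"age_center": center}
        try:
            est = bootstrap_ci(base, specs, n_boot=n_boot,
                               seed=seed + j, weight_mode=weight_mode)
        except (UndefinedRatioError, RuntimeError):
            row.update(R_bar=np.nan, var_bar=np.nan, ci_low=np.nan,
                       ci_high=np.nan, n_strata=0, n_dropped=len(specs),
                       n_fatalities=0, usable=False)
        else:
            row.update(R_bar=est.R_bar, var_bar=est.var_bar,
                       ci_low=est.ci_low, ci_high=est.ci_high,
                       n_strata=est.n_strata, n_dropped=est.n_dropped,
                       n_fatalities=est.n_fatalities, usable=True)
        rows.append(row)
    return pd.DataFrame(rows)
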