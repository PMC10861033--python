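"""Inverse-variance pooling, bootstrap CIs, and the age sweep."""

import numpy as np
import pandas as pd
import pytest

import doublepair as dp
from doublepair.filters import AgeBinning, CaseCriteria
from doublepair.pairs import PairCounts
from doublepair.pooling import _pool_arrays, build_stratum_specs
from doublepair.stats import RiskEstimate, UndefinedRatioError, \
    estimate_stratum


def make_estimate(R, var, label="s"):
    return RiskEstimate(stratum_label=label, r1=R, r2=1.0, R=R,
                        var_logR=var, counts=None, n_fatalities=10)


def test_single_stratum_pooling_is_identity():
    est = make_estimate(0.699, 0.137)
    R_bar, var_bar = dp.pooled_R([est])
    assert R_bar == pytest.approx(0.699, rel=1e-12)
    assert var_bar == pytest.approx(0.137, rel=1e-12)


def test_reciprocal_pair_with_equal_weights_pools_to_one():
    ests = [make_estimate(2.0, 0.3), make_estimate(0.5, 0.3)]
    R_bar, _ = dp.pooled_R(ests)
    assert R_bar == pytest.approx(1.0, rel=1e-12)


def test_pooling_matches_direct_summation_oracle(rng):
    ests = [make_estimate(float(np.exp(rng.normal(0, 0.4))),
                          float(rng.uniform(0.01, 1.0)), f"s{i}")
            for i in range(10)]
    w = np.array([1 / e.var_logR for e in ests])
    lnR = np.array([np.log(e.R) for e in ests])
    expected_R = np.exp((lnR * w).sum() / w.sum())
    expected_var = 1.0 / w.sum()
    R_bar, var_bar = dp.pooled_R(ests)
    assert R_bar == pytest.approx(expected_R, rel=1e-12)
    assert var_bar == pytest.approx(expected_var, rel=1e-12)


def test_pooling_order_invariant(rng):
    ests = [make_estimate(float(np.exp(rng.normal(0, 0.4))),
                          float(rng.uniform(0.01, 1.0))) for _ in range(8)]
    a = dp.pooled_R(ests)
    b = dp.pooled_R(list(reversed(ests)))
    assert a == pytest.approx(b, rel=1e-14)


def test_pooling_of_identical_strata_returns_common_R():
    ests = [make_estimate(1.31, 0.2) for _ in range(7)]
    R_bar, var_bar = dp.pooled_R(ests)
    assert R_bar == pytest.approx(1.31, rel=1e-12)
    assert var_bar == pytest.approx(0.2 / 7, rel=1e-12)


def test_undefined_strata_skipped_with_warning():
    ests = [make_estimate(1.2, 0.1), make_estimate(float("nan"), 0.1),
            make_estimate(1.2, float("inf"))]
    with pytest.warns(UserWarning, match="dropped 2"):
        R_bar, _ = dp.pooled_R(ests)
    assert R_bar == pytest.approx(1.2, rel=1e-12)


def test_empty_usable_set_raises():
    with pytest.raises(UndefinedRatioError):
        dp.pooled_R([make_estimate(float("nan"), 0.1)])


def test_inverse_square_weight_mode_changes_weighting():
    ests = [make_estimate(2.0, 0.1), make_estimate(0.5, 0.4)]
    r_var, _ = dp.pooled_R(ests, weight_mode="variance")
    r_sq, _ = dp.pooled_R(ests, weight_mode="inverse_sq")
    # the low-variance stratum dominates more strongly under 1/var^2
    assert r_sq > r_var


def test_two_level_pooling_collapses_to_flat_pool(rng):
    """Pooling control cohorts within subject strata and then pooling
    the summaries equals one flat inverse-variance pool."""
    groups = []
    for _ in range(4):
        groups.append([make_estimate(float(np.exp(rng.normal(0, 0.3))),
                                     float(rng.uniform(0.05, 0.5)))
                       for _ in range(5)])
    level1 = []
    for g in groups:
        R_bar, var_bar = dp.pooled_R(g)
        level1.append(make_estimate(R_bar, var_bar))
    two_level_R, two_level_var = dp.pooled_R(level1)
    flat_R, flat_var = dp.pooled_R([e for g in groups for e in g])
    assert two_level_R == pytest.approx(flat_R, rel=1e-12)
    assert two_level_var == pytest.approx(flat_var, rel=1e-12)


def test_pool_arrays_agrees_with_estimate_path(rng):
    counts = rng.integers(0, 60, size=(30, 6))
    ests = []
    for row in counts:
        try:
            ests.append(estimate_stratum(PairCounts(*(int(x) for x in row))))
        except UndefinedRatioError:
            pass
    usable = [e for e in ests if e.R > 0 and e.var_logR > 0]
    R_arr, var_arr, n_used, _ = _pool_arrays(counts.astype(float))
    R_ref, var_ref = dp.pooled_R(usable)
    assert n_used == len(usable)
    assert R_arr == pytest.approx(R_ref, rel=1e-12)
    assert var_arr == pytest.approx(var_ref, rel=1e-12)


# ---------------------------------------------------------------------------
# bootstrap


@pytest.fixture(scope="module")
def small_dataset():
    cfg = dp.SyntheticConfig(n_crashes=4000, seed=5, true_R=1.2)
    records = dp.generate(cfg)
    return dp.select_cases(records, CaseCriteria(vehicle_body="passenger_car"))


@pytest.fixture(scope="module")
def specs_25():
    return build_stratum_specs(AgeBinning(25))


def test_bootstrap_deterministic_given_seed(small_dataset, specs_25):
    a = dp.bootstrap_ci(small_dataset, specs_25, n_boot=100, seed=42)
    b = dp.bootstrap_ci(small_dataset, specs_25, n_boot=100, seed=42)
    assert (a.ci_low, a.ci_high, a.R_bar) == (b.ci_low, b.ci_high, b.R_bar)
    c = dp.bootstrap_ci(small_dataset, specs_25, n_boot=100, seed=43)
    assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)


def test_bootstrap_ci_ordered_and_brackets_point(small_dataset, specs_25):
    est = dp.bootstrap_ci(small_dataset, specs_25, n_boot=200, seed=1)
    assert est.ci_low <= est.ci_high
    assert est.n_strata >= 1
    assert est.n_boot == 200
    # percentile CI of a well-behaved replicate distribution brackets R_bar
    assert est.ci_low <= est.R_bar <= est.ci_high


def test_degenerate_replicates_give_point_ci():
    """Data where every stratum is perfectly balanced in every replicate
    pools to R=1 regardless of resampling."""
    rows = []
    for v in range(30):
        for sex, pid in (("female", "s"), ("male", "m")):
            rows.append(dict(
                crash_id=f"c{v}{sex[0]}", vehicle_id="v0",
                person_id=pid, crash_year=2015,
                vehicle_body="passenger_car", rollover=False,
                n_vehicles_in_crash=1, impact_point="front", seat="driver",
                sex=sex, age_years=25.0, belted="belted", airbag="deployed",
                died=True))
            rows.append(dict(
                crash_id=f"c{v}{sex[0]}", vehicle_id="v0", person_id="c",
                crash_year=2015, vehicle_body="passenger_car",
                rollover=False, n_vehicles_in_crash=1, impact_point="front",
                seat="front_right", sex="male", age_years=20.0,
                belted="belted", airbag="deployed", died=True))
    records = pd.DataFrame(rows)
    records["age_years"] = records["age_years"].astype("Float64")
    spec = dp.StratumSpec(
        subject_seat="driver", subject_belted="belted",
        subject_age=AgeBinning(25), control_seat="front_right",
        control_sex="male", control_age_band="b16_24",
        control_belted="belted", airbag_mode="matched")
    est = dp.bootstrap_ci(records, [spec], n_boot=50, seed=0)
    assert est.R_bar == pytest.approx(1.0)
    assert est.ci_low == pytest.approx(1.0)
    assert est.ci_high == pytest.approx(1.0)


def test_stratum_level_resampling_mode(small_dataset, specs_25):
    est = dp.bootstrap_ci(small_dataset, specs_25, n_boot=100, seed=9,
                          resample="strata")
    assert est.ci_low <= est.ci_high
    with pytest.raises(ValueError):
        dp.bootstrap_ci(small_dataset, specs_25, n_boot=10, seed=0,
                        resample="bogus")


def test_bootstrap_ci_width_shrinks_with_sample_size(specs_25):
    widths = {}
    for n in (1200, 4800):
        cfg = dp.SyntheticConfig(n_crashes=n, seed=77, true_R=1.0)
        sel = dp.select_cases(dp.generate(cfg),
                              CaseCriteria(vehicle_body="passenger_car"))
        est = dp.bootstrap_ci(sel, specs_25, n_boot=300, seed=3)
        widths[n] = est.ci_high - est.ci_low
    assert widths[4800] < widths[1200]


def test_age_sweep_collapse_and_structure(small_dataset):
    sub = [dp.SubjectStratum(seat="driver", belted="belted",
                             airbag_mode="any")]
    ctl = [dp.ControlCohort(sex="male", age_band="b16_24")]
    sweep = dp.age_sweep(small_dataset, centers=[25], subjects=sub,
                         controls=ctl, n_boot=100, seed=4)
    assert list(sweep["age_center"]) == [25]
    row = sweep.iloc[0]
    # single stratum: pooled value equals that stratum's R
    spec = build_stratum_specs(AgeBinning(25), subjects=sub, controls=ctl)[0]
    counts = dp.tabulate(dp.build_pairs(small_dataset, spec))
    expected = dp.risk_ratio(counts)
    assert row["R_bar"] == pytest.approx(expected, rel=1e-12)


def test_age_sweep_empty_center_flagged(small_dataset):
    sweep = dp.age_sweep(small_dataset, centers=[25, 112], n_boot=50, seed=2)
    assert bool(sweep.loc[sweep["age_center"] == 25, "usable"].iloc[0])
    impossible = sweep.loc[sweep["age_center"] == 112].iloc[0]
    assert not bool(impossible["usable"])
    assert np.isnan(impossible["R_bar"])
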