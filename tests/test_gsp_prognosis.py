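"""Index, enumeration, survival statistics and the selection machinery."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from rxagsp.datatypes import GeneSetPair
from rxagsp.gsp_prognosis import (
    cohort_survival,
    count_gsps,
    cox_binary_breslow,
    empirical_pvalue,
    enumerate_gsps,
    gsp_index,
    km_curve,
    liptak_combine,
    logrank_test,
    pair_count,
    pool_orientation_check,
    search_gsps,
    select_gsps,
)
from rxagsp.synthetic_data import SimulationConfig, simulate_cohorts

PAIR = GeneSetPair(("p1", "p2", "p3"), ("g1", "g2", "g3"))


# ------------------------------------------------------------------- index

def test_index_is_median_difference():
    s = pd.Series({"p1": 5, "p2": 7, "p3": 9, "g1": 6, "g2": 8, "g3": 10})
    r = gsp_index(s, PAIR)
    assert r.index_value == pytest.approx(-1.0)
    assert r.indicator == "negative"


def test_index_tie_is_negative():
    s = pd.Series({"p1": 3, "p2": 3, "g1": 3, "g2": 3})
    r = gsp_index(s, GeneSetPair(("p1", "p2"), ("g1", "g2")))
    assert r.index_value == 0
    assert r.indicator == "negative"


def test_index_uses_measured_genes_only_and_flags_unscorable():
    s = pd.Series({"p1": 5.0, "g1": np.nan, "g2": 4.0})
    r = gsp_index(s, GeneSetPair(("p1", "p2"), ("g1", "g2")))
    assert r.index_value == pytest.approx(1.0)
    with pytest.raises(ValueError, match="unscorable"):
        gsp_index(pd.Series({"p1": 5.0}), PAIR)


def test_index_invariant_under_monotone_transforms_for_odd_sets():
    rng = np.random.default_rng(0)
    transforms = [np.exp, np.cbrt, lambda x: 3 * x + 2, np.arctan]
    for _ in range(25):
        vals = rng.normal(7, 2, 6)
        s = pd.Series(vals, index=["p1", "p2", "p3", "g1", "g2", "g3"])
        base = gsp_index(s, PAIR).indicator
        f = transforms[rng.integers(len(transforms))]
        assert gsp_index(pd.Series(f(vals), index=s.index), PAIR).indicator == base


# ------------------------------------------------------------- enumeration

def test_minimal_pools_give_single_pair():
    pairs = list(enumerate_gsps(["a", "b"], ["c", "d"]))
    assert pairs == [GeneSetPair(("a", "b"), ("c", "d"))]


def test_three_by_three_pools_give_sixteen_pairs():
    pairs = list(enumerate_gsps(["a", "b", "c"], ["x", "y", "z"]))
    assert len(pairs) == 16
    assert len(set(pairs)) == 16


@pytest.mark.parametrize("na,nb", [(2, 2), (3, 5), (4, 4), (6, 6), (8, 7)])
def test_streamed_count_matches_closed_form(na, nb):
    a = [f"a{i}" for i in range(na)]
    b = [f"b{i}" for i in range(nb)]
    assert count_gsps(a, b) == pair_count(na, nb) == len(list(enumerate_gsps(a, b)))


def test_closed_form_for_published_pools():
    assert pair_count(10, 11) == 2_062_468
    assert pair_count(10, 11) == (2**10 - 11) * (2**11 - 12)


def test_undersized_pool_warns_and_is_empty():
    with pytest.warns(UserWarning):
        assert list(enumerate_gsps(["a"], ["b", "c"])) == []


# ----------------------------------------------------- log-rank / Cox core

def test_logrank_worked_example():
    # group A events at t=1,2; group B events at t=3,4; no censoring
    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.array([1, 1, 1, 1])
    group = np.array([1, 1, 0, 0])
    chi2, p = logrank_test(time, event, group)
    assert chi2 == pytest.approx(2.88235, abs=1e-4)


def test_identical_groups_give_null_statistics():
    time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    event = np.ones(6, dtype=int)
    group = np.array([1, 1, 1, 0, 0, 0])
    chi2, _ = logrank_test(time, event, group)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    beta, _, _ = cox_binary_breslow(time, event, group)
    assert np.exp(beta) == pytest.approx(1.0, abs=1e-6)


def test_logrank_matches_lifelines_on_tie_free_data():
    rng = np.random.default_rng(1)
    for _ in range(5):
        n = 60
        g = rng.integers(0, 2, n)
        time = rng.exponential(1.0 / np.exp(0.8 * g))
        event = (rng.random(n) > 0.25).astype(int)
        chi2, p = logrank_test(time, event, g)
        ref = ll_logrank(time[g == 1], time[g == 0], event[g == 1], event[g == 0])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


def test_cox_matches_lifelines_on_tie_free_data():
    rng = np.random.default_rng(2)
    n = 120
    g = rng.integers(0, 2, n)
    time = rng.exponential(1.0 / np.exp(1.0 * g))
    event = (rng.random(n) > 0.2).astype(int)
    beta, se, p = cox_binary_breslow(time, event, g)
    df = pd.DataFrame({"T": time, "E": event, "g": g})
    cph = CoxPHFitter().fit(df, "T", "E")  # Efron = Breslow without ties
    assert beta == pytest.approx(cph.params_["g"], rel=1e-5)
    assert se == pytest.approx(cph.standard_errors_["g"], rel=1e-4)


def test_logrank_equals_cox_score_statistic_without_ties():
    """For a binary covariate the log-rank chi-square is the Cox score test."""
    rng = np.random.default_rng(3)
    n = 80
    g = rng.integers(0, 2, n)
    time = rng.exponential(1.0, n)  # continuous: no ties
    event = np.ones(n, dtype=int)
    chi2, _ = logrank_test(time, event, g)
    # score statistic U(0)^2 / I(0) computed independently from risk sets
    order = np.argsort(time)
    g_s = g[order]
    U = I = 0.0
    for j in range(n):
        at_risk = g_s[j:]
        pbar = at_risk.mean()
        U += g_s[j] - pbar
        I += pbar * (1 - pbar)
    assert chi2 == pytest.approx(U**2 / I, rel=1e-6)


def test_cox_recovers_planted_log_hazard():
    rng = np.random.default_rng(4)
    betas = []
    for _ in range(50):
        n = 200
        g = rng.integers(0, 2, n)
        time = rng.exponential(1.0 / np.exp(1.0 * g))
        event = np.ones(n, dtype=int)
        beta, *_ = cox_binary_breslow(time, event, g)
        betas.append(beta)
    assert abs(np.mean(betas) - 1.0) < 0.15


def test_cohort_survival_interface():
    clin = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "efs_time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "efs_event": [1, 1, 1, 1, 0, 0],
            "os_time": [1.0] * 6,
            "os_event": [1] * 6,
        }
    )
    ind = pd.Series([True, True, True, False, False, False], index=clin["sample_id"])
    res = cohort_survival(ind, clin, "efs")
    assert res.testable and res.n == 6 and res.n_events == 4
    assert res.hazard_ratio > 1
    one_class = pd.Series([True] * 6, index=clin["sample_id"])
    assert not cohort_survival(one_class, clin, "efs").testable


# ------------------------------------------------------------------ Liptak

def test_liptak_single_cohort_is_identity():
    z, p = liptak_combine([0.2], [3.0])
    assert p == pytest.approx(0.2, rel=1e-9)


def test_liptak_two_cohorts_at_alpha():
    _, p = liptak_combine([0.05, 0.05], [1.0, 1.0])
    assert p == pytest.approx(0.0100, abs=2e-4)


def test_liptak_null_midpoint():
    _, p = liptak_combine([0.5, 0.5], [1.0, 1.0])
    assert p == pytest.approx(0.5)


def test_liptak_clips_degenerate_p_with_warning():
    with pytest.warns(UserWarning):
        _, p = liptak_combine([0.0, 0.5], [1.0, 1.0])
    assert 0.0 < p < 0.5


# -------------------------------------------------------------- permutation

def test_empirical_p_deterministic_and_minimal_for_separation():
    rng = np.random.default_rng(5)
    n = 40
    clin = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "efs_time": np.concatenate([rng.uniform(0, 1, 20), rng.uniform(5, 6, 20)]),
            "efs_event": np.ones(n, dtype=int),
            "os_time": np.ones(n),
            "os_event": np.ones(n, dtype=int),
        }
    )
    ind = pd.Series([True] * 20 + [False] * 20, index=clin["sample_id"])
    p1 = empirical_pvalue(ind, clin, "efs", n_perm=199, seed=7)
    p2 = empirical_pvalue(ind, clin, "efs", n_perm=199, seed=7)
    assert p1 == p2 == pytest.approx(1 / 200)


def test_empirical_p_warns_on_low_resolution():
    clin = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c", "d"],
            "efs_time": [1.0, 2.0, 3.0, 4.0],
            "efs_event": [1, 1, 1, 1],
            "os_time": [1.0] * 4,
            "os_event": [1] * 4,
        }
    )
    ind = pd.Series([True, True, False, False], index=clin["sample_id"])
    with pytest.warns(UserWarning):
        empirical_pvalue(ind, clin, "efs", n_perm=50, seed=0)


# --------------------------------------------------------------------- KM

def test_km_no_events_is_flat():
    km = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
    assert (km["survival"] == 1.0).all()
    assert km["n_at_risk"].tolist() == [3, 2, 1]


def test_km_product_limit_worked_example():
    km = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
    np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])


def test_km_rejects_negative_times():
    with pytest.raises(ValueError):
        km_curve([-1.0, 2.0], [1, 1])


def test_km_matches_lifelines():
    rng = np.random.default_rng(6)
    time = rng.exponential(1.0, 50).round(2)  # ties on purpose
    event = (rng.random(50) > 0.3).astype(int)
    km = km_curve(time, event)
    kmf = KaplanMeierFitter().fit(time, event)
    ref = kmf.survival_function_at_times(km["time"]).to_numpy()
    np.testing.assert_allclose(km["survival"], ref, atol=1e-12)


# ------------------------------------------------------- search & selection

@pytest.fixture(scope="module")
def planted_search():
    cfg = SimulationConfig(n_genes=300, n_samples_per_cohort=100, seed=1)
    cohorts, clinical, *_, truth = simulate_cohorts(cfg)
    res = search_gsps(cohorts, clinical, truth.pool_unfavorable, truth.pool_favorable)
    return res, truth, [c.name for c in cohorts]


def test_search_enumerates_all_pairs(planted_search):
    res, truth, _ = planted_search
    assert len(res) == pair_count(6, 6)


def test_search_selects_planted_pair(planted_search):
    res, truth, _ = planted_search
    pp = "|".join(truth.planted_pair.poor_set)
    gg = "|".join(truth.planted_pair.good_set)
    row = res[(res["poor_set"] == pp) & (res["good_set"] == gg)].iloc[0]
    assert row["selected"]
    assert row["q_joint"] < 0.05


def test_selection_is_monotone_in_thresholds(planted_search):
    res, _, names = planted_search
    tight = set(select_gsps(res, names, per_cohort_alpha=0.01, joint_fdr=0.01).index)
    loose = set(select_gsps(res, names, per_cohort_alpha=0.05, joint_fdr=0.05).index)
    assert tight <= loose


def test_orientation_check_flags_adverse_skew(planted_search):
    res, *_ = planted_search
    frac, p = pool_orientation_check(res["strat_score"])
    assert frac > 0.5
    assert p < 0.05


def test_orientation_check_trivial_cases():
    frac, _ = pool_orientation_check([1.0, 2.0, 0.5])
    assert frac == 1.0
    frac, p = pool_orientation_check(np.concatenate([np.ones(50), -np.ones(50)]))
    assert frac == pytest.approx(0.5)
    assert p > 0.05
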