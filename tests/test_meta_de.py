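"""Pooling, batch adjustment, Welch DE and the Stouffer/BH combination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rxagsp.meta_de import (
    adjust_batch,
    bh_fdr,
    call_signature,
    meta_de_table,
    platform_de,
    pool_by_platform,
    quantile_normalize,
    run_meta_de,
    stouffer_combine,
    t_to_z,
)
from conftest import make_cohort


# ------------------------------------------------------------------ pooling

def test_pool_intersects_genes_within_platform():
    rng = np.random.default_rng(0)
    c1 = make_cohort(rng.normal(7, 1, (4, 6)), name="c1")
    c2 = make_cohort(rng.normal(7, 1, (4, 6)), name="c2")
    # rename genes: c1 has {a,b,c}, c2 has {b,c,d}
    c1.values.index = ["a", "b", "c", "x"]
    c1.values = c1.values.drop(index="x")
    c2.values.index = ["b", "c", "d", "y"]
    c2.values = c2.values.drop(index="y")
    pooled = pool_by_platform([c1, c2])
    assert list(pooled["P1"].gene_ids) == ["b", "c"]
    assert pooled["P1"].n_samples == 12
    assert set(pooled["P1"].batch.unique()) == {"c1", "c2"}


def test_pool_does_not_intersect_across_platforms():
    rng = np.random.default_rng(1)
    c1 = make_cohort(rng.normal(7, 1, (5, 4)), name="c1", platform="P1")
    c2 = make_cohort(rng.normal(7, 1, (3, 4)), name="c2", platform="P2")
    pooled = pool_by_platform([c1, c2])
    assert len(pooled) == 2
    assert pooled["P1"].values.shape[0] == 5
    assert pooled["P2"].values.shape[0] == 3


def test_pool_rejects_duplicate_sample_ids():
    rng = np.random.default_rng(2)
    c1 = make_cohort(rng.normal(7, 1, (3, 4)), name="c1")
    c2 = make_cohort(rng.normal(7, 1, (3, 4)), name="c1")  # same sample ids
    with pytest.raises(ValueError, match="duplicate sample_ids"):
        pool_by_platform([c1, c2])


def test_quantile_normalize_equalizes_column_distributions():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(50, 5)) * [1, 2, 3, 4, 5])
    qn = quantile_normalize(df)
    ref = np.sort(qn.to_numpy()[:, 0])
    for j in range(1, 5):
        np.testing.assert_allclose(np.sort(qn.to_numpy()[:, j]), ref)


# ----------------------------------------------------------------- batches

def test_adjust_batch_single_batch_is_identity():
    rng = np.random.default_rng(4)
    c = make_cohort(rng.normal(7, 1, (20, 10)))
    out = adjust_batch(c)
    pd.testing.assert_frame_equal(out.values, c.values)


def test_adjust_batch_removes_planted_shift(two_batch_cohort):
    """Oracle: direct per-gene batch-mean difference after a +2.0 planted shift."""
    raw_diff = (
        two_batch_cohort.values.loc[:, (two_batch_cohort.batch == "B").to_numpy()].mean(axis=1)
        - two_batch_cohort.values.loc[:, (two_batch_cohort.batch == "A").to_numpy()].mean(axis=1)
    )
    assert abs(raw_diff.mean() - 2.0) < 0.1  # the shift is really there
    adj = adjust_batch(two_batch_cohort)
    diff = (
        adj.values.loc[:, (adj.batch == "B").to_numpy()].mean(axis=1)
        - adj.values.loc[:, (adj.batch == "A").to_numpy()].mean(axis=1)
    )
    assert abs(diff.mean()) < 0.1


def test_adjust_batch_rejects_singleton_batch():
    rng = np.random.default_rng(5)
    c = make_cohort(rng.normal(7, 1, (10, 5)), batch=["A", "A", "A", "A", "B"])
    with pytest.raises(ValueError, match="B"):
        adjust_batch(c)


def test_adjust_batch_passes_constant_gene_through():
    rng = np.random.default_rng(6)
    vals = rng.normal(7, 1, (10, 8))
    vals[0] = 3.14
    c = make_cohort(vals, batch=["A"] * 4 + ["B"] * 4)
    with pytest.warns(UserWarning, match="constant"):
        out = adjust_batch(c)
    np.testing.assert_allclose(out.values.iloc[0], 3.14)


def test_adjust_batch_preserves_grand_mean_for_identical_batches():
    rng = np.random.default_rng(7)
    c = make_cohort(rng.normal(7, 1, (50, 60)), batch=["A", "B"] * 30)
    out = adjust_batch(c)
    shift = (out.values.mean(axis=1) - c.values.mean(axis=1)).abs()
    assert shift.max() < 0.05


# ---------------------------------------------------------------- Welch DE

def test_platform_de_matches_textbook_welch_formula():
    rng = np.random.default_rng(8)
    vals = rng.normal(7, 1, (30, 21))
    status = ["MA"] * 9 + ["MN"] * 12
    c = make_cohort(vals, status=status)
    res = platform_de(c)
    # independent brute-force Welch on one gene
    x, y = vals[4, :9], vals[4, 9:]
    se2 = x.var(ddof=1) / 9 + y.var(ddof=1) / 12
    t_manual = (x.mean() - y.mean()) / np.sqrt(se2)
    df_manual = se2**2 / (
        (x.var(ddof=1) / 9) ** 2 / 8 + (y.var(ddof=1) / 12) ** 2 / 11
    )
    assert res["t"].iloc[4] == pytest.approx(t_manual, rel=1e-12)
    assert res["df"].iloc[4] == pytest.approx(df_manual, rel=1e-12)
    assert res["log2_fc"].iloc[4] == pytest.approx(x.mean() - y.mean())


def test_platform_de_forced_fold_change():
    vals = np.ones((1, 6))
    vals[0, :3] = 2.0
    vals += np.random.default_rng(0).normal(0, 1e-9, vals.shape)
    c = make_cohort(vals, status=["MA"] * 3 + ["MN"] * 3)
    res = platform_de(c)
    assert res["log2_fc"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_platform_de_requires_both_groups():
    c = make_cohort(np.ones((2, 4)), status=["MA"] * 4)
    with pytest.raises(ValueError):
        platform_de(c)


# -------------------------------------------------------------- combination

def test_stouffer_equal_weights_is_z_times_sqrt_k():
    z, p = stouffer_combine([1.0, 1.0, 1.0, 1.0], [1, 1, 1, 1])
    assert z == pytest.approx(2.0)


def test_stouffer_single_study_identity():
    z, _ = stouffer_combine([2.5], [7.3])
    assert z == pytest.approx(2.5)


def test_stouffer_weighted_example():
    z, _ = stouffer_combine([1.5, -0.5], [np.sqrt(50), np.sqrt(100)])
    assert z == pytest.approx(0.4578, abs=1e-4)


def test_stouffer_rejects_bad_weights():
    with pytest.raises(ValueError):
        stouffer_combine([1.0], [0.0])
    with pytest.raises(ValueError):
        stouffer_combine([1.0, 2.0], [1.0])


def test_t_to_z_preserves_tail_probability():
    t_vals = np.array([-3.2, -0.5, 0.0, 1.7, 6.0])
    df = np.full_like(t_vals, 14.0)
    z = t_to_z(t_vals, df)
    np.testing.assert_allclose(
        stats.norm.sf(np.abs(z)), stats.t.sf(np.abs(t_vals), df), rtol=1e-10
    )
    assert (np.sign(z) == np.sign(t_vals)).all()


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5], [0.5]),
        ([0.001, 0.5], [0.002, 0.5]),
    ],
)
def test_bh_fdr_worked_examples(p, expected):
    np.testing.assert_allclose(bh_fdr(p), expected)


def test_bh_fdr_matches_brute_force_step_up():
    def brute(p):
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p)
        q = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            q[i] = running
        return q

    rng = np.random.default_rng(9)
    for _ in range(20):
        p = rng.random(rng.integers(1, 200))
        np.testing.assert_allclose(bh_fdr(p), brute(p), rtol=1e-12)


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------- signature calls

def _meta_row(q, fc_signs, **kw):
    return dict(q_value=q, fc_signs=fc_signs, **kw)


def test_call_signature_rules():
    meta = pd.DataFrame(
        {
            "q_value": [5e-4, 5e-4, 5e-3, 5e-4, 5e-4],
            "fc_signs": [(1.0, 1.0), (1.0,), (1.0, 1.0), (-1.0, -1.0), (1.0, -1.0)],
            "log2_fc": [1.0, 1.0, 1.0, -1.0, 0.1],
        },
        index=["both_up", "one_platform", "not_sig", "both_down", "conflict"],
    )
    ma_hi, mn_hi = call_signature(meta, fdr_threshold=0.001)
    assert ma_hi == ["both_up", "one_platform"]
    assert mn_hi == ["both_down"]
    assert meta.loc["conflict", "call"] == "none"
    assert meta.loc["not_sig", "call"] == "none"


def test_meta_table_combines_platforms_with_sqrt_n_weights():
    rng = np.random.default_rng(10)
    c1 = make_cohort(rng.normal(7, 1, (10, 50)), name="c1", platform="P1")
    c2 = make_cohort(rng.normal(7, 1, (10, 100)), name="c2", platform="P2")
    r1, r2 = platform_de(c1), platform_de(c2)
    meta = meta_de_table({"P1": r1, "P2": r2})
    g = meta.index[0]
    z1 = t_to_z(np.array([r1.loc[g, "t"]]), np.array([r1.loc[g, "df"]]))[0]
    z2 = t_to_z(np.array([r2.loc[g, "t"]]), np.array([r2.loc[g, "df"]]))[0]
    w1, w2 = np.sqrt(50), np.sqrt(100)
    expected = (w1 * z1 + w2 * z2) / np.sqrt(w1**2 + w2**2)
    assert meta.loc[g, "z_combined"] == pytest.approx(expected, rel=1e-10)


def test_run_meta_de_recovers_planted_signature(small_study):
    cohorts, *_, truth = small_study
    meta, ma_hi, mn_hi = run_meta_de(cohorts)
    sens_ma = len(set(ma_hi) & set(truth.ma_hi_genes)) / len(truth.ma_hi_genes)
    sens_mn = len(set(mn_hi) & set(truth.mn_hi_genes)) / len(truth.mn_hi_genes)
    assert sens_ma > 0.85 and sens_mn > 0.85
    # recovered genes carry the planted direction
    assert not set(ma_hi) & set(truth.mn_hi_genes)
    assert not set(mn_hi) & set(truth.ma_hi_genes)
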