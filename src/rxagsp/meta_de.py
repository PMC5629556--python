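"""Cross-platform differential-expression meta-analysis of MYCN status.

Cohorts measured on the same platform are pooled (per-sample quantile
normalisation, source cohort kept as the batch label), batch effects are
shrunk with a parametric empirical-Bayes location/scale adjustment, each
platform contributes a Welch t statistic per gene for MYCN-amplified (MA)
versus normal-copy (MN) samples, and platforms are combined with a weighted
Stouffer z (weights sqrt of platform sample size).  Genes pass into the
MA_hi / MN_hi signature at a Benjamini-Hochberg FDR below ``fdr_threshold``
(default 0.001) when the fold-change direction is consistent on every
platform that covers the gene; genes covered by a single platform are
retained on that platform's evidence alone.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionCohort

__all__ = [
    "pool_by_platform",
    "quantile_normalize",
    "adjust_batch",
    "platform_de",
    "stouffer_combine",
    "t_to_z",
    "bh_fdr",
    "meta_de_table",
    "call_signature",
]


# ----------------------------------------------------------------- pooling

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-sample quantile normalisation to the mean sorted profile.

    Every column is mapped onto the reference distribution obtained by
    averaging the sorted columns, the textbook procedure for making array
    intensity distributions comparable before pooling.
    """
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0)
    ranks = np.argsort(order, axis=0)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = reference[ranks]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def pool_by_platform(
    cohorts: list[ExpressionCohort], normalize: bool = True
) -> dict[str, ExpressionCohort]:
    """Merge cohorts measured on the same platform into one pooled cohort.

    Genes are restricted to those present in every cohort of the platform
    (no intersection is applied across platforms); each source cohort
    becomes one batch of the pooled cohort.
    """
    all_samples = pd.concat([pd.Series(c.sample_ids) for c in cohorts])
    dup = all_samples[all_samples.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_ids across cohorts: {sorted(set(dup))[:5]}")

    by_platform: dict[str, list[ExpressionCohort]] = {}
    for c in cohorts:
        by_platform.setdefault(c.platform, []).append(c)

    pooled = {}
    for platform in sorted(by_platform):
        group = by_platform[platform]
        genes = group[0].gene_ids
        for c in group[1:]:
            genes = genes.intersection(c.gene_ids)
        genes = genes.sort_values()
        mats, batches, statuses = [], [], []
        for c in group:
            mat = c.values.loc[genes]
            if normalize:
                mat = quantile_normalize(mat)
            mats.append(mat)
            batches.append(pd.Series(c.name, index=c.sample_ids))
            statuses.append(c.mycn_status)
        pooled[platform] = ExpressionCohort(
            values=pd.concat(mats, axis=1),
            name=f"pooled_{platform}",
            platform=platform,
            batch=pd.concat(batches),
            mycn_status=pd.concat(statuses),
        )
    return pooled


# ------------------------------------------------- empirical-Bayes batches

def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative solution of the parametric EB posterior means (per batch)."""
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def adjust_batch(cohort: ExpressionCohort) -> ExpressionCohort:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene, expression is standardised under a model with batch and MYCN
    status effects; per-batch additive and multiplicative effects are
    estimated, shrunk toward moments-matched priors (normal for location,
    inverse-gamma for scale) and removed.  The MYCN group contrast is part
    of the design and therefore preserved.

    Raises
    ------
    ValueError
        If some batch contains fewer than two samples.
    """
    batches = sorted(cohort.batch.unique())
    if len(batches) == 1:
        return cohort.copy()
    counts = cohort.batch.value_counts()
    singles = counts[counts < 2]
    if len(singles):
        raise ValueError(f"batch {singles.index[0]!r} has fewer than 2 samples")

    Y = cohort.values.to_numpy(dtype=float)
    n_genes, n = Y.shape

    # genes constant everywhere carry no batch information; pass through
    gene_sd = Y.std(axis=1)
    const = gene_sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant genes passed through unadjusted")

    batch_idx = [np.flatnonzero((cohort.batch == b).to_numpy()) for b in batches]
    n_b = np.array([len(ix) for ix in batch_idx], dtype=float)

    X_batch = np.zeros((n, len(batches)))
    for j, ix in enumerate(batch_idx):
        X_batch[ix, j] = 1.0
    x_mycn = (cohort.mycn_status == "MA").to_numpy(dtype=float)[:, None]
    X = np.hstack([X_batch, x_mycn])

    B_hat, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (n_batch+1, genes)
    grand_mean = (n_b / n) @ B_hat[: len(batches)]
    var_pooled = ((Y - (X @ B_hat).T) ** 2).mean(axis=1)

    adjustable = ~const & (var_pooled > 0)
    stand_mean = grand_mean[:, None] + (x_mycn @ B_hat[len(batches):]).T
    sd = np.sqrt(var_pooled[adjustable])[:, None]
    Z = (Y[adjustable] - stand_mean[adjustable]) / sd

    out = Y.copy()
    Z_adj = np.empty_like(Z)
    for j, ix in enumerate(batch_idx):
        sdat = Z[:, ix]
        g_hat = sdat.mean(axis=1)
        d_hat = sdat.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        if s2 == 0 or t2 == 0:  # degenerate prior: fall back to raw estimates
            g_star, d_star = g_hat, np.maximum(d_hat, 1e-12)
        else:
            a = (2 * s2 + m**2) / s2
            b = (m * s2 + m**3) / s2
            g_star, d_star = _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b)
        Z_adj[:, ix] = (sdat - g_star[:, None]) / np.sqrt(d_star)[:, None]
    out[adjustable] = Z_adj * sd + stand_mean[adjustable]

    adjusted = cohort.copy()
    adjusted.values = pd.DataFrame(out, index=cohort.gene_ids, columns=cohort.sample_ids)
    return adjusted


# -------------------------------------------------------- per-platform DE

def platform_de(cohort: ExpressionCohort) -> pd.DataFrame:
    """Welch two-sample t per gene, MA versus MN samples.

    Returns a DataFrame indexed by gene with columns ``t, p, df, n_ma,
    n_mn, log2_fc`` (log2_fc = mean(MA) - mean(MN)).  Genes with fewer
    than two finite values in either group are flagged ``testable=False``
    and excluded from the meta-analysis.
    """
    ma = cohort.values.loc[:, (cohort.mycn_status == "MA").to_numpy()]
    mn = cohort.values.loc[:, (cohort.mycn_status == "MN").to_numpy()]
    if ma.shape[1] == 0 or mn.shape[1] == 0:
        raise ValueError("both MA and MN groups must be non-empty")
    a, b = ma.to_numpy(dtype=float), mn.to_numpy(dtype=float)
    n1 = np.isfinite(a).sum(axis=1)
    n2 = np.isfinite(b).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1, m2 = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    res = pd.DataFrame(
        {
            "t": t, "p": p, "df": df,
            "n_ma": n1, "n_mn": n2, "log2_fc": m1 - m2,
            "testable": (n1 >= 2) & (n2 >= 2) & np.isfinite(t),
        },
        index=cohort.gene_ids,
    )
    return res


# ------------------------------------------------------------- combination

def t_to_z(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Map t statistics to standard-normal z preserving sign and tail mass."""
    t = np.asarray(t, dtype=float)
    one_sided = stats.t.sf(np.abs(t), df)
    return np.sign(t) * stats.norm.isf(np.clip(one_sided, 1e-300, 1.0))


def stouffer_combine(z_list, weights) -> tuple[float, float]:
    """Weighted Stouffer combination: z = sum(w_i z_i) / sqrt(sum w_i^2).

    Returns the combined z and its two-sided normal p-value.
    """
    z = np.asarray(z_list, dtype=float)
    w = np.asarray(weights, dtype=float)
    if z.shape != w.shape or z.size == 0:
        raise ValueError("z_list and weights must be equal-length and non-empty")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    z_comb = float((w * z).sum() / np.sqrt((w**2).sum()))
    return z_comb, float(2.0 * stats.norm.sf(abs(z_comb)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -------------------------------------------------------------- meta table

def meta_de_table(platform_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-platform Welch statistics into a per-gene meta table.

    ``platform_results`` maps platform -> output of :func:`platform_de`.
    Platform weights are sqrt of the platform's total sample count.  The
    returned frame has one row per gene in the union, with per-platform
    ``t_<p>``, ``fc_<p>`` columns, the combined z / p / q and the
    platform-averaged log2 fold change.
    """
    platforms = sorted(platform_results)
    genes = sorted(set().union(*[set(r.index) for r in platform_results.values()]))
    rows = {g: {"platforms_covering": []} for g in genes}

    for plat in platforms:
        res = platform_results[plat]
        w_plat = float(np.sqrt((res["n_ma"] + res["n_mn"]).iloc[0]))
        testable = res[res["testable"]]
        z_plat = t_to_z(testable["t"].to_numpy(), testable["df"].to_numpy())
        for (g, row), z in zip(testable.iterrows(), z_plat):
            d = rows[g]
            d.setdefault("z", []).append(z)
            d.setdefault("w", []).append(w_plat)
            d.setdefault("fcs", []).append(row["log2_fc"])
            d[f"t_{plat}"] = row["t"]
            d[f"fc_{plat}"] = row["log2_fc"]
            d[f"n_{plat}"] = (row["n_ma"], row["n_mn"])
            d["platforms_covering"].append(plat)

    records = []
    for g in genes:
        d = rows[g]
        if "z" not in d:
            continue
        z_comb, p_comb = stouffer_combine(d.pop("z"), d.pop("w"))
        fcs = d.pop("fcs")
        records.append(
            {
                "gene_id": g, **d,
                "z_combined": z_comb, "p_combined": p_comb,
                "log2_fc": float(np.mean(fcs)),
                "fc_signs": tuple(np.sign(f) for f in fcs),
            }
        )
    out = pd.DataFrame.from_records(records).set_index("gene_id")
    out["q_value"] = bh_fdr(out["p_combined"].to_numpy())
    return out


def call_signature(
    meta: pd.DataFrame, fdr_threshold: float = 0.001
) -> tuple[list[str], list[str]]:
    """Call the MA_hi / MN_hi signature from the meta table.

    A gene is MA_hi when q < threshold and its fold change is positive on
    every platform covering it; MN_hi likewise with negative fold changes.
    Genes significant on one platform but absent from the other are
    retained; genes with conflicting fold-change signs are dropped.
    """
    sig = meta[meta["q_value"] < fdr_threshold]
    ma_hi, mn_hi = [], []
    for g, row in sig.iterrows():
        signs = set(row["fc_signs"])
        if signs == {1.0}:
            ma_hi.append(g)
        elif signs == {-1.0}:
            mn_hi.append(g)
        # mixed signs across platforms: cross-platform inconsistency, drop
    meta["call"] = "none"
    meta.loc[ma_hi, "call"] = "MA_hi"
    meta.loc[mn_hi, "call"] = "MN_hi"
    return sorted(ma_hi), sorted(mn_hi)


def run_meta_de(
    cohorts: list[ExpressionCohort],
    fdr_threshold: float = 0.001,
    normalize: bool = True,
    adjust_batches: bool = True,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """End-to-end meta-DE: pool, adjust, test per platform, combine, call."""
    pooled = pool_by_platform(cohorts, normalize=normalize)
    results = {}
    for plat, cohort in pooled.items():
        if adjust_batches and cohort.batch.nunique() > 1:
            cohort = adjust_batch(cohort)
        results[plat] = platform_de(cohort)
    meta = meta_de_table(results)
    ma_hi, mn_hi = call_signature(meta, fdr_threshold)
    return meta, ma_hi, mn_hi
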