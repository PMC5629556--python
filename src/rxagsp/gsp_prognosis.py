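"""Prognostic gene-set-pair (GSP) search by relative expression analysis.

A gene-set pair is an ordered pair of disjoint gene sets drawn from the
unfavorable (MA_hi) and favorable (MN_hi) candidate pools.  Each patient
receives the index

    I = median(log2 expr, poor-outcome set) - median(log2 expr, good-outcome set)

evaluated within the patient's own profile, so the resulting positive /
negative indicator needs no cross-cohort normalisation.  All subset pairs
of size >= ``min_set_size`` are enumerated; in each training cohort the
indicator is scored by the two-group log-rank test and a univariate Cox
model, one-sided cohort p-values (direction: positive indicator = worse
event-free survival) are combined across cohorts with Liptak's weighted-z
method (weights sqrt of cohort size), and pairs are selected when the
joint Benjamini-Hochberg FDR is below ``joint_fdr`` and every cohort shows
HR > 1 with log-rank and Cox p below ``per_cohort_alpha``.

Per-pair screening uses the closed-form log-rank score over precomputed
risk tables; full Cox fits (Newton-Raphson on the Breslow partial
likelihood) are only run for pairs that survive screening, which keeps the
multi-million-pair search tractable on one CPU.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionCohort, GeneSetPair
from .meta_de import bh_fdr

__all__ = [
    "GSPIndicator",
    "CohortSurvival",
    "gsp_index",
    "enumerate_gsps",
    "count_gsps",
    "pair_count",
    "cohort_survival",
    "liptak_combine",
    "search_gsps",
    "select_gsps",
    "empirical_pvalue",
    "pool_orientation_check",
    "km_curve",
]


# ------------------------------------------------------------------- index

@dataclass
class GSPIndicator:
    sample_id: str
    index_value: float
    indicator: str  # "positive" | "negative"


def gsp_index(expr_for_sample: pd.Series, pair: GeneSetPair) -> GSPIndicator:
    """Score one sample: median(poor set) - median(good set), measured genes only.

    A tie (index exactly 0) is classed negative, matching the strict
    "higher than" definition of a positive indicator.

    Raises
    ------
    ValueError
        If either set has no measured gene in the sample.
    """
    s = pd.Series(expr_for_sample).dropna()
    poor = s.reindex([g for g in pair.poor_set if g in s.index]).dropna()
    good = s.reindex([g for g in pair.good_set if g in s.index]).dropna()
    if len(poor) == 0 or len(good) == 0:
        raise ValueError("sample unscorable: a set has zero measured genes")
    value = float(poor.median() - good.median())
    return GSPIndicator(
        sample_id=str(getattr(expr_for_sample, "name", "")),
        index_value=value,
        indicator="positive" if value > 0 else "negative",
    )


# ------------------------------------------------------------- enumeration

def pair_count(n_a: int, n_b: int, min_set_size: int = 2) -> int:
    """Closed-form number of subset pairs with both sides >= min_set_size."""
    def n_subsets(n: int) -> int:
        total = 2**n
        small = sum(_binom(n, k) for k in range(min_set_size))
        return total - small

    return n_subsets(n_a) * n_subsets(n_b)


def _binom(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def count_gsps(pool_a, pool_b, min_set_size: int = 2) -> int:
    """Count the enumerable pairs by streaming over the subset product.

    Cross-checks :func:`pair_count` without constructing pair objects;
    pools of 10 and 11 (the published candidate pools) stream their
    2,062,468 combinations in well under a second.
    """
    if len(pool_a) < min_set_size or len(pool_b) < min_set_size:
        return 0
    subsets_b = list(_subsets(sorted(pool_b), min_set_size))
    return sum(
        1 for _ in itertools.product(_subsets(sorted(pool_a), min_set_size), subsets_b)
    )


def enumerate_gsps(pool_a, pool_b, min_set_size: int = 2):
    """Yield every GeneSetPair (A subset of pool_a, B subset of pool_b).

    Subsets are emitted in deterministic order: by size, then
    lexicographically within sorted pools.  Pools smaller than
    ``min_set_size`` produce an empty iterator (with a warning).
    """
    pool_a, pool_b = sorted(pool_a), sorted(pool_b)
    if set(pool_a) & set(pool_b):
        raise ValueError("candidate pools must be disjoint")
    if len(pool_a) < min_set_size or len(pool_b) < min_set_size:
        warnings.warn("a pool is smaller than min_set_size; no pairs to enumerate")
        return
    subsets_b = list(_subsets(pool_b, min_set_size))
    for a in _subsets(pool_a, min_set_size):
        for b in subsets_b:
            yield GeneSetPair(poor_set=a, good_set=b)


def _subsets(pool: list[str], min_size: int):
    for k in range(min_size, len(pool) + 1):
        yield from itertools.combinations(pool, k)


# ------------------------------------------------- log-rank / Cox internals

class _RiskTable:
    """Per-cohort precomputation for the two-group log-rank score.

    Sorts samples by time ascending and groups tied event times into
    blocks; group-1 at-risk counts for any indicator vector are then
    suffix sums along the sorted axis.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if (time < 0).any():
            raise ValueError("negative survival time")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.t_sorted = time[self.order]
        self.e_sorted = event[self.order]
        # blocks = distinct times with at least one event
        starts, d, n_at_risk = [], [], []
        i = 0
        while i < self.n:
            j = i
            while j < self.n and self.t_sorted[j] == self.t_sorted[i]:
                j += 1
            d_block = int(self.e_sorted[i:j].sum())
            if d_block > 0:
                starts.append(i)
                d.append(d_block)
                n_at_risk.append(self.n - i)
            i = j
        self.block_start = np.array(starts, dtype=int)
        self.block_end = np.array(
            [self._block_end(s) for s in starts], dtype=int
        )
        self.d = np.array(d, dtype=float)
        self.n_at_risk = np.array(n_at_risk, dtype=float)
        self.n_events = int(event.sum())

    def _block_end(self, start: int) -> int:
        t = self.t_sorted[start]
        j = start
        while j < self.n and self.t_sorted[j] == t:
            j += 1
        return j

    def score(self, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Log-rank score U and hypergeometric variance V for each row of G.

        G is a (pairs x samples) 0/1 indicator matrix in original sample
        order; U > 0 means the positive-indicator group has more events
        than expected (worse survival).
        """
        G = np.atleast_2d(np.asarray(G, dtype=float))
        Gs = G[:, self.order]
        # at-risk in group 1 at each block start: suffix sums
        suffix = np.cumsum(Gs[:, ::-1], axis=1)[:, ::-1]
        n1 = suffix[:, self.block_start]
        # observed group-1 events per block
        ce = np.cumsum(Gs * self.e_sorted, axis=1)
        hi = ce[:, self.block_end - 1]
        lo = np.where(self.block_start > 0, self.block_start - 1, 0)
        o1 = hi - np.where(self.block_start > 0, ce[:, lo], 0.0)
        frac = n1 / self.n_at_risk
        U = (o1 - self.d * frac).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vterm = (
                self.d * frac * (1.0 - frac)
                * (self.n_at_risk - self.d)
                / np.maximum(self.n_at_risk - 1.0, 1.0)
            )
        V = np.where(self.n_at_risk > 1, vterm, 0.0).sum(axis=1)
        return U, V


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its two-sided p-value."""
    rt = _RiskTable(time, event)
    U, V = rt.score(np.asarray(group, dtype=float)[None, :])
    if V[0] <= 0:
        return 0.0, 1.0
    chi2 = float(U[0] ** 2 / V[0])
    return chi2, float(stats.chi2.sf(chi2, 1))


def cox_binary_breslow(time, event, group, max_iter: int = 50, tol: float = 1e-9):
    """Univariate Cox fit for a binary covariate, Breslow tie handling.

    Newton-Raphson on the partial likelihood; returns (beta, se, wald_p).
    Monotone likelihoods (complete separation) are capped at |beta| = 15.
    """
    rt = _RiskTable(time, event)
    g = np.asarray(group, dtype=float)
    gs = g[rt.order]
    suffix = np.cumsum(gs[::-1])[::-1]
    n1 = suffix[rt.block_start]
    n0 = rt.n_at_risk - n1
    ce = np.cumsum(gs * rt.e_sorted)
    hi = ce[rt.block_end - 1]
    lo = np.where(rt.block_start > 0, ce[np.maximum(rt.block_start - 1, 0)], 0.0)
    o1_total = float((hi - lo).sum())

    beta = 0.0
    info = np.nan
    for _ in range(max_iter):
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        score = o1_total - float((rt.d * n1 * eb / denom).sum())
        info = float((rt.d * n1 * n0 * eb / denom**2).sum())
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(beta) > 15.0:
            beta = float(np.clip(beta, -15.0, 15.0))
            break
        if abs(step) < tol:
            break
    se = 1.0 / np.sqrt(info) if info and info > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if np.isfinite(se) else 1.0
    return float(beta), float(se), p


# --------------------------------------------------------- cohort survival

@dataclass
class CohortSurvival:
    hazard_ratio: float
    cox_p: float
    logrank_p: float
    n: int
    n_events: int
    testable: bool = True


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    endpoint = endpoint.lower()
    if endpoint not in {"efs", "os"}:
        raise ValueError("endpoint must be 'efs' or 'os'")
    return f"{endpoint}_time", f"{endpoint}_event"


def cohort_survival(
    indicators: pd.Series, clinical: pd.DataFrame, endpoint: str = "efs"
) -> CohortSurvival:
    """Survival association of a binary indicator in one cohort.

    ``indicators`` maps sample_id -> bool (positive indicator); ``clinical``
    rows are matched by sample_id.  Returns log-rank p (two-sided), Cox
    hazard ratio for positive vs negative and its Wald p, or a result
    flagged untestable when a group is empty or no event occurred.
    """
    tcol, ecol = _endpoint_columns(endpoint)
    clin = clinical.set_index("sample_id").loc[list(indicators.index)]
    time = clin[tcol].to_numpy(dtype=float)
    event = clin[ecol].to_numpy(dtype=int)
    g = np.asarray(indicators.to_numpy(), dtype=float)
    n, n_events = len(g), int(event.sum())
    if g.sum() == 0 or g.sum() == n or n_events == 0:
        return CohortSurvival(np.nan, np.nan, np.nan, n, n_events, testable=False)
    chi2, lr_p = logrank_test(time, event, g)
    beta, se, cox_p = cox_binary_breslow(time, event, g)
    return CohortSurvival(float(np.exp(beta)), cox_p, lr_p, n, n_events)


# --------------------------------------------------------------- meta step

def liptak_combine(p_values, weights) -> tuple[float, float]:
    """Liptak (weighted Stouffer on p-values) combination of one-sided p's.

    z_i = Phi^-1(1 - p_i); z = sum(w_i z_i)/sqrt(sum w_i^2); the returned
    p is the upper normal tail.  p of exactly 0 or 1 is clipped to the
    representable range with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape or p.size == 0:
        raise ValueError("p_values and weights must be equal-length, non-empty")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    eps = 1e-300
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values of exactly 0 or 1 clipped for the normal quantile")
        p = np.clip(p, eps, 1 - 1e-16)
    z = stats.norm.isf(p)
    z_comb = float((w * z).sum() / np.sqrt((w**2).sum()))
    return z_comb, float(stats.norm.sf(z_comb))


# ------------------------------------------------------------------ search

def _subset_medians(values: np.ndarray, gene_pos: dict[str, int], subsets):
    """Median log2 expression over each subset's measured genes, per sample.

    Returns (medians matrix len(subsets) x n_samples, testable mask).
    Subsets with no measured gene get NaN rows.
    """
    n = values.shape[1]
    out = np.full((len(subsets), n), np.nan)
    ok = np.zeros(len(subsets), dtype=bool)
    for i, sub in enumerate(subsets):
        rows = [gene_pos[g] for g in sub if g in gene_pos]
        if not rows:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN sample columns
            out[i] = np.nanmedian(values[rows], axis=0)
        ok[i] = np.isfinite(out[i]).all()
    return out, ok


def search_gsps(
    cohorts: list[ExpressionCohort],
    clinical: pd.DataFrame,
    pool_a: list[str],
    pool_b: list[str],
    endpoint: str = "efs",
    min_set_size: int = 2,
    per_cohort_alpha: float = 0.05,
    joint_fdr: float = 0.05,
) -> pd.DataFrame:
    """Exhaustive GSP search across training cohorts.

    Returns one row per enumerated pair with per-cohort log-rank statistics,
    the Liptak-combined one-sided p, the joint BH q over all pairs, Cox
    hazard ratios / Wald p for pairs surviving screening, the stratified
    Cox score at beta=0 (pooled over cohorts, used for the pool-orientation
    diagnostic) and the final ``selected`` flag.
    """
    pool_a, pool_b = sorted(pool_a), sorted(pool_b)
    subsets_a = list(_subsets(pool_a, min_set_size)) if len(pool_a) >= min_set_size else []
    subsets_b = list(_subsets(pool_b, min_set_size)) if len(pool_b) >= min_set_size else []
    if not subsets_a or not subsets_b:
        warnings.warn("empty enumeration: a pool is smaller than min_set_size")
        return pd.DataFrame()
    n_pairs = len(subsets_a) * len(subsets_b)
    tcol, ecol = _endpoint_columns(endpoint)
    clin = clinical.set_index("sample_id")

    cohort_names = [c.name for c in cohorts]
    U_all = np.zeros((len(cohorts), n_pairs))
    V_all = np.zeros((len(cohorts), n_pairs))
    testable = np.ones((len(cohorts), n_pairs), dtype=bool)
    weights = np.zeros(len(cohorts))
    surv_data = []

    indicator_cache = []
    for ci, cohort in enumerate(cohorts):
        meta = clin.loc[list(cohort.sample_ids)]
        time = meta[tcol].to_numpy(dtype=float)
        event = meta[ecol].to_numpy(dtype=int)
        surv_data.append((time, event))
        weights[ci] = np.sqrt(len(time))
        rt = _RiskTable(time, event)
        values = cohort.values.to_numpy(dtype=float)
        gene_pos = {g: i for i, g in enumerate(cohort.gene_ids)}
        med_a, ok_a = _subset_medians(values, gene_pos, subsets_a)
        med_b, ok_b = _subset_medians(values, gene_pos, subsets_b)
        # index > 0 -> positive indicator; ties and unscorable -> negative
        idx = med_a[:, None, :] - med_b[None, :, :]
        G = (idx > 0).reshape(n_pairs, -1).astype(float)
        pair_ok = (ok_a[:, None] & ok_b[None, :]).reshape(n_pairs)
        U, V = rt.score(G)
        degenerate = (G.sum(axis=1) == 0) | (G.sum(axis=1) == G.shape[1]) | (V <= 0)
        U_all[ci], V_all[ci] = U, V
        testable[ci] = pair_ok & ~degenerate
        indicator_cache.append(G)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(testable & (V_all > 0), U_all / np.sqrt(np.maximum(V_all, 1e-300)), 0.0)
        chi2 = z**2
    logrank_p = stats.chi2.sf(chi2, 1)
    one_sided = stats.norm.sf(z)

    liptak_z = (weights[:, None] * stats.norm.isf(np.clip(one_sided, 1e-300, 1 - 1e-16))).sum(
        axis=0
    ) / np.sqrt((weights**2).sum())
    liptak_p = stats.norm.sf(liptak_z)
    q_joint = bh_fdr(liptak_p)

    all_testable = testable.all(axis=0)
    screened = (
        all_testable
        & (q_joint < joint_fdr)
        & (z > 0).all(axis=0)
        & (logrank_p < per_cohort_alpha).all(axis=0)
    )

    records = {
        "poor_set": ["|".join(a) for a in subsets_a for _ in subsets_b],
        "good_set": ["|".join(b) for _ in subsets_a for b in subsets_b],
        "liptak_z": liptak_z,
        "liptak_p": liptak_p,
        "q_joint": q_joint,
        "strat_score": U_all.sum(axis=0),
        "testable": all_testable,
    }
    for ci, name in enumerate(cohort_names):
        records[f"logrank_p_{name}"] = logrank_p[ci]
        records[f"z_{name}"] = z[ci]
    df = pd.DataFrame(records)

    # full Cox fits only for screened pairs
    hr_cols = {name: np.full(n_pairs, np.nan) for name in cohort_names}
    coxp_cols = {name: np.full(n_pairs, np.nan) for name in cohort_names}
    for pi in np.flatnonzero(screened):
        for ci, name in enumerate(cohort_names):
            time, event = surv_data[ci]
            beta, se, p = cox_binary_breslow(time, event, indicator_cache[ci][pi])
            hr_cols[name][pi] = np.exp(beta)
            coxp_cols[name][pi] = p
    for name in cohort_names:
        df[f"hr_{name}"] = hr_cols[name]
        df[f"cox_p_{name}"] = coxp_cols[name]

    hr_ok = np.ones(n_pairs, dtype=bool)
    coxp_ok = np.ones(n_pairs, dtype=bool)
    for name in cohort_names:
        hr_ok &= np.nan_to_num(df[f"hr_{name}"].to_numpy(), nan=0.0) > 1.0
        coxp_ok &= np.nan_to_num(df[f"cox_p_{name}"].to_numpy(), nan=1.0) < per_cohort_alpha
    df["selected"] = screened & hr_ok & coxp_ok
    return df


def select_gsps(
    results: pd.DataFrame,
    cohort_names: list[str],
    per_cohort_alpha: float = 0.05,
    joint_fdr: float = 0.05,
) -> pd.DataFrame:
    """Apply the two selection criteria to a search table.

    selected <=> q_joint < joint_fdr AND, in every training cohort,
    HR > 1 AND log-rank p < alpha AND Cox p < alpha.
    """
    mask = results["q_joint"].to_numpy() < joint_fdr
    for name in cohort_names:
        mask &= np.nan_to_num(results[f"hr_{name}"].to_numpy(), nan=0.0) > 1.0
        mask &= np.nan_to_num(results[f"logrank_p_{name}"].to_numpy(), nan=1.0) < per_cohort_alpha
        mask &= np.nan_to_num(results[f"cox_p_{name}"].to_numpy(), nan=1.0) < per_cohort_alpha
    out = results.copy()
    out["selected"] = mask
    return out[out["selected"]]


# ------------------------------------------------------------- permutation

def empirical_pvalue(
    indicators: pd.Series,
    clinical: pd.DataFrame,
    endpoint: str = "efs",
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the log-rank statistic of one indicator.

    (time, event) pairs are permuted jointly across samples while the
    indicator stays fixed; the add-one estimator
    (1 + #{permuted chi2 >= observed}) / (1 + n_perm) is returned.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse empirical p-value grid")
    tcol, ecol = _endpoint_columns(endpoint)
    clin = clinical.set_index("sample_id").loc[list(indicators.index)]
    time = clin[tcol].to_numpy(dtype=float)
    event = clin[ecol].to_numpy(dtype=int)
    g = np.asarray(indicators.to_numpy(), dtype=float)
    obs, _ = logrank_test(time, event, g)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(time))
        chi2, _ = logrank_test(time[perm], event[perm], g)
        if chi2 >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


# -------------------------------------------------------------- diagnostics

def pool_orientation_check(strat_scores) -> tuple[float, float]:
    """Diagnostic: do enumerated pairs skew toward adverse (positive) effects?

    ``strat_scores`` are per-pair cohort-stratified Cox scores at beta=0
    (their sign equals the sign of the stratified Cox coefficient, since
    the partial likelihood is concave).  Returns the fraction of positive
    coefficients and a two-sided sign test p-value against 0.5.
    """
    s = np.asarray(strat_scores, dtype=float)
    s = s[s != 0]
    if s.size == 0:
        return 0.5, 1.0
    n_pos = int((s > 0).sum())
    frac = n_pos / s.size
    p = stats.binomtest(n_pos, s.size, 0.5).pvalue
    return frac, float(p)


# --------------------------------------------------------------------- KM

def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit table: (time, survival, n_at_risk).

    One row per distinct observed time; survival is the estimate just
    after that time, n_at_risk the count just before it.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    rows = []
    surv = 1.0
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append({"time": t[i], "survival": surv, "n_at_risk": at_risk})
        i = j
    return pd.DataFrame(rows)
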