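"""Retinoic-acid differentiation markers and the ddCt fold-change utility.

Three RA-treatment experiments each yield per-gene differential-expression
statistics; static contrasts are thresholded at FDR < 0.05 and linear fold
change > 1.5 (stricter per-experiment thresholds are configurable), a
time-course design is tested with a per-gene linear model F-test on the
treatment-involving terms, and the core differentiation-marker set is the
genes induced in at least ``min_support`` experiments and repressed in
none ("repeatedly induced without conflicts").  The same machinery with
directions swapped yields the de-differentiation (RA-repressed) control
set.  A comparative-Ct (ddCt) calculator converts RT-PCR cycle thresholds
into fold changes 2**(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection
from .meta_de import bh_fdr
from .variant_integration import overlap_fet

__all__ = [
    "CtMeasurements",
    "threshold_de",
    "timecourse_de",
    "core_set",
    "marker_overlap_report",
    "ddct_fold_change",
]


# ------------------------------------------------------------- static test

def threshold_de(
    stats_table: pd.DataFrame, fdr_max: float = 0.05, fc_min: float = 1.5
) -> pd.DataFrame:
    """Assign up/down/none directions from a per-gene stats table.

    ``stats_table`` needs columns ``log2_fc`` and ``q`` (gene_id index or
    column).  A gene is up when q < fdr_max and linear fold change
    2**log2_fc > fc_min; down when q < fdr_max and fold change < 1/fc_min.
    """
    df = stats_table.copy()
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    missing = {"log2_fc", "q"} - set(df.columns)
    if missing:
        raise ValueError(f"stats table missing columns {sorted(missing)}")
    fc = 2.0 ** df["log2_fc"].to_numpy(dtype=float)
    q = df["q"].to_numpy(dtype=float)
    direction = np.where(
        (q < fdr_max) & (fc > fc_min), "up",
        np.where((q < fdr_max) & (fc < 1.0 / fc_min), "down", "none"),
    )
    df["direction"] = direction
    return df


# -------------------------------------------------------------- time course

def timecourse_de(
    expr: pd.DataFrame,
    time: np.ndarray,
    treatment: np.ndarray,
    fdr_max: float = 0.05,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Per-gene linear-model F-test over a treated-vs-vehicle time course.

    ``expr`` is genes x samples (log2); ``time`` and ``treatment``
    (boolean, True = treated) annotate the columns.  The full model has
    time (categorical), treatment and treatment x time terms; the F-test
    compares it against the time-only model, so the p-value covers all
    treatment-involving terms.  Direction comes from the end-point
    (latest-time) fold change.
    """
    time = np.asarray(time, dtype=float)
    treatment = np.asarray(treatment, dtype=bool)
    if treatment.all() or (~treatment).all():
        raise ValueError("both treated and vehicle arms are required")
    levels = np.unique(time)
    if levels.size < 2:
        raise ValueError("need at least two time points")

    def dummies(cats):
        return np.column_stack([(time == lv).astype(float) for lv in cats[1:]])

    n = len(time)
    X_red = np.column_stack([np.ones(n), dummies(levels)])
    tr = treatment.astype(float)
    X_full = np.column_stack([X_red, tr, dummies(levels) * tr[:, None]])

    Y = expr.to_numpy(dtype=float).T  # samples x genes
    rss_red = _rss(X_red, Y)
    rss_full = _rss(X_full, Y)
    df_num = X_full.shape[1] - X_red.shape[1]
    df_den = n - X_full.shape[1]
    if df_den <= 0:
        raise ValueError("not enough replication for the full model")
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    p = stats.f.sf(F, df_num, df_den)
    p = np.where(np.isfinite(p), p, 1.0)

    last = time == levels[-1]
    log2_fc = (
        Y[last & treatment].mean(axis=0) - Y[last & ~treatment].mean(axis=0)
    )
    out = pd.DataFrame(
        {"log2_fc": log2_fc, "p": p, "q": bh_fdr(p)}, index=expr.index
    )
    return threshold_de(out, fdr_max=fdr_max, fc_min=fc_min)


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid**2).sum(axis=0)


# ---------------------------------------------------------------- core set

def core_set(
    up_sets: list[set], down_sets: list[set], min_support: int = 2
) -> list[str]:
    """Genes induced in >= min_support experiments and repressed in none.

    The "without conflicts" rule drops any gene that appears in a
    down-regulated set of any experiment, however strong its support.
    """
    if len(up_sets) < 2:
        raise ValueError("need at least two up-regulated sets")
    support: dict[str, int] = {}
    for s in up_sets:
        for g in s:
            support[g] = support.get(g, 0) + 1
    conflicted = set().union(*down_sets) if down_sets else set()
    return sorted(g for g, k in support.items() if k >= min_support and g not in conflicted)


# ---------------------------------------------------------------- overlaps

def marker_overlap_report(
    core: list[str],
    target_collections: GeneSetCollection,
    mutated: list[str],
    universe_size: int | None = None,
) -> dict:
    """Pairwise and triple overlaps of the core markers with target lists.

    For every target list in the collection: FET of core vs targets, of
    mutated vs targets, and the explicit triple intersection
    core & targets & mutated (the candidate tumor-suppressor markers).
    """
    universe = universe_size if universe_size is not None else target_collections.universe_size
    core_s, mut_s = set(core), set(mutated)
    report: dict = {"core_vs_mutated": overlap_fet(core_s, mut_s, universe).as_dict()}
    report["collections"] = {}
    for name in target_collections.names():
        targets = set(target_collections.sets[name])
        triple = sorted(core_s & targets & mut_s)
        report["collections"][name] = {
            "core_vs_targets": overlap_fet(core_s, targets, universe).as_dict(),
            "mutated_vs_targets": overlap_fet(mut_s, targets, universe).as_dict(),
            "triple_intersection": triple,
        }
    return report


# -------------------------------------------------------------------- ddCt

@dataclass
class CtMeasurements:
    """RT-PCR cycle thresholds for target and endogenous-control genes."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        vals = [
            self.ct_target_treated, self.ct_reference_treated,
            self.ct_target_calibrator, self.ct_reference_calibrator,
        ]
        if not np.isfinite(vals).all():
            raise ValueError("Ct values must be finite")


def ddct_fold_change(m: CtMeasurements) -> float:
    """Comparative-Ct relative quantity: fold change = 2**(-ddCt).

    dCt(treated) = Ct(target) - Ct(reference control); ddCt subtracts the
    calibrator sample's dCt, so a negative ddCt means induction.
    """
    dct_treated = m.ct_target_treated - m.ct_reference_treated
    dct_cal = m.ct_target_calibrator - m.ct_reference_calibrator
    return float(2.0 ** -(dct_treated - dct_cal))
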