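"""Synthetic multi-cohort study generator with planted ground truth.

Emulates the data structure the pipeline assumes: several cohorts of
high-risk neuroblastoma patients measured on two array platforms with
partial gene coverage, per-cohort batch distortions, genes differentially
expressed by MYCN amplification status, survival endpoints whose hazard
depends on a planted gene-set-pair indicator, a verified-variant table
whose recurrent genes concentrate in the signature, a GMT collection with
planted enrichment, and an interaction network with designated bottleneck
nodes.  Every random draw flows through one seeded generator, so equal
seeds give byte-identical outputs.

The survival model is exponential: log hazard = log(1) + planted_log_hr *
indicator, where the indicator is the relative-expression rule (median of
the planted poor set above the median of the planted good set) evaluated
on the clean, pre-batch expression.  Censoring is an independent
exponential administrative time calibrated so that a baseline-hazard
patient is censored with probability ``censoring_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CLINICAL_COLUMNS,
    ExpressionCohort,
    GeneSetCollection,
    GeneSetPair,
)
from .meta_de import bh_fdr

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_cohorts", "simulate_ra_series"]


@dataclass
class SimulationConfig:
    """Parameters of the planted multi-cohort simulation.

    Defaults mirror the study design the pipeline targets: four training
    cohorts of ~100 patients on two platforms, a two-set prognostic pair
    planted with log hazard ratio 1, and recurrent variants concentrated
    on twelve signature genes (six per pool, the fast search
    configuration).
    """

    n_genes: int = 2000
    n_cohorts: int = 4
    n_samples_per_cohort: int = 100
    platform_coverage: float = 0.9
    frac_ma_samples: float = 0.4
    n_ma_hi: int = 100
    n_mn_hi: int = 100
    de_effect: float = 1.0
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.1
    pool_size_unfavorable: int = 6
    pool_size_favorable: int = 6
    planted_pair: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    planted_log_hr: float = 1.0
    censoring_rate: float = 0.2
    n_variant_genes: int = 21
    recurrence_rate: float = 0.3
    n_batches_per_cohort: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cohorts <= 0 or self.n_samples_per_cohort <= 0:
            raise ValueError("sizes must be positive")
        if not (0 < self.platform_coverage <= 1):
            raise ValueError("platform_coverage must be in (0, 1]")
        if not (0 < self.frac_ma_samples < 1):
            raise ValueError("frac_ma_samples must be in (0, 1)")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.n_ma_hi + self.n_mn_hi > self.n_genes:
            raise ValueError("planted differential genes exceed n_genes")
        if self.pool_size_unfavorable > self.n_ma_hi or self.pool_size_favorable > self.n_mn_hi:
            raise ValueError("pool sizes exceed the planted differential gene counts")
        if self.planted_pair is not None:
            poor, good = self.planted_pair
            if set(poor) & set(good):
                raise ValueError("planted pair gene lists must be disjoint")


@dataclass
class SimulationTruth:
    """Everything planted, for recovery tests downstream."""

    ma_hi_genes: list[str]
    mn_hi_genes: list[str]
    pool_unfavorable: list[str]
    pool_favorable: list[str]
    planted_pair: GeneSetPair
    planted_log_hr: float
    batch_assignments: dict[str, str]
    bottleneck_nodes: list[str]
    indicator: dict[str, bool] = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cohorts(config: SimulationConfig):
    """Generate the full synthetic study.

    Returns (cohorts, clinical, variants, gene_sets, edges, truth):
    a list of :class:`ExpressionCohort`, the clinical table, the variant
    table, a :class:`GeneSetCollection` with planted enrichment, the
    network edge table, and the :class:`SimulationTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)

    ma_hi = genes[: config.n_ma_hi]
    mn_hi = genes[config.n_ma_hi: config.n_ma_hi + config.n_mn_hi]
    pool_unfav = ma_hi[: config.pool_size_unfavorable]
    pool_fav = mn_hi[: config.pool_size_favorable]
    if config.planted_pair is None:
        k_poor = min(3, len(pool_unfav))
        k_good = min(3, len(pool_fav))
        planted_pair = GeneSetPair(tuple(pool_unfav[:k_poor]), tuple(pool_fav[:k_good]))
    else:
        planted_pair = GeneSetPair(tuple(config.planted_pair[0]), tuple(config.planted_pair[1]))
    pool_genes = set(pool_unfav) | set(pool_fav) | set(planted_pair.poor_set) | set(
        planted_pair.good_set
    )
    for g in pool_genes:
        if g not in genes:
            raise ValueError(f"planted gene {g!r} not among the simulated genes")

    mu = rng.normal(7.0, 1.0, size=config.n_genes)
    sigma = rng.uniform(0.4, 1.2, size=config.n_genes)
    # pool genes share a common baseline so the planted index splits
    # patients by the MYCN-driven shifts rather than by arbitrary offsets
    # between the two sets' baseline medians (a degenerate planted truth)
    pool_rows = [i for i, g in enumerate(genes) if g in pool_genes]
    mu[pool_rows] = 7.0

    # two platforms; cohorts alternate; planted/pool genes always covered
    platform_of = {i: ("P1" if i % 2 == 0 else "P2") for i in range(config.n_cohorts)}
    coverage = {}
    must_cover = np.array([g in pool_genes for g in genes])
    for plat in ("P1", "P2"):
        mask = rng.random(config.n_genes) < config.platform_coverage
        coverage[plat] = mask | must_cover
    # every planted signature gene is measured on at least one platform
    signature = np.array([g in set(ma_hi) | set(mn_hi) for g in genes])
    orphan = signature & ~coverage["P1"] & ~coverage["P2"]
    if orphan.any():
        assign_p1 = rng.random(int(orphan.sum())) < 0.5
        idx = np.flatnonzero(orphan)
        coverage["P1"][idx[assign_p1]] = True
        coverage["P2"][idx[~assign_p1]] = True

    ma_idx = np.array([g in set(ma_hi) for g in genes])
    mn_idx = np.array([g in set(mn_hi) for g in genes])
    poor_rows = [genes.index(g) for g in planted_pair.poor_set]
    good_rows = [genes.index(g) for g in planted_pair.good_set]

    cohorts, clin_rows = [], []
    truth_batches: dict[str, str] = {}
    truth_indicator: dict[str, bool] = {}
    censor_rate = (
        config.censoring_rate / (1.0 - config.censoring_rate)
        if config.censoring_rate > 0 else 0.0
    )

    for ci in range(config.n_cohorts):
        cname = f"cohort{ci + 1}"
        plat = platform_of[ci]
        n = config.n_samples_per_cohort
        sample_ids = [f"{cname}_S{j + 1:03d}" for j in range(n)]
        is_ma = rng.random(n) < config.frac_ma_samples
        # guarantee both groups occur
        if is_ma.all():
            is_ma[0] = False
        if not is_ma.any():
            is_ma[0] = True

        signal = np.broadcast_to(mu[:, None], (config.n_genes, n)).copy()
        signal[np.ix_(ma_idx, is_ma)] += config.de_effect
        signal[np.ix_(mn_idx, ~is_ma)] += config.de_effect
        noise = sigma[:, None] * rng.standard_normal((config.n_genes, n))
        clean = signal + noise

        batches = np.array(
            [f"{cname}_b{(j % config.n_batches_per_cohort) + 1}" for j in rng.permutation(n)]
        )
        # location/scale batch model: Y = signal + gamma_bg + delta_bg * noise
        observed = clean.copy()
        for b in np.unique(batches):
            cols = batches == b
            shift = rng.normal(0.0, config.batch_shift_sd, size=config.n_genes)
            scale = np.exp(rng.normal(0.0, config.batch_scale_sd, size=config.n_genes))
            observed[:, cols] = (
                signal[:, cols] + shift[:, None] + scale[:, None] * noise[:, cols]
            )

        # The relative-expression index is a deterministic function of the
        # patient's measured profile, so the planted hazard is tied to the
        # indicator evaluated on the observed (batch-affected) expression.
        ind = np.median(observed[poor_rows], axis=0) > np.median(observed[good_rows], axis=0)

        hazard = np.exp(config.planted_log_hr * ind.astype(float))
        t_efs = rng.exponential(1.0 / hazard)
        t_os = rng.exponential(1.0 / hazard)  # independent OS draw, same planted effect
        if censor_rate > 0:
            c_efs = rng.exponential(1.0 / censor_rate, size=n)
            c_os = rng.exponential(1.0 / censor_rate, size=n)
        else:
            c_efs = np.full(n, np.inf)
            c_os = np.full(n, np.inf)
        efs_time = np.minimum(t_efs, c_efs)
        efs_event = (t_efs <= c_efs).astype(int)
        os_time = np.minimum(t_os, c_os)
        os_event = (t_os <= c_os).astype(int)

        covered = coverage[plat]
        values = pd.DataFrame(
            observed[covered],
            index=pd.Index(np.array(genes)[covered], name="gene_id"),
            columns=sample_ids,
        )
        cohorts.append(
            ExpressionCohort(
                values=values,
                name=cname,
                platform=plat,
                batch=pd.Series(batches, index=sample_ids),
                mycn_status=pd.Series(np.where(is_ma, "MA", "MN"), index=sample_ids),
            )
        )
        for j, sid in enumerate(sample_ids):
            truth_batches[sid] = batches[j]
            truth_indicator[sid] = bool(ind[j])
            clin_rows.append(
                {
                    "sample_id": sid, "cohort": cname, "platform": plat,
                    "batch": batches[j],
                    "mycn_status": "MA" if is_ma[j] else "MN",
                    "efs_time": efs_time[j], "efs_event": efs_event[j],
                    "os_time": os_time[j], "os_event": os_event[j],
                }
            )

    clinical = pd.DataFrame(clin_rows, columns=CLINICAL_COLUMNS)
    variants = _simulate_variants(rng, config, genes, ma_hi, mn_hi, pool_unfav, pool_fav)
    gene_sets = _simulate_gene_sets(rng, config, genes, ma_hi, mn_hi)
    edges, bottlenecks = _simulate_network(rng, ma_hi, mn_hi, pool_unfav, pool_fav)

    truth = SimulationTruth(
        ma_hi_genes=list(ma_hi), mn_hi_genes=list(mn_hi),
        pool_unfavorable=list(pool_unfav), pool_favorable=list(pool_fav),
        planted_pair=planted_pair, planted_log_hr=config.planted_log_hr,
        batch_assignments=truth_batches, bottleneck_nodes=bottlenecks,
        indicator=truth_indicator,
    )
    return cohorts, clinical, variants, gene_sets, edges, truth


def _simulate_variants(rng, config, genes, ma_hi, mn_hi, pool_unfav, pool_fav):
    """Recurrent verified variants concentrated on the signature pools.

    Pool genes receive >= 2 distinct cases each (Poisson-boosted); the
    remaining variant genes get 1 + Poisson(recurrence_rate) cases, so
    some are recurrent and some are not.  One favorable-pool gene also
    carries a germline GWAS record.
    """
    ma_set, mn_set = set(ma_hi), set(mn_hi)
    # background variant genes fall outside the signature, so the candidate
    # pools recovered downstream are exactly the planted signature genes
    other = [g for g in genes if g not in ma_set | mn_set]
    n_extra = max(config.n_variant_genes - len(pool_unfav) - len(pool_fav), 0)
    extra = list(rng.choice(other, size=min(n_extra, len(other)), replace=False))
    rows = []
    case_counter = [0]
    classifications = ["Missense", "Missense", "Missense", "Nonsense", "Frame_Shift_Del"]
    methods = ["PCR/MiSeq", "PCR/HiSeq", "Sequenom", "PCR/Sanger"]

    def add_rows(gene, n_cases, gwas=False):
        klass = "MA-hi" if gene in ma_set else ("MN-hi" if gene in mn_set else "NA")
        for _ in range(n_cases):
            case_counter[0] += 1
            rows.append(
                {
                    "gene_symbol": gene, "class": klass,
                    "case_id": f"CASE-{case_counter[0]:04d}",
                    "chromosome": str(rng.integers(1, 23)),
                    "position": int(rng.integers(1_000_000, 200_000_000)),
                    "variant_classification": "GWAS SNP" if gwas else str(rng.choice(classifications)),
                    "mycn_status": str(rng.choice(["amp", "non-amp"])),
                    "verification_method": "GWAS" if gwas else str(rng.choice(methods)),
                }
            )

    for gene in list(pool_unfav) + list(pool_fav):
        add_rows(gene, 2 + int(rng.poisson(2 * config.recurrence_rate)))
    if pool_fav:
        add_rows(pool_fav[-1], 1, gwas=True)
    for gene in extra:
        add_rows(gene, 1 + int(rng.poisson(config.recurrence_rate)))
    return pd.DataFrame(rows)


def _simulate_gene_sets(rng, config, genes, ma_hi, mn_hi, n_random_sets: int = 20):
    """GMT collection: one set enriched for each signature arm plus noise."""
    sets: dict[str, list[str]] = {}
    half = 25
    sets["PLANTED_MA_SET"] = sorted(
        set(rng.choice(ma_hi, size=min(half, len(ma_hi)), replace=False))
        | set(rng.choice(genes, size=half, replace=False))
    )
    sets["PLANTED_MN_SET"] = sorted(
        set(rng.choice(mn_hi, size=min(half, len(mn_hi)), replace=False))
        | set(rng.choice(genes, size=half, replace=False))
    )
    for i in range(n_random_sets):
        size = int(rng.integers(20, 80))
        sets[f"RANDOM_SET_{i + 1:02d}"] = sorted(rng.choice(genes, size=size, replace=False))
    return GeneSetCollection(sets=sets, source="synthetic", universe_size=config.n_genes)


def _simulate_network(rng, ma_hi, mn_hi, pool_unfav, pool_fav, cluster_size: int = 25):
    """Two dense clusters whose only bridge runs through the bottleneck pair.

    Every shortest path between the clusters crosses both designated
    bottleneck nodes (cluster_a - hub_a - hub_b - cluster_b), while each
    hub fans out to several cluster members so that no single gateway
    node inherits the bridge load; the hubs are therefore the
    unambiguous top-betweenness nodes.
    """
    cluster_a = list(ma_hi[-cluster_size:])
    cluster_b = list(mn_hi[-cluster_size:])
    hub_a, hub_b = pool_unfav[0], pool_fav[0]
    rows = []

    def dense(cluster, p=0.3, edge_type="ppi"):
        for i, a in enumerate(cluster):
            for b in cluster[i + 1:]:
                if rng.random() < p:
                    rows.append({"node_a": a, "node_b": b, "edge_type": edge_type})
        # ring to guarantee connectivity
        for a, b in zip(cluster, cluster[1:] + cluster[:1]):
            rows.append({"node_a": a, "node_b": b, "edge_type": edge_type})

    dense(cluster_a)
    dense(cluster_b)
    n_fan = min(5, cluster_size)
    for node in cluster_a[:n_fan]:
        rows.append({"node_a": hub_a, "node_b": node, "edge_type": "tf_target"})
    for node in cluster_b[:n_fan]:
        rows.append({"node_a": hub_b, "node_b": node, "edge_type": "tf_target"})
    rows.append({"node_a": hub_a, "node_b": hub_b, "edge_type": "ppi"})
    edges = pd.DataFrame(rows).drop_duplicates(subset=["node_a", "node_b"])
    return edges, [hub_a, hub_b]


# ----------------------------------------------------------------- RA series

def simulate_ra_series(
    n_genes: int,
    n_experiments: int = 3,
    n_induced: int = 50,
    n_repressed: int = 30,
    seed: int = 0,
    n_replicates: int = 4,
    effect: float = 2.0,
    noise_sd: float = 0.3,
):
    """Per-experiment differential-expression stats with planted responders.

    Each experiment compares ``n_replicates`` treated vs vehicle samples.
    Every planted induced gene is up-regulated in at least two experiments
    and never down; repressed genes mirror this.  The default planted
    effect is 2 log2 units (4-fold), the strength of a clearly induced
    differentiation marker, so planted responders are genuinely induced
    rather than borderline relative to the fold-change threshold.
    Returns (stats_tables, induced_truth, repressed_truth) where each
    stats table has columns log2_fc, p, q indexed by gene.
    """
    if n_experiments < 2:
        raise ValueError("need at least two experiments")
    if n_induced + n_repressed > n_genes:
        raise ValueError("planted responder counts exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    induced = genes[:n_induced]
    repressed = genes[n_induced: n_induced + n_repressed]

    effect_matrix = np.zeros((n_genes, n_experiments))
    for gi, gene in enumerate(induced):
        support = rng.choice(n_experiments, size=int(rng.integers(2, n_experiments + 1)),
                             replace=False)
        effect_matrix[gi, support] = effect
    for gi in range(n_induced, n_induced + n_repressed):
        support = rng.choice(n_experiments, size=int(rng.integers(2, n_experiments + 1)),
                             replace=False)
        effect_matrix[gi, support] = -effect

    from scipy import stats as sps

    tables = []
    base = rng.normal(7.0, 1.0, size=n_genes)
    for e in range(n_experiments):
        control = base[:, None] + rng.normal(0, noise_sd, size=(n_genes, n_replicates))
        treated = (
            base[:, None]
            + effect_matrix[:, e][:, None]
            + rng.normal(0, noise_sd, size=(n_genes, n_replicates))
        )
        t, p = sps.ttest_ind(treated, control, axis=1, equal_var=False)
        log2_fc = treated.mean(axis=1) - control.mean(axis=1)
        tables.append(
            pd.DataFrame(
                {"log2_fc": log2_fc, "p": p, "q": bh_fdr(p)},
                index=pd.Index(genes, name="gene_id"),
            )
        )
    return tables, list(induced), list(repressed)
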