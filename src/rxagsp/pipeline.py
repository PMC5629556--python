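"""End-to-end orchestration of the integrative prognostic analysis.

Stages run in dependency order — simulate, de-meta, variants, gsp-search,
enrich, network, ra-core — each reading and writing the shared plain-text
formats, and a JSON run manifest records parameters, counts and output
checksums so that two runs with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, meta_de, variant_integration
from .datatypes import GeneSetPair
from .enrichment_concurrence import enrich, enrichment_table, pathway_concurrence
from .gsp_prognosis import empirical_pvalue, km_curve, pool_orientation_check, search_gsps
from .network_bottleneck import betweenness_rank, build_graph, scores_table
from .ra_differentiation import core_set, threshold_de
from .synthetic_data import SimulationConfig, simulate_cohorts, simulate_ra_series

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run.

    Threshold defaults are the published operating points of the analysis:
    signature FDR 0.001, joint survival FDR 0.05, per-cohort alpha 0.05,
    enrichment OR > 2 at FDR < 0.01, fold-change cut 1.5, candidate
    universe ~21k protein-coding genes (replaced by the measured gene
    count when ``universe_from_data``), minimum set size 2.
    """

    outdir: str = "pipeline_out"
    seed: int = 17
    endpoint: str = "efs"
    fdr_de: float = 0.001
    fdr_joint: float = 0.05
    alpha_cohort: float = 0.05
    or_min: float = 2.0
    fdr_enrich: float = 0.01
    fc_min: float = 1.5
    universe: int = 21000
    universe_from_data: bool = True
    min_set_size: int = 2
    n_perm: int = 1000
    simulation: dict = field(default_factory=dict)
    ra_series: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("fdr_de", "fdr_joint", "alpha_cohort", "fdr_enrich"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.endpoint.lower() not in {"efs", "os"}:
            raise ValueError("endpoint must be efs or os")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, params: dict, counts: dict, files: list[Path]):
        manifest["stages"][stage] = {
            "params": params,
            "counts": counts,
            "outputs": {f.name: _sha256(f) for f in files},
        }
        log.info("stage %s done: %s", stage, counts)

    # ------------------------------------------------------------ simulate
    sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
    cohorts, clinical, variants, gene_sets, edges, truth = simulate_cohorts(sim_cfg)
    files = []
    for c in cohorts:
        p = out / f"expr_{c.name}.tsv"
        io.write_expression(c.values, p)
        files.append(p)
    p_clin, p_var = out / "clinical.tsv", out / "variants.tsv"
    p_gmt, p_edges = out / "gene_sets.gmt", out / "edges.tsv"
    io.write_clinical(clinical, p_clin)
    io.write_variants(variants, p_var)
    io.write_gmt(gene_sets, p_gmt)
    io.write_edges(edges, p_edges)
    p_truth = out / "truth.json"
    p_truth.write_text(json.dumps(
        {
            "ma_hi_genes": truth.ma_hi_genes, "mn_hi_genes": truth.mn_hi_genes,
            "pool_unfavorable": truth.pool_unfavorable,
            "pool_favorable": truth.pool_favorable,
            "planted_pair": [list(truth.planted_pair.poor_set), list(truth.planted_pair.good_set)],
            "planted_log_hr": truth.planted_log_hr,
            "bottleneck_nodes": truth.bottleneck_nodes,
        },
        indent=1,
    ))
    files += [p_clin, p_var, p_gmt, p_edges, p_truth]
    record("simulate", asdict(sim_cfg),
           {"n_cohorts": len(cohorts), "n_samples": len(clinical),
            "n_variant_records": len(variants)}, files)

    # ------------------------------------------------------------- de-meta
    expr_by_cohort = {c.name: io.read_expression(out / f"expr_{c.name}.tsv") for c in cohorts}
    clinical_df = io.read_clinical(p_clin)
    cohort_objs = io.cohorts_from_frames(expr_by_cohort, clinical_df)
    meta, ma_hi, mn_hi = meta_de.run_meta_de(cohort_objs, fdr_threshold=config.fdr_de)
    p_meta = out / "meta_de.tsv"
    meta_out = meta.drop(columns=["fc_signs", "platforms_covering"], errors="ignore")
    meta_out.to_csv(p_meta, sep="\t", float_format="%.6g")
    p_ma, p_mn = out / "ma_hi.txt", out / "mn_hi.txt"
    io.write_gene_list(ma_hi, p_ma)
    io.write_gene_list(mn_hi, p_mn)
    record("de-meta", {"fdr": config.fdr_de},
           {"n_genes_tested": len(meta), "n_ma_hi": len(ma_hi), "n_mn_hi": len(mn_hi)},
           [p_meta, p_ma, p_mn])

    # ------------------------------------------------------------ variants
    var_df = io.read_variants(p_var)
    recurrent = variant_integration.recurrent_genes(var_df)
    universe = len(meta) if config.universe_from_data else config.universe
    overlap = variant_integration.overlap_fet(
        var_df["gene_symbol"].unique(), ma_hi + mn_hi, universe_size=universe
    )
    pools = variant_integration.build_candidate_pools((ma_hi, mn_hi), recurrent)
    p_pools, p_overlap = out / "pools.tsv", out / "variant_overlap.json"
    pools.as_frame().to_csv(p_pools, sep="\t", index=False)
    p_overlap.write_text(json.dumps(overlap.as_dict(), indent=1))
    record("variants", {"min_cases": 2, "universe": universe},
           {"n_recurrent": len(recurrent),
            "pool_unfavorable": len(pools.unfavorable_pool),
            "pool_favorable": len(pools.favorable_pool)},
           [p_pools, p_overlap])

    # ---------------------------------------------------------- gsp-search
    pools_df = pd.read_csv(p_pools, sep="\t")
    pool_a = pools_df.loc[pools_df["pool"] == "unfavorable", "gene_id"].tolist()
    pool_b = pools_df.loc[pools_df["pool"] == "favorable", "gene_id"].tolist()
    results = search_gsps(
        cohort_objs, clinical_df, pool_a, pool_b,
        endpoint=config.endpoint, min_set_size=config.min_set_size,
        per_cohort_alpha=config.alpha_cohort, joint_fdr=config.fdr_joint,
    )
    results = results.sort_values("liptak_p", kind="stable").reset_index(drop=True)
    p_gsp = out / "gsp_results.tsv"
    results.to_csv(p_gsp, sep="\t", index=False, float_format="%.6g")
    frac_pos, sign_p = pool_orientation_check(results["strat_score"]) if len(results) else (0.5, 1.0)
    gsp_files = [p_gsp]
    counts = {
        "n_pairs": len(results),
        "n_selected": int(results["selected"].sum()) if len(results) else 0,
        "orientation_fraction_positive": round(frac_pos, 4),
        "orientation_sign_p": sign_p,
    }
    if len(results) and results["selected"].any():
        top = results[results["selected"]].iloc[0]
        pair = GeneSetPair(tuple(top["poor_set"].split("|")), tuple(top["good_set"].split("|")))
        ind_rows, km_frames = [], []
        for c in cohort_objs:
            poor = [g for g in pair.poor_set if g in c.gene_ids]
            good = [g for g in pair.good_set if g in c.gene_ids]
            idx = (
                c.values.loc[poor].median(axis=0) - c.values.loc[good].median(axis=0)
            )
            for sid, v in idx.items():
                ind_rows.append(
                    {"sample_id": sid, "cohort": c.name, "index_value": v,
                     "indicator": "positive" if v > 0 else "negative"}
                )
        ind_df = pd.DataFrame(ind_rows)
        p_ind = out / "top_pair_indicators.tsv"
        ind_df.to_csv(p_ind, sep="\t", index=False, float_format="%.6g")
        clin_idx = clinical_df.set_index("sample_id")
        tcol, ecol = f"{config.endpoint}_time", f"{config.endpoint}_event"
        for label, grp in ind_df.groupby("indicator"):
            sub = clin_idx.loc[grp["sample_id"]]
            km = km_curve(sub[tcol].to_numpy(), sub[ecol].to_numpy())
            km["group"] = label
            km_frames.append(km)
        p_km = out / "top_pair_km.tsv"
        pd.concat(km_frames).to_csv(p_km, sep="\t", index=False, float_format="%.6g")
        # permutation p in the first cohort for the top selected pair
        c0 = cohort_objs[0]
        ind0 = ind_df[ind_df["cohort"] == c0.name].set_index("sample_id")
        emp_p = empirical_pvalue(
            ind0["indicator"] == "positive", clinical_df,
            endpoint=config.endpoint, n_perm=config.n_perm, seed=config.seed,
        )
        counts["top_pair"] = str(pair)
        counts["top_pair_empirical_p_cohort1"] = emp_p
        gsp_files += [p_ind, p_km]
    record("gsp-search",
           {"endpoint": config.endpoint, "min_set_size": config.min_set_size,
            "alpha": config.alpha_cohort, "fdr": config.fdr_joint, "n_perm": config.n_perm},
           counts, gsp_files)

    # --------------------------------------------------------------- enrich
    collection = io.read_gmt(p_gmt, universe_size=gene_sets.universe_size)
    enr_mn = enrich(mn_hi, collection, or_min=config.or_min, fdr_max=config.fdr_enrich)
    enr_var = enrich(sorted(var_df["gene_symbol"].unique()), collection,
                     or_min=config.or_min, fdr_max=config.fdr_enrich)
    t_mn, t_var = enrichment_table(enr_mn), enrichment_table(enr_var)
    p_enr_mn, p_enr_var = out / "enrichment_mn_hi.tsv", out / "enrichment_variants.tsv"
    t_mn.to_csv(p_enr_mn, sep="\t", index=False, float_format="%.6g")
    t_var.to_csv(p_enr_var, sep="\t", index=False, float_format="%.6g")
    conc = pathway_concurrence(
        [r.set_name for r in enr_mn if r.enriched],
        [r.set_name for r in enr_var if r.enriched],
        n_pathways=len(collection),
    )
    p_conc = out / "pathway_concurrence.json"
    p_conc.write_text(json.dumps(conc.as_dict(), indent=1))
    record("enrich", {"or_min": config.or_min, "fdr": config.fdr_enrich},
           {"n_enriched_mn_hi": int(t_mn["enriched"].sum()) if len(t_mn) else 0,
            "n_enriched_variants": int(t_var["enriched"].sum()) if len(t_var) else 0},
           [p_enr_mn, p_enr_var, p_conc])

    # -------------------------------------------------------------- network
    graph = build_graph(io.read_edges(p_edges))
    scores = betweenness_rank(graph, top_k=20)
    p_nodes = out / "bottlenecks.tsv"
    scores_table(scores).to_csv(p_nodes, sep="\t", index=False, float_format="%.6g")
    record("network", {"top_k": 20},
           {"n_nodes": graph.number_of_nodes(), "n_edges": graph.number_of_edges(),
            "top_bottleneck": scores[0].node},
           [p_nodes])

    # -------------------------------------------------------------- ra-core
    ra_cfg = {"n_genes": 1000, "n_experiments": 3, "n_induced": 50,
              "n_repressed": 30, **config.ra_series}
    tables, induced_truth, _ = simulate_ra_series(seed=config.seed + 1, **ra_cfg)
    up_sets, down_sets = [], []
    for tab in tables:
        called = threshold_de(tab, fdr_max=0.05, fc_min=config.fc_min)
        up_sets.append(set(called.index[called["direction"] == "up"]))
        down_sets.append(set(called.index[called["direction"] == "down"]))
    core = core_set(up_sets, down_sets, min_support=2)
    p_core = out / "ra_core_set.txt"
    io.write_gene_list(core, p_core)
    recovered = len(set(core) & set(induced_truth)) / max(len(induced_truth), 1)
    record("ra-core", ra_cfg,
           {"n_core": len(core), "planted_recovery": round(recovered, 4)},
           [p_core])

    p_manifest = out / "manifest.json"
    p_manifest.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
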