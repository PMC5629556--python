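"""Gene-set enrichment by Fisher's exact test and pathway-level concurrence.

Enrichment of a query gene list against a GMT collection uses the same
one-sided hypergeometric overlap statistic as the variant/signature
integration, with a BH FDR across tested sets and the selection rule
odds ratio > 2 and FDR < 0.01 (sets larger than 2000 genes are skipped).
Concurrence asks whether the *names* of the sets enriched for two
different signatures overlap more than chance within a finite pathway
universe (e.g. 185 KEGG pathways).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .datatypes import GeneSetCollection, OverlapStat
from .meta_de import bh_fdr
from .variant_integration import overlap_fet

__all__ = ["EnrichmentResult", "enrich", "enrichment_table", "pathway_concurrence"]


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: OverlapStat
    q_value: float
    enriched: bool


def enrich(
    query,
    collection: GeneSetCollection,
    or_min: float = 2.0,
    fdr_max: float = 0.01,
    max_set_size: int = 2000,
    universe_size: int | None = None,
) -> list[EnrichmentResult]:
    """Test a query gene list against every set of a collection.

    Sets larger than ``max_set_size`` are skipped; q-values are BH over the
    tested sets (deterministic alphabetical order).  A set is ``enriched``
    when OR > or_min and q < fdr_max.
    """
    query = sorted(set(query))
    if not query:
        raise ValueError("query gene list is empty")
    universe = universe_size if universe_size is not None else collection.universe_size
    names = [n for n in collection.names() if len(collection.sets[n]) <= max_set_size]
    if not names:
        return []
    stats_ = [overlap_fet(query, collection.sets[n], universe) for n in names]
    q = bh_fdr([s.p_value for s in stats_])
    return [
        EnrichmentResult(
            set_name=n,
            overlap=s,
            q_value=float(qv),
            enriched=bool(s.odds_ratio > or_min and qv < fdr_max),
        )
        for n, s, qv in zip(names, stats_, q)
    ]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = r.overlap.as_dict()
        rows.append(
            {
                "set_name": r.set_name,
                "a": d["a"], "b": d["b"], "c": d["c"], "d": d["d"],
                "odds_ratio": d["odds_ratio"], "p_value": d["p_value"],
                "q_value": r.q_value, "enriched": r.enriched,
            }
        )
    return pd.DataFrame(rows)


def pathway_concurrence(
    enriched_a, enriched_b, n_pathways: int = 185
) -> OverlapStat:
    """FET on enriched-pathway *names* against the pathway universe.

    Both lists must come from the same collection; reports enrichment or
    depletion according to the sample odds ratio.
    """
    a, b = set(enriched_a), set(enriched_b)
    if len(a | b) > n_pathways:
        raise ValueError("pathway union exceeds the stated pathway universe")
    return overlap_fet(a, b, universe_size=n_pathways, alternative="auto")
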