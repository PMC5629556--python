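"""Integration of recurrent verified variants with the expression signature.

The verified-variant table (one row per variant observation, gene symbol +
case id + verification method) is reduced to genes with recurrent support,
overlap with the MA_hi / MN_hi signature is scored by a one-sided
Fisher's-exact (hypergeometric) test against a protein-coding universe of
~21k genes, and the two candidate pools that seed the gene-set-pair search
are emitted: unfavorable = MA_hi genes with recurrent variants, favorable =
MN_hi genes with recurrent variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .datatypes import OverlapStat
from .io import read_variants as load_variants  # re-exported module surface

__all__ = [
    "load_variants",
    "recurrent_genes",
    "overlap_fet",
    "build_candidate_pools",
    "CandidatePools",
]


@dataclass
class CandidatePools:
    """The two signature-anchored candidate pools for the GSP search."""

    unfavorable_pool: list[str]  # MA_hi genes with recurrent variants
    favorable_pool: list[str]    # MN_hi genes with recurrent variants

    def as_frame(self) -> pd.DataFrame:
        rows = [(g, "unfavorable") for g in self.unfavorable_pool]
        rows += [(g, "favorable") for g in self.favorable_pool]
        return pd.DataFrame(rows, columns=["gene_id", "pool"])


def recurrent_genes(variants: pd.DataFrame, min_cases: int = 2) -> list[str]:
    """Genes with variant records in >= ``min_cases`` distinct cases.

    Germline GWAS hits count as recurrent population-level evidence and
    pass the filter regardless of case count.
    """
    kept = set()
    for gene, grp in variants.groupby("gene_symbol"):
        if grp["case_id"].nunique() >= min_cases:
            kept.add(gene)
        elif (
            grp["verification_method"].str.contains("GWAS", case=False, na=False).any()
            or grp["variant_classification"].str.contains("GWAS", case=False, na=False).any()
        ):
            kept.add(gene)
    return sorted(kept)


def overlap_fet(
    set_a, set_b, universe_size: int = 21000, alternative: str = "greater"
) -> OverlapStat:
    """One-sided Fisher's exact test for overlap between two gene lists.

    With ``alternative="greater"`` (the default, over-representation) the
    p-value is the upper hypergeometric tail P(X >= a); ``"less"`` tests
    depletion with the lower tail; ``"auto"`` picks the tail matching the
    sample odds ratio (used for pathway-concurrence reporting, where both
    enrichment and depletion are of interest).  The OR is the plain sample
    estimate a*d/(b*c), ``inf`` when b*c = 0 with a > 0, and 0 when there
    is no overlap.
    """
    sa, sb = set(set_a), set(set_b)
    if universe_size < len(sa | sb):
        raise ValueError("universe_size smaller than the union of the two sets")
    a = len(sa & sb)
    na, nb = len(sa), len(sb)
    b, c = na - a, nb - a
    d = universe_size - na - nb + a

    if a == 0:
        odds = 0.0
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = a * d / (b * c)

    direction = "enriched" if odds >= 1 else "depleted"
    if alternative == "auto":
        alternative = "greater" if odds >= 1 else "less"
    hg = stats.hypergeom(universe_size, na, nb)
    if alternative == "greater":
        p = float(hg.sf(a - 1))  # P(X >= a)
    elif alternative == "less":
        p = float(hg.cdf(a))  # P(X <= a)
    else:
        raise ValueError("alternative must be 'greater', 'less' or 'auto'")
    return OverlapStat(
        a=a, set_a_size=na, set_b_size=nb, universe_size=universe_size,
        odds_ratio=odds, p_value=min(p, 1.0), direction=direction,
    )


def build_candidate_pools(
    signature: tuple[list[str], list[str]], recurrent: list[str]
) -> CandidatePools:
    """Intersect the signature calls with the recurrent-variant genes.

    Returns alphabetically ordered pools for determinism; warns when a pool
    is too small to seed any gene-set pair.
    """
    ma_hi, mn_hi = signature
    rec = set(recurrent)
    pools = CandidatePools(
        unfavorable_pool=sorted(set(ma_hi) & rec),
        favorable_pool=sorted(set(mn_hi) & rec),
    )
    if len(pools.unfavorable_pool) < 2 or len(pools.favorable_pool) < 2:
        warnings.warn("a candidate pool has fewer than 2 genes; GSP search will be empty")
    return pools
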