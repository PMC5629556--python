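"""Shared in-memory containers used across the pipeline.

Expression is always log2 scale, genes in rows, samples in columns.
Clinical and variant tables are plain pandas DataFrames with documented
column schemas (see :mod:`rxagsp.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: clinical TSV column order
CLINICAL_COLUMNS = [
    "sample_id", "cohort", "platform", "batch", "mycn_status",
    "efs_time", "efs_event", "os_time", "os_event",
]

#: variant TSV column order (recurrent-candidate table schema)
VARIANT_COLUMNS = [
    "gene_symbol", "class", "case_id", "chromosome", "position",
    "variant_classification", "mycn_status", "verification_method",
]


@dataclass
class ExpressionCohort:
    """One cohort's log2 expression matrix plus per-sample annotations.

    Parameters
    ----------
    values
        genes x samples DataFrame of finite log2 intensities; the index is
        the gene-symbol namespace shared by all cohorts.
    name
        Cohort label; becomes the batch label when cohorts are pooled.
    platform
        Measurement platform label. Gene content may differ by platform.
    batch
        Per-sample batch label (defaults to the cohort name).
    mycn_status
        Per-sample MYCN copy-number group, ``"MA"`` (amplified, >10 copies)
        or ``"MN"`` (normal, 2 copies).
    """

    values: pd.DataFrame
    name: str
    platform: str
    batch: pd.Series
    mycn_status: pd.Series

    def __post_init__(self) -> None:
        self.batch = pd.Series(self.batch, index=self.values.columns)
        self.mycn_status = pd.Series(self.mycn_status, index=self.values.columns)
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r} in cohort {self.name!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(f"non-finite expression values in cohort {self.name!r}")
        bad = set(self.mycn_status.unique()) - {"MA", "MN"}
        if bad:
            raise ValueError(f"unknown MYCN status labels {sorted(bad)}")
        if self.batch.isna().any() or self.mycn_status.isna().any():
            raise ValueError("every sample needs a batch and a MYCN status")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionCohort":
        return ExpressionCohort(
            self.values.copy(), self.name, self.platform,
            self.batch.copy(), self.mycn_status.copy(),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. one GMT file) plus the enrichment universe size."""

    sets: dict[str, list[str]]
    source: str = ""
    universe_size: int = 21000

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return sorted(self.sets)


@dataclass(frozen=True)
class GeneSetPair:
    """An ordered pair of disjoint gene sets: (poor-outcome, good-outcome).

    A patient is index-positive when the median log2 expression of the
    poor-outcome set exceeds that of the good-outcome set within the
    patient's own profile; the rule is therefore rank-based and free of
    cross-cohort normalisation.
    """

    poor_set: tuple[str, ...]
    good_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.poor_set) & set(self.good_set):
            raise ValueError("poor_set and good_set must be disjoint")

    def __str__(self) -> str:
        return f"{'|'.join(self.poor_set)} vs {'|'.join(self.good_set)}"


@dataclass
class OverlapStat:
    """2x2 overlap of two gene (or pathway) lists against a finite universe.

    ``odds_ratio`` is the sample OR a*d/(b*c); ``p_value`` is the one-sided
    hypergeometric tail in the reported ``direction``.
    """

    a: int
    set_a_size: int
    set_b_size: int
    universe_size: int
    odds_ratio: float
    p_value: float
    direction: str  # "enriched" | "depleted"

    @property
    def table(self) -> np.ndarray:
        b = self.set_a_size - self.a
        c = self.set_b_size - self.a
        d = self.universe_size - self.set_a_size - self.set_b_size + self.a
        return np.array([[self.a, b], [c, d]])

    def as_dict(self) -> dict:
        b, c = self.set_a_size - self.a, self.set_b_size - self.a
        d = self.universe_size - self.set_a_size - self.set_b_size + self.a
        return {
            "a": self.a, "b": b, "c": c, "d": d,
            "set_a_size": self.set_a_size, "set_b_size": self.set_b_size,
            "universe_size": self.universe_size,
            "odds_ratio": self.odds_ratio, "p_value": self.p_value,
            "direction": self.direction,
        }
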