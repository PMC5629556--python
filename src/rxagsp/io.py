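"""Readers and writers for the plain-text formats shared by all stages.

Formats
-------
expression TSV
    First column ``gene_id``, remaining columns one per sample, log2 scale.
clinical TSV
    Columns ``sample_id, cohort, platform, batch, mycn_status, efs_time,
    efs_event, os_time, os_event``; mycn_status in {MA, MN}.
variant TSV
    Columns ``gene_symbol, class, case_id, chromosome, position,
    variant_classification, mycn_status, verification_method``.
GMT
    Standard tab-separated gene-set format: name, description, genes...
edge TSV
    Columns ``node_a, node_b, edge_type`` with edge_type in {ppi, tf_target}.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from .datatypes import (
    CLINICAL_COLUMNS,
    VARIANT_COLUMNS,
    ExpressionCohort,
    GeneSetCollection,
)


# ---------------------------------------------------------------- expression

def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    if first != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {first!r}")
    return df.set_index("gene_id")


def write_expression(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


# ------------------------------------------------------------------ clinical

def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    return df


def write_clinical(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def cohorts_from_frames(
    expr_by_cohort: dict[str, pd.DataFrame], clinical: pd.DataFrame
) -> list[ExpressionCohort]:
    """Assemble :class:`ExpressionCohort` objects from raw tables.

    ``clinical`` supplies platform, batch and MYCN status per sample; each
    expression frame's columns must appear in the clinical table under the
    matching cohort label.
    """
    clin = clinical.set_index("sample_id")
    cohorts = []
    for name in sorted(expr_by_cohort):
        expr = expr_by_cohort[name]
        meta = clin.loc[expr.columns]
        platforms = meta["platform"].unique()
        if len(platforms) != 1:
            raise ValueError(f"cohort {name!r} spans several platforms: {platforms}")
        cohorts.append(
            ExpressionCohort(
                values=expr,
                name=name,
                platform=platforms[0],
                batch=meta["batch"],
                mycn_status=meta["mycn_status"],
            )
        )
    return cohorts


# ------------------------------------------------------------------ variants

def read_variants(path: str | os.PathLike) -> pd.DataFrame:
    """Parse the recurrent-candidate variant TSV; see module docstring."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "gene_symbol" not in header:
            raise ValueError(f"{path}:1: missing 'gene_symbol' column")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=header)
    if "position" in df.columns:
        df["position"] = pd.to_numeric(df["position"], errors="coerce")
        if (df["position"].dropna() <= 0).any():
            raise ValueError(f"{path}: positions must be positive (1-based)")
    if (df["gene_symbol"].str.len() == 0).any():
        raise ValueError(f"{path}: empty gene_symbol")
    return df


def write_variants(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------- GMT

def read_gmt(path: str | os.PathLike, universe_size: int = 21000) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, description, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets=sets, source=str(path), universe_size=universe_size)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            genes = collection.sets[name]
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


# --------------------------------------------------------------------- edges

def read_edges(path: str | os.PathLike) -> pd.DataFrame:
    """Read an edge TSV (node_a, node_b, edge_type) or a 3-column SIF file."""
    df = pd.read_csv(path, sep="\t")
    if set(df.columns) >= {"node_a", "node_b"}:
        if "edge_type" not in df.columns:
            df["edge_type"] = "ppi"
        return df[["node_a", "node_b", "edge_type"]]
    # SIF: source <relation> target
    sif = pd.read_csv(path, sep="\t", header=None, names=["node_a", "edge_type", "node_b"])
    return sif[["node_a", "node_b", "edge_type"]]


def write_edges(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["node_a", "node_b", "edge_type"]].to_csv(path, sep="\t", index=False)


def write_sif(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["node_a", "edge_type", "node_b"]].to_csv(path, sep="\t", index=False, header=False)


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
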