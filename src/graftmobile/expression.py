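"""FPKM normalization and differential expressed gene (DEG) calling."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .delta import delta_table
from .design import resident_heterograft


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM = counts * 1e9 / (per-sample total * feature length).  ``totals``
    defaults to the column sums of ``counts``.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("feature lengths must be positive for every feature")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any() or totals.isna().any():
        raise ValueError("per-sample read totals must be positive")
    return counts.mul(1e9).div(totals, axis=1).div(lengths, axis=0)


def call_degs(
    expression: pd.DataFrame,
    species: str,
    tissue: str,
    threshold: float = 2.0,
    pseudocount: float = 1.0,
    aggregate: str = "mean",
    log_space: bool = True,
) -> pd.DataFrame:
    """Delta-of-delta DEG table for one species' genes in one tissue.

    The heterograft group is the combination in which ``species`` is the
    resident partner of ``tissue`` (its scion for leaf, its rootstock for
    root); the homograft group is ``species/species``.  Genes with
    statistic > ``threshold`` are upregulated DEGs, < -``threshold``
    downregulated.
    """
    scion, rootstock = resident_heterograft(species, tissue)
    return delta_table(
        expression,
        het_graft=f"{scion}/{rootstock}",
        homo_graft=f"{species}/{species}",
        tissue=tissue,
        threshold=threshold,
        pseudocount=pseudocount,
        aggregate=aggregate,
        log_space=log_space,
    )


def deg_sets(deg_table: pd.DataFrame) -> dict[str, set[str]]:
    """Venn-ready id sets of up- and down-regulated features."""
    return {
        "up": set(deg_table.loc[deg_table["call"] == "up", "feature"]),
        "down": set(deg_table.loc[deg_table["call"] == "down", "feature"]),
    }
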