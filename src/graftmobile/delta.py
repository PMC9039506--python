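"""The heterograft-vs-homograft delta-of-delta contrast.

Both differential genes (on FPKM) and differential metabolites (on ion
intensity) are called with the same two-step contrast:

* delta1 = log2 fold change of the heterograft over the matched homograft
  in the *control* condition,
* delta2 = the same fold change under *chilling*,
* statistic = delta2 - delta1, thresholded at ±2 (i.e. a 4-fold change of
  the het/homo ratio between conditions).

Fold changes are computed on replicate-aggregated group means with a
pseudocount guarding zeros: delta = log2(mean_het + pc) - log2(mean_homo + pc).
A raw-space mode (plain difference of group means, thresholded at ±2^t on
the magnitude) is available for sensitivity checks.

This module is the single implementation behind both the DEG and DIM
callers and behind the contrast vectors used for transcript-metabolite
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CHILLING, CONTROL, GraftSample

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass(frozen=True)
class DeltaResult:
    """Per-feature delta-of-delta outcome."""

    feature: str
    tissue: str
    delta1: float
    delta2: float
    statistic: float
    call: str


def _aggregate(values: np.ndarray, how: str) -> float:
    if how == "mean":
        return float(np.mean(values))
    if how == "median":
        return float(np.median(values))
    raise ValueError(f"unknown replicate aggregation {how!r}")


def log2_contrast(
    het: np.ndarray,
    homo: np.ndarray,
    pseudocount: float = 1.0,
    aggregate: str = "mean",
) -> float:
    """log2 fold change of aggregated heterograft over homograft values."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    m_het = _aggregate(np.asarray(het, dtype=float), aggregate)
    m_homo = _aggregate(np.asarray(homo, dtype=float), aggregate)
    if pseudocount == 0 and (m_het <= 0 or m_homo <= 0):
        raise ValueError("zero group mean with pseudocount 0; contrast undefined")
    return math.log2(m_het + pseudocount) - math.log2(m_homo + pseudocount)


def delta_statistic(
    het_control,
    homo_control,
    het_chilling,
    homo_chilling,
    feature: str = "",
    tissue: str = "",
    threshold: float = 2.0,
    pseudocount: float = 1.0,
    aggregate: str = "mean",
    log_space: bool = True,
) -> DeltaResult:
    """Compute delta1, delta2 and the delta-of-delta statistic for one feature.

    With ``log_space`` (default) the deltas are log2 fold changes and the
    statistic is their difference, called up when > ``threshold`` and down
    when < -``threshold``.  In raw mode the deltas are plain differences of
    group means and the call thresholds the statistic at ±2**``threshold``.
    """
    if log_space:
        d1 = log2_contrast(het_control, homo_control, pseudocount, aggregate)
        d2 = log2_contrast(het_chilling, homo_chilling, pseudocount, aggregate)
        stat = d2 - d1
        cut = threshold
    else:
        d1 = _aggregate(np.asarray(het_control, dtype=float), aggregate) - _aggregate(
            np.asarray(homo_control, dtype=float), aggregate
        )
        d2 = _aggregate(np.asarray(het_chilling, dtype=float), aggregate) - _aggregate(
            np.asarray(homo_chilling, dtype=float), aggregate
        )
        stat = d2 - d1
        cut = 2.0**threshold
    call = UP if stat > cut else DOWN if stat < -cut else NONE
    return DeltaResult(feature, tissue, d1, d2, stat, call)


def _group_columns(columns) -> dict[tuple[str, str, str], list[str]]:
    """Map (graft, tissue, condition) to the sample columns of that group."""
    groups: dict[tuple[str, str, str], list[str]] = {}
    for col in columns:
        s = GraftSample.from_key(col)
        groups.setdefault((s.graft, s.tissue, s.condition), []).append(col)
    return groups


def delta_table(
    matrix: pd.DataFrame,
    het_graft: str,
    homo_graft: str,
    tissue: str,
    threshold: float = 2.0,
    pseudocount: float = 1.0,
    aggregate: str = "mean",
    log_space: bool = True,
) -> pd.DataFrame:
    """Delta-of-delta results for every feature of a matrix (features x samples).

    ``het_graft`` and ``homo_graft`` are scion/rootstock strings such as
    ``"Csa/Cmo"`` and ``"Csa/Csa"``.  All four groups (het/homo x
    control/chilling) must be present; a missing group raises with its name.
    """
    groups = _group_columns(matrix.columns)
    needed = {}
    for graft in (het_graft, homo_graft):
        for condition in (CONTROL, CHILLING):
            key = (graft, tissue, condition)
            if key not in groups:
                raise ValueError(f"missing sample group {graft} {tissue} {condition}")
            needed[key] = groups[key]
    rows = []
    for feature in matrix.index:
        values = {
            key: matrix.loc[feature, cols].to_numpy(dtype=float)
            for key, cols in needed.items()
        }
        res = delta_statistic(
            values[(het_graft, tissue, CONTROL)],
            values[(homo_graft, tissue, CONTROL)],
            values[(het_graft, tissue, CHILLING)],
            values[(homo_graft, tissue, CHILLING)],
            feature=feature,
            tissue=tissue,
            threshold=threshold,
            pseudocount=pseudocount,
            aggregate=aggregate,
            log_space=log_space,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows, columns=["feature", "tissue", "delta1", "delta2", "statistic", "call"])


def contrast_log2fc(
    matrix: pd.DataFrame,
    pseudocount: float = 1.0,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Heterograft-vs-resident-homograft log2FC vectors for correlation.

    For every heterograft cell (graft x tissue) present in the matrix
    columns and every condition, computes log2(mean het + pc) - log2(mean
    homo + pc) against the homograft of the tissue's resident species.
    Returns features x contrast keys, keys named ``graft.tissue.condition``.
    Contrasts whose homograft group is absent are skipped.
    """
    groups = _group_columns(matrix.columns)
    keys = []
    for (graft, tissue, condition) in sorted(groups):
        scion, rootstock = graft.split("/")
        if scion == rootstock:
            continue
        resident = scion if tissue == "leaf" else rootstock
        homo_key = (f"{resident}/{resident}", tissue, condition)
        if homo_key in groups:
            keys.append(((graft, tissue, condition), homo_key))
    data = {}
    for (het_key, homo_key) in keys:
        name = f"{het_key[0]}.{het_key[1]}.{het_key[2]}"
        het = matrix[groups[het_key]].to_numpy(dtype=float)
        homo = matrix[groups[homo_key]].to_numpy(dtype=float)
        agg = np.mean if aggregate == "mean" else np.median
        data[name] = np.log2(agg(het, axis=1) + pseudocount) - np.log2(
            agg(homo, axis=1) + pseudocount
        )
    return pd.DataFrame(data, index=matrix.index)
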