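"""Metabolome-side analysis: DIM calling, R/Z filtering, clustering, PCA.

Differentially intense metabolites (DIMs) reuse the delta-of-delta contrast
from :mod:`graftmobile.delta` on ion intensities.  The clustering-set filter
works on a different, per-combination quantity: for each tissue x graft
combination the chilling/control intensity ratio R and its log2, Z, are
computed, and a metabolite is retained when its Z profile passes the
configured rule.  Retained profiles are min-max normalized or clustered
hierarchically; a PCA summary reports scores, explained variance and the
strongest positive and negative loadings per component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .delta import delta_table, _group_columns
from .design import CHILLING, CONTROL, resident_heterograft

logger = logging.getLogger(__name__)

#: retain when every contrast is strongly up or every contrast strongly down
RULE_LITERAL = "zmin_gt2_or_zmax_ltm2"
#: retain when any contrast is strongly changed (the permissive variant)
RULE_ANY_EXTREME = "zmax_gt2_or_zmin_ltm2"


def call_dims(
    intensity: pd.DataFrame,
    species: str,
    tissue: str,
    threshold: float = 2.0,
    pseudocount: float = 1.0,
    aggregate: str = "mean",
    log_space: bool = True,
) -> pd.DataFrame:
    """Delta-of-delta DIM table for one tissue, contrasted in ``species`` tissues.

    Same statistic and thresholds as DEG calling; the heterograft is the
    combination where ``species`` is resident in ``tissue``, the homograft
    is ``species/species``.
    """
    scion, rootstock = resident_heterograft(species, tissue)
    return delta_table(
        intensity,
        het_graft=f"{scion}/{rootstock}",
        homo_graft=f"{species}/{species}",
        tissue=tissue,
        threshold=threshold,
        pseudocount=pseudocount,
        aggregate=aggregate,
        log_space=log_space,
    )


def fold_change_rz(
    intensity: pd.DataFrame,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Chilling/control ratio R and Z = log2(R) per tissue x combination.

    Returns a long table (metabolite, contrast, R, Z); contrast keys are
    ``graft.tissue``.  Metabolites with a zero control group mean and
    ``pseudocount`` 0 are excluded from the affected contrast with a log
    entry.
    """
    groups = _group_columns(intensity.columns)
    cells = sorted({(g, t) for (g, t, _) in groups})
    rows = []
    for graft, tissue in cells:
        ctrl_key, chill_key = (graft, tissue, CONTROL), (graft, tissue, CHILLING)
        if ctrl_key not in groups or chill_key not in groups:
            continue
        ctrl = intensity[groups[ctrl_key]].mean(axis=1) + pseudocount
        chill = intensity[groups[chill_key]].mean(axis=1) + pseudocount
        for m in intensity.index:
            c, h = float(ctrl[m]), float(chill[m])
            if c <= 0 or h <= 0:
                logger.info(
                    "metabolite %s excluded from contrast %s.%s: non-positive group mean",
                    m,
                    graft,
                    tissue,
                )
                continue
            r = h / c
            rows.append({"metabolite": m, "contrast": f"{graft}.{tissue}", "R": r, "Z": np.log2(r)})
    return pd.DataFrame(rows, columns=["metabolite", "contrast", "R", "Z"])


def select_cluster_set(
    intensity: pd.DataFrame,
    rule: str = RULE_LITERAL,
    pseudocount: float = 0.0,
) -> tuple[list[str], pd.DataFrame]:
    """Metabolites retained for clustering by their Z profile, plus R/Z records.

    The default rule retains a metabolite when min(Z) > 2 or max(Z) < -2,
    i.e. when every single combination shows a strong, same-signed chilling
    response.  ``RULE_ANY_EXTREME`` (max(Z) > 2 or min(Z) < -2) retains any
    metabolite with at least one strong response.
    """
    records = fold_change_rz(intensity, pseudocount=pseudocount)
    retained: list[str] = []
    for m, grp in records.groupby("metabolite", sort=False):
        z = grp["Z"].to_numpy()
        if rule == RULE_LITERAL:
            keep = z.min() > 2 or z.max() < -2
        elif rule == RULE_ANY_EXTREME:
            keep = z.max() > 2 or z.min() < -2
        else:
            raise ValueError(f"unknown retention rule {rule!r}")
        if keep:
            retained.append(m)
    retained = [m for m in intensity.index if m in set(retained)]
    return retained, records


def minmax_normalize(values) -> pd.DataFrame:
    """Min-max normalization x* = (x - min) / (max - min) over a sample set.

    Returns a table with the original value, the normalized value and the
    extremes; raises on a constant vector (undefined denominator).
    """
    series = pd.Series(values, dtype=float)
    lo, hi = float(series.min()), float(series.max())
    if hi == lo:
        raise ValueError("constant vector: min-max normalization undefined")
    out = pd.DataFrame(
        {
            "x": series,
            "x_star": (series - lo) / (hi - lo),
        }
    )
    out["min"] = lo
    out["max"] = hi
    return out


def cluster_metabolites(fold_changes: pd.DataFrame, k: int = 8) -> pd.Series:
    """Agglomerative clustering of log2 fold-change profiles into k clusters.

    Average linkage on Euclidean distances; the dendrogram is cut to exactly
    ``k`` flat clusters, labelled 1..k.  Input rows are metabolites, columns
    contrast keys.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(fold_changes):
        raise ValueError(f"k={k} exceeds the {len(fold_changes)} rows available")
    if not np.isfinite(fold_changes.to_numpy(dtype=float)).all():
        raise ValueError("fold-change matrix must be finite")
    linkage = hierarchy.linkage(fold_changes.to_numpy(dtype=float), method="average", metric="euclidean")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=fold_changes.index, name="cluster")


@dataclass
class PcaSummary:
    """Sample scores, variance fractions and extreme loadings of a PCA."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame
    top_positive: dict[str, pd.Series]
    top_negative: dict[str, pd.Series]


def pca_summary(matrix: pd.DataFrame, n_components: int = 2, top_k: int = 10) -> PcaSummary:
    """Column-centered PCA of a samples x features matrix.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so outputs are reproducible across linear-algebra
    backends.  ``top_k`` larger than the feature count is truncated with a
    warning.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    x = matrix.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("rank-0 matrix: no variance to decompose")
    if top_k > matrix.shape[1]:
        warnings.warn(
            f"top_k={top_k} exceeds {matrix.shape[1]} features; truncating", stacklevel=2
        )
        top_k = matrix.shape[1]
    n_components = min(n_components, min(matrix.shape))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x - x.mean(axis=0))
    loadings = pca.components_.T  # features x components
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=comp_names)
    loadings_df = pd.DataFrame(loadings, index=matrix.columns, columns=comp_names)
    top_pos = {c: loadings_df[c].sort_values(ascending=False).head(top_k) for c in comp_names}
    top_neg = {c: loadings_df[c].sort_values().head(top_k) for c in comp_names}
    return PcaSummary(
        scores=scores_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings_df,
        top_positive=top_pos,
        top_negative=top_neg,
    )
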