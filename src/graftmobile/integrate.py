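"""Joining mobile mRNAs, DEGs and DIMs into enrichment tables and networks.

The joins are the ones a multi-omics grafting study needs: best-hit global
alignment maps each mobile transcript to its homolog in the other species;
Pearson correlation of het-vs-homo log2 fold-change contrast vectors links
genes to metabolites; pathway identifiers are the common vocabulary for
enrichment and for requiring that a mobile mRNA and a DEG act in the same
pathway before drawing an edge between them.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from Bio import Align
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EDGE_MOBILE_DEG = "mobile-deg"
EDGE_DEG_DIM = "deg-dim"
EDGE_MOBILE_PATHWAY = "mobile-pathway"


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def best_hit_orthology(
    fasta_a: dict[str, str], fasta_b: dict[str, str]
) -> pd.DataFrame:
    """One-to-one ortholog map by best-hit global alignment score.

    For every species-A sequence the highest-scoring species-B sequence is
    taken (ties to the lexicographically smallest B id); B-ids hit by
    several A-ids keep only the highest-scoring pair (ties to the smallest
    A id).  Empty sequences are skipped with a log entry.
    """
    if not fasta_a or not fasta_b:
        raise ValueError("both FASTA inputs must be non-empty")
    aligner = _aligner()
    hits = []
    for id_a in sorted(fasta_a):
        seq_a = fasta_a[id_a]
        if not seq_a:
            logger.info("skipping empty sequence %s", id_a)
            continue
        best_score, best_b = None, None
        for id_b in sorted(fasta_b):
            seq_b = fasta_b[id_b]
            if not seq_b:
                logger.info("skipping empty sequence %s", id_b)
                continue
            score = aligner.score(seq_a, seq_b)
            if best_score is None or score > best_score:
                best_score, best_b = score, id_b
        if best_b is not None:
            hits.append((id_a, best_b, float(best_score)))
    frame = pd.DataFrame(hits, columns=["id_a", "id_b", "score"])
    # deduplicate: one A per B, highest score wins, ties to smallest id_a
    frame = frame.sort_values(["id_b", "score", "id_a"], ascending=[True, False, True])
    frame = frame.drop_duplicates("id_b", keep="first").sort_values("id_a").reset_index(drop=True)
    return frame


def correlate_deg_dim(
    gene_fc: pd.DataFrame,
    metabolite_fc: pd.DataFrame,
    min_points: int = 4,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Pearson correlation edges between gene and metabolite contrast vectors.

    Both inputs are features x contrast-key tables of log2 fold changes
    (see :func:`graftmobile.delta.contrast_log2fc`).  For each gene the
    correlation is computed over the contrast keys it shares with the
    metabolite table (NaN entries dropped); pairs with fewer than
    ``min_points`` shared keys or a zero-variance vector are skipped with a
    log entry.  Edges are emitted where \\|cor\\| >= ``threshold``.
    """
    edges = []
    for gene in gene_fc.index:
        gvec = gene_fc.loc[gene].dropna()
        keys = [k for k in gvec.index if k in metabolite_fc.columns]
        if len(keys) < min_points:
            logger.info("gene %s skipped: only %d shared contrasts", gene, len(keys))
            continue
        g = gvec[keys].to_numpy(dtype=float)
        if np.std(g) == 0:
            logger.info("gene %s skipped: zero-variance contrast vector", gene)
            continue
        g0 = g - g.mean()
        gnorm = np.sqrt((g0**2).sum())
        mets = metabolite_fc[keys].to_numpy(dtype=float)
        m0 = mets - mets.mean(axis=1, keepdims=True)
        mnorm = np.sqrt((m0**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            cors = (m0 @ g0) / (mnorm * gnorm)
        for m_id, cor, sd in zip(metabolite_fc.index, cors, mnorm):
            if sd == 0:
                logger.info("pair (%s, %s) skipped: zero-variance metabolite", gene, m_id)
                continue
            if abs(cor) >= threshold:
                edges.append(
                    {
                        "gene": gene,
                        "metabolite": m_id,
                        "cor": float(cor),
                        "sign": 1 if cor > 0 else -1,
                    }
                )
    return pd.DataFrame(edges, columns=["gene", "metabolite", "cor", "sign"]).sort_values(
        ["gene", "metabolite"], ignore_index=True
    )


def pathway_enrichment(
    feature_set: set[str],
    annotation: pd.DataFrame,
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways in a feature set.

    ``annotation`` has columns ``feature`` and ``pathway`` and must cover
    the background.  For each pathway with hits in the set, the upper-tail
    hypergeometric probability of seeing at least that many hits is
    computed, followed by Benjamini-Hochberg adjustment; rows are sorted by
    ascending p.
    """
    if not feature_set:
        raise ValueError("feature set is empty")
    if not feature_set <= background:
        raise ValueError("feature set must be a subset of the background")
    ann = annotation[annotation["feature"].isin(background)]
    bg_size = len(background)
    set_size = len(feature_set)
    rows = []
    for pathway, grp in ann.groupby("pathway"):
        members = set(grp["feature"])
        bg_hits = len(members)
        hits = len(members & feature_set)
        p = float(hypergeom.sf(hits - 1, bg_size, bg_hits, set_size))
        rows.append(
            {
                "pathway": pathway,
                "hits": hits,
                "set_size": set_size,
                "background_hits": bg_hits,
                "background_size": bg_size,
                "p": p,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["pathway", "hits", "set_size", "background_hits", "background_size", "p"]
    )
    if frame.empty:
        frame["p_adj"] = []
        return frame
    frame["p_adj"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame.sort_values(["p", "pathway"], ignore_index=True)


def venn_overlap(sets: list[set[str]], names: list[str] | None = None) -> pd.DataFrame:
    """Exact region cardinalities of up to four sets.

    One row per non-empty membership pattern; ``region`` is a tuple of 0/1
    flags aligned with ``names`` and ``count`` the number of elements whose
    membership matches it exactly.
    """
    if len(sets) > 4:
        raise ValueError("at most 4 sets supported")
    if names is None:
        names = [f"set{i + 1}" for i in range(len(sets))]
    universe = set().union(*sets) if sets else set()
    rows = []
    for pattern in itertools.product((1, 0), repeat=len(sets)):
        if not any(pattern):
            continue
        members = universe
        for s, flag in zip(sets, pattern):
            members = members & s if flag else members - s
        rows.append({"region": pattern, "count": len(members)})
    frame = pd.DataFrame(rows, columns=["region", "count"])
    frame.attrs["names"] = names
    return frame


def build_network(
    mobile: pd.DataFrame,
    degs: pd.DataFrame,
    orthology: pd.DataFrame,
    correlations: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Typed edge list joining mobile mRNAs, DEGs and DIMs.

    * ``mobile-deg``: a mobile transcript whose ortholog (either direction
      of the orthology map) is a called DEG and shares at least one pathway
      id with it.
    * ``deg-dim``: a correlation edge whose gene is a called DEG, signed by
      the correlation.

    Dangling ids (correlation genes absent from the DEG table) are dropped
    with a logged count.  Output is sorted by ids for determinism.
    """
    deg_ids = set(degs.loc[degs["call"].isin(["up", "down"]), "feature"])
    mobile_ids = set(mobile.loc[mobile["is_mobile"], "transcript"]) if len(mobile) else set()
    pathways_of: dict[str, set[str]] = {
        f: set(grp["pathway"]) for f, grp in annotation.groupby("feature")
    }
    ortho: dict[str, str] = {}
    for row in orthology.itertuples(index=False):
        ortho[row.id_a] = row.id_b
        ortho[row.id_b] = row.id_a

    edges = []
    for m in sorted(mobile_ids):
        g = ortho.get(m)
        if g is None or g not in deg_ids:
            continue
        if pathways_of.get(m, set()) & pathways_of.get(g, set()):
            edges.append({"source": m, "target": g, "edge_type": EDGE_MOBILE_DEG, "sign": 0})

    dropped = 0
    for row in correlations.itertuples(index=False):
        if row.gene not in deg_ids:
            dropped += 1
            continue
        edges.append(
            {"source": row.gene, "target": row.metabolite, "edge_type": EDGE_DEG_DIM, "sign": row.sign}
        )
    if dropped:
        logger.info("dropped %d correlation edges whose gene is not a DEG", dropped)
    frame = pd.DataFrame(edges, columns=["source", "target", "edge_type", "sign"])
    return frame.sort_values(["edge_type", "source", "target"], ignore_index=True)


def to_networkx(edges: pd.DataFrame):
    """The edge list as a networkx graph (edge attributes: type, sign)."""
    import networkx as nx

    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_edge(row.source, row.target, edge_type=row.edge_type, sign=row.sign)
    return graph


def write_sif(edges: pd.DataFrame, path) -> None:
    """Simple interaction format: source <tab> edge type <tab> target."""
    lines = [f"{r.source}\t{r.edge_type}\t{r.target}" for r in edges.itertuples(index=False)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
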