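"""Canonical synthetic study conditions used for validation.

These functions freeze the study designs the package is validated against:
a mobility-recovery run over 30 homolog pairs with eight planted mobile
transcripts, a noiseless delta-of-delta round trip at transcriptome /
metabolome scale, and a single planted mobile -> ortholog-DEG ->
correlated-DIM chain.  They are ordinary library code — the same generator
and callers users run — packaged so tests and reproduction scripts exercise
identical conditions.
"""

from __future__ import annotations

import pandas as pd

from .simulate import (
    GraftDataset,
    MobilePlanEntry,
    SimulationConfig,
    generate_dataset,
    make_expression_tables,
    make_metabolite_tables,
    TruthTable,
)

#: eight planted mobile transcripts covering both species, both heterograft
#: orientations, both tissues and both conditions, 30 foreign reads per replicate
STANDARD_MOBILITY_PLAN = [
    MobilePlanEntry("Csa_0001", "Csa", "Cmo", "root", "chilling", 30),
    MobilePlanEntry("Csa_0002", "Cmo", "Csa", "leaf", "chilling", 30),
    MobilePlanEntry("Csa_0003", "Csa", "Cmo", "root", "control", 30),
    MobilePlanEntry("Csa_0004", "Cmo", "Csa", "leaf", "control", 30),
    MobilePlanEntry("Cmo_0005", "Csa", "Cmo", "leaf", "chilling", 30),
    MobilePlanEntry("Cmo_0006", "Cmo", "Csa", "root", "chilling", 30),
    MobilePlanEntry("Cmo_0007", "Csa", "Cmo", "leaf", "control", 30),
    MobilePlanEntry("Cmo_0008", "Cmo", "Csa", "root", "control", 30),
]


def mobility_recovery_scenario(seed: int, error_rate: float = 0.0) -> GraftDataset:
    """Thirty 500-b homolog pairs at 1% divergence, 150-bp reads, depth 20."""
    config = SimulationConfig(
        n_pairs=30,
        transcript_length=500,
        divergence_rate=0.01,
        read_length=150,
        depth=20.0,
        error_rate=error_rate,
        n_replicates=3,
        seed=seed,
    )
    return generate_dataset(config, mobility_plan=list(STANDARD_MOBILITY_PLAN))


def mobility_precision_recall(calls: pd.DataFrame, truth: TruthTable) -> tuple[float, float]:
    """Precision and recall of mobile calls against the planted truth."""
    found = {
        (r.transcript, r.origin, r.graft, r.tissue, r.condition)
        for r in calls.itertuples(index=False)
        if r.is_mobile
    }
    planted = truth.mobile_truth
    tp = len(found & planted)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(planted) if planted else 1.0
    return precision, recall


def pooled_mobility_recall(
    base_seed: int, n_runs: int = 10, error_rate: float = 0.005
) -> tuple[float, float, int]:
    """Precision and recall pooled over replicate simulations of the scenario.

    With eight planted transcripts a single run quantizes recall in steps of
    1/8, so the recovery rate is estimated over ``n_runs`` independent
    simulations (seeds derived from ``base_seed``), pooling all planted
    events.  Returns (precision, recall, number of planted events).
    """
    from .origin import call_mobile_transcripts, pairs_from_map

    tp_prec_num = found_total = tp = planted_total = 0
    for i in range(n_runs):
        ds = mobility_recovery_scenario(seed=base_seed + 7919 * i, error_rate=error_rate)
        pairs = pairs_from_map(ds.references, ds.pair_map)
        calls = call_mobile_transcripts(ds.reads, pairs)
        found = {
            (r.transcript, r.origin, r.graft, r.tissue, r.condition)
            for r in calls.itertuples(index=False)
            if r.is_mobile
        }
        tp += len(found & ds.truth.mobile_truth)
        planted_total += len(ds.truth.mobile_truth)
        tp_prec_num += len(found & ds.truth.mobile_truth)
        found_total += len(found)
    precision = tp_prec_num / found_total if found_total else 1.0
    recall = tp / planted_total if planted_total else 1.0
    return precision, recall, planted_total


#: planted delta-of-delta effects: 20 above the ±2 threshold, 6 below it
ROUNDTRIP_GENE_EFFECTS = [
    ("Csa_0001", "leaf", 3.0), ("Csa_0002", "leaf", -4.0), ("Csa_0003", "leaf", 2.5),
    ("Csa_0004", "root", -2.6), ("Csa_0005", "root", 5.0), ("Csa_0006", "root", 2.2),
    ("Csa_0007", "leaf", -3.3), ("Csa_0008", "root", -4.4), ("Csa_0009", "leaf", 4.1),
    ("Csa_0010", "root", 2.8),
    ("Cmo_0001", "leaf", -3.0), ("Cmo_0002", "leaf", 4.0), ("Cmo_0003", "leaf", -2.5),
    ("Cmo_0004", "root", 2.6), ("Cmo_0005", "root", -5.0), ("Cmo_0006", "root", -2.2),
    ("Cmo_0007", "leaf", 3.3), ("Cmo_0008", "root", 4.4), ("Cmo_0009", "leaf", -4.1),
    ("Cmo_0010", "root", -2.8),
    # sub-threshold effects the caller must leave uncalled
    ("Csa_0011", "leaf", 1.0), ("Csa_0012", "root", -1.5), ("Cmo_0011", "leaf", 1.9),
    ("Cmo_0012", "root", -0.5), ("Csa_0013", "leaf", 0.8), ("Cmo_0013", "root", 1.2),
]

ROUNDTRIP_DIM_EFFECTS = [
    ("met_0001", "leaf", 3.0), ("met_0002", "leaf", -3.5), ("met_0003", "root", 4.0),
    ("met_0004", "root", -2.4), ("met_0005", "leaf", 2.7), ("met_0006", "root", 5.0),
    ("met_0007", "leaf", -4.2), ("met_0008", "root", -2.9), ("met_0009", "leaf", 3.8),
    ("met_0010", "root", 2.1), ("met_0011", "leaf", -5.0), ("met_0012", "root", 3.3),
    ("met_0013", "leaf", 2.6), ("met_0014", "root", -3.1), ("met_0015", "leaf", 4.6),
    # sub-threshold
    ("met_0016", "leaf", 1.4), ("met_0017", "root", -1.9), ("met_0018", "leaf", 0.3),
]


def delta_roundtrip_scenario(
    seed: int, n_genes: int = 500, n_metabolites: int = 300
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, TruthTable, list, list]:
    """Noiseless expression and intensity tables with planted effects.

    Returns (expression tables by species, intensity table, merged truth,
    gene effects, metabolite effects).
    """
    genes = {
        sp: [f"{sp}_{i:04d}" for i in range(1, n_genes + 1)] for sp in ("Csa", "Cmo")
    }
    expression, truth = make_expression_tables(
        genes, ROUNDTRIP_GENE_EFFECTS, noise_sd=0.0, seed=seed
    )
    metabolites = [f"met_{i:04d}" for i in range(1, n_metabolites + 1)]
    intensity, dim_truth = make_metabolite_tables(
        metabolites, ROUNDTRIP_DIM_EFFECTS, [], noise_sd=0.0, seed=seed + 1
    )
    truth.merge(dim_truth)
    return expression, intensity, truth, ROUNDTRIP_GENE_EFFECTS, ROUNDTRIP_DIM_EFFECTS


def chain_scenario(seed: int) -> GraftDataset:
    """One planted mobile -> ortholog-DEG -> positively correlated DIM chain."""
    config = SimulationConfig(
        n_pairs=10, transcript_length=400, depth=15.0, seed=seed
    )
    return generate_dataset(
        config,
        mobility_plan=[MobilePlanEntry("Cmo_0005", "Cmo", "Csa", "root", "chilling", 30)],
        planted_effects=[("Csa_0005", "leaf", 3.0), ("Csa_0005", "root", 1.5)],
        planted_correlations=[("Csa_0005", "met_0010", 1)],
        n_metabolites=12,
        enriched_pathway_plan={"map00042": ["Cmo_0005", "Csa_0005"]},
    )
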