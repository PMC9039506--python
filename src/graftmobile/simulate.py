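"""Synthetic heterograft dataset generator with planted ground truth.

Emulates the raw inputs of a reciprocal grafting study between two species
("Csa", cucumber-like, and "Cmo", pumpkin-like):

* homologous transcript pairs that differ only by substitutions at a
  tunable divergence rate (the diagnostic sites used for per-read species
  assignment);
* 150-bp single-end reads per graft sample, drawn from the tissue's
  resident transcripts plus any transcripts planted as graft-mobile;
* FPKM expression tables and metabolite ion-intensity tables over the full
  4 combinations x 2 tissues x 2 conditions x replicates design, with
  planted delta-of-delta effects and planted transcript-metabolite
  correlations;
* a pathway annotation table with an optionally over-represented pathway.

Every generator records what it planted in a :class:`TruthTable`.  The
analysis stages never receive the truth table; tests compare their output
against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    CHILLING,
    CONTROL,
    GraftSample,
    SPECIES,
    TISSUES,
    full_design,
    other_species,
    resident_heterograft,
)
from . import io

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the study conditions being emulated: 150-bp reads,
    three biological replicates, ~1% sequence divergence between the two
    species' homologs (comfortably above the one-diagnostic-site minimum),
    and a modest per-transcript depth suitable for desk-scale runs.
    """

    n_pairs: int = 30
    transcript_length: int = 500
    divergence_rate: float = 0.01
    read_length: int = 150
    depth: float = 20.0
    error_rate: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "transcript_length", "read_length", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.divergence_rate < 1.0:
            raise ValueError("divergence_rate must be in [0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length > self.transcript_length:
            raise ValueError("read_length exceeds transcript_length")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class MobilePlanEntry:
    """One transcript planted as graft-mobile.

    ``reads_per_replicate`` foreign reads of ``transcript_id`` are added to
    every replicate of the destination sample group (graft x tissue x
    condition).  The destination tissue's resident species must differ from
    the transcript's species: only a heterograft can receive foreign mRNA.
    """

    transcript_id: str
    scion: str
    rootstock: str
    tissue: str
    condition: str
    reads_per_replicate: int = 30

    @property
    def origin_species(self) -> str:
        return self.transcript_id.split("_")[0]

    def destination(self, replicate: int) -> GraftSample:
        return GraftSample(self.scion, self.rootstock, self.tissue, self.condition, replicate)


@dataclass
class TruthTable:
    """Planted ground truth, emitted alongside the data and never read by the pipeline."""

    mobile_truth: set[tuple[str, str, str, str, str]] = field(default_factory=set)
    #: (transcript id, origin species, graft, tissue, condition)
    deg_truth: set[tuple[str, str, str]] = field(default_factory=set)
    #: (gene id, tissue, direction "up"/"down")
    dim_truth: set[tuple[str, str, str]] = field(default_factory=set)
    #: (metabolite id, tissue, direction)
    correlation_truth: set[tuple[str, str, int]] = field(default_factory=set)
    #: (gene id, metabolite id, sign +1/-1)
    enriched_pathways: set[tuple[str, str]] = field(default_factory=set)
    #: (pathway id, member feature id) rows of the deliberately enriched pathway

    def merge(self, other: "TruthTable") -> None:
        self.mobile_truth |= other.mobile_truth
        self.deg_truth |= other.deg_truth
        self.dim_truth |= other.dim_truth
        self.correlation_truth |= other.correlation_truth
        self.enriched_pathways |= other.enriched_pathways

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_tsv(
            outdir / "truth_mobile.tsv",
            pd.DataFrame(
                sorted(self.mobile_truth),
                columns=["transcript", "origin", "graft", "tissue", "condition"],
            ),
        )
        io.write_tsv(
            outdir / "truth_deg.tsv",
            pd.DataFrame(sorted(self.deg_truth), columns=["gene", "tissue", "direction"]),
        )
        io.write_tsv(
            outdir / "truth_dim.tsv",
            pd.DataFrame(sorted(self.dim_truth), columns=["metabolite", "tissue", "direction"]),
        )
        io.write_tsv(
            outdir / "truth_correlation.tsv",
            pd.DataFrame(sorted(self.correlation_truth), columns=["gene", "metabolite", "sign"]),
        )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _substitute(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for pos in positions:
        current = arr[pos]
        alternatives = BASES[BASES != current]
        arr[pos] = rng.choice(alternatives)
    return arr.tobytes().decode()


def gene_id(species: str, index: int) -> str:
    return f"{species}_{index:04d}"


def make_homolog_references(
    config: SimulationConfig, allow_no_divergence: bool = False
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Generate two species' transcript sets and the homolog-pair map.

    The second species' sequence of each pair is the first species' sequence
    with substitutions (no indels) at uniformly chosen positions, drawn at
    ``divergence_rate`` per base; every pair carries at least one
    substitution so each homolog pair is discriminable.

    Returns ``(references, pair_map)`` where ``references`` maps species to
    ``{transcript id: sequence}`` and ``pair_map`` has columns ``id_a``
    (Csa) and ``id_b`` (Cmo).
    """
    if config.divergence_rate == 0.0 and not allow_no_divergence:
        raise ValueError(
            "divergence_rate = 0 leaves no diagnostic sites; "
            "pass allow_no_divergence=True to force it"
        )
    if config.divergence_rate * config.transcript_length < 1 and not allow_no_divergence:
        raise ValueError("expected substitutions per pair < 1; increase divergence or length")
    rng = np.random.default_rng(config.seed)
    species_a, species_b = SPECIES
    refs: dict[str, dict[str, str]] = {species_a: {}, species_b: {}}
    rows = []
    for i in range(1, config.n_pairs + 1):
        seq_a = _random_sequence(rng, config.transcript_length)
        n_sub = rng.binomial(config.transcript_length, config.divergence_rate)
        if config.divergence_rate > 0:
            n_sub = max(1, int(n_sub))
        positions = rng.choice(config.transcript_length, size=int(n_sub), replace=False)
        seq_b = _substitute(rng, seq_a, positions) if n_sub else seq_a
        id_a, id_b = gene_id(species_a, i), gene_id(species_b, i)
        refs[species_a][id_a] = seq_a
        refs[species_b][id_b] = seq_b
        rows.append((id_a, id_b))
    pair_map = pd.DataFrame(rows, columns=["id_a", "id_b"])
    return refs, pair_map


def _draw_read(
    rng: np.random.Generator, seq: str, read_length: int, error_rate: float
) -> str:
    start = int(rng.integers(0, len(seq) - read_length + 1))
    read = np.frombuffer(seq[start : start + read_length].encode(), dtype="S1").copy()
    if error_rate > 0:
        errs = np.flatnonzero(rng.random(read_length) < error_rate)
        for pos in errs:
            read[pos] = rng.choice(BASES[BASES != read[pos]])
    return read.tobytes().decode()


def simulate_graft_reads(
    references: dict[str, dict[str, str]],
    mobility_plan: list[MobilePlanEntry],
    config: SimulationConfig,
) -> tuple[dict[str, list[tuple[str, str]]], TruthTable]:
    """Simulate per-sample read sets over the full grafting design.

    Each sample receives Poisson(``depth``) uniformly positioned forward-strand
    reads from every transcript of its tissue's resident species, plus the
    exact per-replicate read counts named in the mobility plan for heterograft
    destinations.  Per-base substitution errors are applied at ``error_rate``.

    Returns ``(reads, truth)`` with ``reads`` mapping sample key to a list of
    ``(read id, sequence)`` tuples.
    """
    all_ids = {tid for sp in references.values() for tid in sp}
    for entry in mobility_plan:
        if entry.transcript_id not in all_ids:
            raise ValueError(f"planted transcript {entry.transcript_id} not in references")
        if entry.reads_per_replicate < 1:
            raise ValueError("planted abundance must be >= 1 read")
        dest = entry.destination(1)
        if not dest.is_heterograft:
            raise ValueError(
                f"{entry.transcript_id}: homograft {dest.graft} cannot receive foreign mRNA"
            )
        if entry.origin_species == dest.resident_species:
            raise ValueError(
                f"{entry.transcript_id}: origin equals resident species of {dest.key}"
            )

    rng = np.random.default_rng(config.seed)
    design = full_design(config.n_replicates)
    reads: dict[str, list[tuple[str, str]]] = {}
    truth = TruthTable()
    plan_by_sample: dict[str, list[MobilePlanEntry]] = {}
    for entry in mobility_plan:
        truth.mobile_truth.add(
            (
                entry.transcript_id,
                entry.origin_species,
                f"{entry.scion}/{entry.rootstock}",
                entry.tissue,
                entry.condition,
            )
        )
        for rep in range(1, config.n_replicates + 1):
            plan_by_sample.setdefault(entry.destination(rep).key, []).append(entry)

    for sample in design:
        resident = references[sample.resident_species]
        sample_reads: list[tuple[str, str]] = []
        serial = 0
        for tid in sorted(resident):
            n = int(rng.poisson(config.depth))
            for _ in range(n):
                seq = _draw_read(rng, resident[tid], config.read_length, config.error_rate)
                sample_reads.append((f"{sample.key}:{serial}", seq))
                serial += 1
        for entry in plan_by_sample.get(sample.key, ()):
            origin_seq = references[entry.origin_species][entry.transcript_id]
            for _ in range(entry.reads_per_replicate):
                seq = _draw_read(rng, origin_seq, config.read_length, config.error_rate)
                sample_reads.append((f"{sample.key}:{serial}", seq))
                serial += 1
        reads[sample.key] = sample_reads
    return reads, truth


# ---------------------------------------------------------------------------
# Expression / intensity tables
# ---------------------------------------------------------------------------


def expected_gene_profiles(
    genes: dict[str, list[str]],
    planted_effects: list[tuple[str, str, float]],
) -> dict[str, dict[tuple[str, str, str], float]]:
    """Expected het-vs-homo log2 fold change per contrast key for each gene.

    Contrast keys are ``(graft, tissue, condition)``.  A planted effect
    ``(gene, tissue, delta)`` is realized entirely in the chilling condition
    of the heterograft whose tissue belongs to the gene's species, so that
    delta1 = 0 and delta2 = delta (the delta-of-delta statistic equals the
    planted value).
    """
    profiles: dict[str, dict[tuple[str, str, str], float]] = {}
    for species, ids in genes.items():
        for g in ids:
            keys = {}
            for tissue in TISSUES:
                sc, rs = resident_heterograft(species, tissue)
                keys[(f"{sc}/{rs}", tissue, CONTROL)] = 0.0
                keys[(f"{sc}/{rs}", tissue, CHILLING)] = 0.0
            profiles[g] = keys
    for g, tissue, effect in planted_effects:
        if not math.isfinite(effect):
            raise ValueError(f"non-finite planted effect for {g}")
        species = g.split("_")[0]
        sc, rs = resident_heterograft(species, tissue)
        profiles[g][(f"{sc}/{rs}", tissue, CHILLING)] = effect
    return profiles


def make_expression_tables(
    genes: dict[str, list[str]],
    planted_effects: list[tuple[str, str, float]],
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
    baseline_mean: float = 30.0,
    pseudocount: float = 1.0,
) -> tuple[dict[str, pd.DataFrame], TruthTable]:
    """FPKM tables per species with planted delta-of-delta effects.

    Rows are genes, columns are the sample keys in which the gene's species
    is the resident tissue partner (its homograft, both tissues, plus the
    heterograft side it occupies).  Background genes have expected
    delta2 - delta1 of 0; a planted ``(gene, tissue, effect)`` shifts the
    chilling heterograft group so the recovered statistic equals ``effect``
    in expectation.  Replicate noise is multiplicative lognormal with
    standard deviation ``noise_sd`` in log space.
    """
    rng = np.random.default_rng(seed)
    profiles = expected_gene_profiles(genes, planted_effects)
    design = full_design(n_replicates)
    truth = TruthTable()
    for g, tissue, effect in planted_effects:
        if abs(effect) > 2:
            truth.deg_truth.add((g, tissue, "up" if effect > 0 else "down"))

    tables: dict[str, pd.DataFrame] = {}
    for species in sorted(genes):
        ids = genes[species]
        samples = [s for s in design if s.resident_species == species]
        baselines = baseline_mean * rng.lognormal(0.0, 0.5, size=len(ids))
        data = np.empty((len(ids), len(samples)))
        for i, g in enumerate(ids):
            b = baselines[i]
            for j, s in enumerate(samples):
                logfc = 0.0
                if s.is_heterograft:
                    logfc = profiles[g][(s.graft, s.tissue, s.condition)]
                mean = (b + pseudocount) * 2.0**logfc - pseudocount
                noise = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
                data[i, j] = mean * noise
        tables[species] = pd.DataFrame(data, index=ids, columns=[s.key for s in samples])
    return tables, truth


def make_metabolite_tables(
    metabolites: list[str],
    planted_dims: list[tuple[str, str, float]],
    planted_correlations: list[tuple[str, str, int]],
    noise_sd: float,
    seed: int,
    gene_profiles: dict[str, dict[tuple[str, str, str], float]] | None = None,
    n_replicates: int = 3,
    baseline_mean: float = 1e5,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, TruthTable]:
    """Ion-intensity table over all samples with planted DIMs and correlations.

    Metabolites are measured in every sample of the design.  A planted DIM
    ``(metabolite, tissue, effect)`` shifts the chilling heterograft groups of
    that tissue (both graft orientations) so the delta-of-delta statistic
    recovers ``effect``.  A planted correlation ``(gene, metabolite, sign)``
    copies ``sign`` times the gene's expected log2 fold-change profile (from
    ``gene_profiles``) onto the metabolite, making their Pearson correlation
    over shared contrasts exactly ±1 in the noiseless case.
    """
    rng = np.random.default_rng(seed)
    design = full_design(n_replicates)
    truth = TruthTable()

    profiles: dict[str, dict[tuple[str, str, str], float]] = {
        m: {} for m in metabolites
    }
    for m, tissue, effect in planted_dims:
        if not math.isfinite(effect):
            raise ValueError(f"non-finite planted effect for {m}")
        if m not in profiles:
            raise ValueError(f"planted DIM {m} not in metabolite list")
        for species in SPECIES:
            sc, rs = resident_heterograft(species, tissue)
            profiles[m][(f"{sc}/{rs}", tissue, CHILLING)] = effect
        if abs(effect) > 2:
            truth.dim_truth.add((m, tissue, "up" if effect > 0 else "down"))
    for g, m, sign in planted_correlations:
        if gene_profiles is None or g not in gene_profiles:
            raise ValueError(f"no expected profile available for correlated gene {g}")
        if sign not in (+1, -1):
            raise ValueError("correlation sign must be +1 or -1")
        for key, value in gene_profiles[g].items():
            profiles[m][key] = sign * value
        truth.correlation_truth.add((g, m, sign))

    baselines = baseline_mean * rng.lognormal(0.0, 0.5, size=len(metabolites))
    data = np.empty((len(metabolites), len(design)))
    for i, m in enumerate(metabolites):
        b = baselines[i]
        for j, s in enumerate(design):
            logfc = 0.0
            if s.is_heterograft:
                logfc = profiles[m].get((s.graft, s.tissue, s.condition), 0.0)
            mean = (b + pseudocount) * 2.0**logfc - pseudocount
            noise = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
            data[i, j] = mean * noise
    table = pd.DataFrame(data, index=metabolites, columns=[s.key for s in design])
    return table, truth


def make_pathway_annotation(
    genes: list[str],
    metabolites: list[str],
    n_pathways: int,
    enriched_pathway_plan: dict[str, list[str]] | None,
    seed: int,
    mean_pathways_per_feature: float = 1.0,
) -> tuple[pd.DataFrame, TruthTable]:
    """Feature-to-pathway annotation table (many-to-many) with a planted enrichment.

    ``enriched_pathway_plan`` maps pathway id to the feature ids deliberately
    annotated to it (over-representation the enrichment test should detect).
    Remaining annotations are drawn uniformly; duplicate (feature, pathway)
    rows are collapsed.
    """
    rng = np.random.default_rng(seed)
    pathways = [f"map{i:05d}" for i in range(1, n_pathways + 1)]
    rows: list[tuple[str, str]] = []
    truth = TruthTable()
    planned: dict[str, set[str]] = {}
    if enriched_pathway_plan:
        for pw, members in enriched_pathway_plan.items():
            for f in members:
                rows.append((f, pw))
                planned.setdefault(f, set()).add(pw)
                truth.enriched_pathways.add((pw, f))
    for f in list(genes) + list(metabolites):
        n = min(int(rng.poisson(mean_pathways_per_feature)), n_pathways)
        for i in rng.choice(n_pathways, size=n, replace=False):
            pw = pathways[int(i)]
            if pw not in planned.get(f, ()):
                rows.append((f, pw))
    frame = pd.DataFrame(rows, columns=["feature", "pathway"])
    before = len(frame)
    frame = frame.drop_duplicates().sort_values(["feature", "pathway"]).reset_index(drop=True)
    if len(frame) < before:
        import warnings

        warnings.warn(f"collapsed {before - len(frame)} duplicate annotation rows", stacklevel=2)
    return frame, truth


# ---------------------------------------------------------------------------
# Whole-dataset orchestration
# ---------------------------------------------------------------------------


@dataclass
class GraftDataset:
    """Everything one synthetic study produces, in memory."""

    config: SimulationConfig
    references: dict[str, dict[str, str]]
    pair_map: pd.DataFrame
    reads: dict[str, list[tuple[str, str]]]
    expression: dict[str, pd.DataFrame]
    intensity: pd.DataFrame
    annotation: pd.DataFrame
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for species, seqs in self.references.items():
            io.write_fasta(outdir / f"ref_{species}.fasta", seqs)
        io.write_tsv(outdir / "pair_map.tsv", self.pair_map)
        readsdir = outdir / "reads"
        readsdir.mkdir(exist_ok=True)
        for key, rds in self.reads.items():
            io.write_fastq(readsdir / f"{key}.fastq", rds)
        for species, table in self.expression.items():
            table.rename_axis("gene").reset_index().to_csv(
                outdir / f"fpkm_{species}.tsv", sep="\t", index=False
            )
        self.intensity.rename_axis("metabolite").reset_index().to_csv(
            outdir / "intensity.tsv", sep="\t", index=False
        )
        io.write_tsv(outdir / "annotation.tsv", self.annotation)
        self.truth.write(outdir / "truth")
        manifest = [f"seed={self.config.seed}"] + [
            f"{k}={getattr(self.config, k)}"
            for k in (
                "n_pairs",
                "transcript_length",
                "divergence_rate",
                "read_length",
                "depth",
                "error_rate",
                "n_replicates",
            )
        ]
        (outdir / "manifest.txt").write_text("\n".join(manifest) + "\n")


def generate_dataset(
    config: SimulationConfig,
    mobility_plan: list[MobilePlanEntry] | None = None,
    planted_effects: list[tuple[str, str, float]] | None = None,
    planted_dims: list[tuple[str, str, float]] | None = None,
    planted_correlations: list[tuple[str, str, int]] | None = None,
    n_metabolites: int = 40,
    n_pathways: int = 12,
    enriched_pathway_plan: dict[str, list[str]] | None = None,
    noise_sd: float = 0.0,
) -> GraftDataset:
    """Generate a complete coherent dataset from one config and seed."""
    mobility_plan = mobility_plan or []
    planted_effects = planted_effects or []
    planted_dims = planted_dims or []
    planted_correlations = planted_correlations or []

    refs, pair_map = make_homolog_references(config)
    reads, truth = simulate_graft_reads(refs, mobility_plan, config)
    genes = {sp: sorted(refs[sp]) for sp in refs}
    expr, deg_truth = make_expression_tables(
        genes,
        planted_effects,
        noise_sd=noise_sd,
        seed=config.seed + 1,
        n_replicates=config.n_replicates,
    )
    truth.merge(deg_truth)
    metabolites = [f"met_{i:04d}" for i in range(1, n_metabolites + 1)]
    profiles = expected_gene_profiles(genes, planted_effects)
    intensity, dim_truth = make_metabolite_tables(
        metabolites,
        planted_dims,
        planted_correlations,
        noise_sd=noise_sd,
        seed=config.seed + 2,
        gene_profiles=profiles,
        n_replicates=config.n_replicates,
    )
    truth.merge(dim_truth)
    all_genes = [g for sp in sorted(genes) for g in genes[sp]]
    annotation, pw_truth = make_pathway_annotation(
        all_genes,
        metabolites,
        n_pathways=n_pathways,
        enriched_pathway_plan=enriched_pathway_plan,
        seed=config.seed + 3,
    )
    truth.merge(pw_truth)
    return GraftDataset(
        config=config,
        references=refs,
        pair_map=pair_map,
        reads=reads,
        expression=expr,
        intensity=intensity,
        annotation=annotation,
        truth=truth,
    )
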